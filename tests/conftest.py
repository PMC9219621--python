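"""Shared fixtures: phantom study sets and cross-validated branch runs.

The heavy artefacts (a 400-lesion default phantom study with segmentation,
features and Model-I CV scores, and a trivially separable deep-branch run)
are session-scoped so the end-to-end checks reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from mammocad.classical import ClassicalConfig, cross_validated_scores
from mammocad.dl import DLConfig, finetune_cv
from mammocad.phantom import PhantomSpec, generate_dataset
from mammocad.radiomics import extract_dataset
from mammocad.scores import make_folds
from mammocad.segmentation import segment_lesion

STUDY_SEED = 42


@pytest.fixture(scope="session")
def phantom_study():
    """200 malignant + 200 benign default phantoms with segmentations."""
    rois = generate_dataset(PhantomSpec(), 200, 200, rng_seed=STUDY_SEED)
    segs = [segment_lesion(r) for r in rois]
    return rois, segs


@pytest.fixture(scope="session")
def phantom_features(phantom_study):
    rois, segs = phantom_study
    feats, labels = extract_dataset(rois, segs)
    return feats, labels


@pytest.fixture(scope="session")
def model1_folds(phantom_features):
    feats, labels = phantom_features
    return make_folds(labels.values, k=10, rng_seed=STUDY_SEED,
                      sample_ids=list(feats.index))


@pytest.fixture(scope="session")
def model1_scores(phantom_features, model1_folds):
    feats, labels = phantom_features
    return cross_validated_scores(feats, labels, model1_folds,
                                  ClassicalConfig())


def separable_specs():
    """Class-coded contrast with fixed lesion size: trivially separable."""
    mal = PhantomSpec(lesion_contrast_range=(2600.0, 3200.0),
                      lesion_radius_range=(20.0, 20.0),
                      edge_case_fraction=0.0)
    ben = PhantomSpec(lesion_contrast_range=(600.0, 900.0),
                      lesion_radius_range=(20.0, 20.0),
                      edge_case_fraction=0.0)
    return mal, ben


@pytest.fixture(scope="session")
def separable_dl_run():
    """Surrogate-backbone finetuning on 60 separable phantoms, k=3."""
    mal_spec, ben_spec = separable_specs()
    rois = (generate_dataset(mal_spec, 30, 0, rng_seed=21, id_prefix="m")
            + generate_dataset(ben_spec, 0, 30, rng_seed=22, id_prefix="b"))
    folds = make_folds([r.label for r in rois], k=3, rng_seed=4,
                       sample_ids=[r.sample_id for r in rois])
    config = DLConfig(rng_seed=9)
    table, history = finetune_cv(rois, folds, config)
    return rois, folds, table, history
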