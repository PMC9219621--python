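"""End-to-end orchestration of the two-branch CAD pipeline.

simulate (or ingest) -> segment -> radiomics features -> Model-I CV scores
-> Model-II CV scores (surrogate backbone) -> four score fusions ->
model-comparison report.  Every intermediate artefact is persisted under the
output directory and all joins are by sample_id.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classical, dl, evaluation, fusion, phantom, radiomics
from .config import PipelineConfig, save_config
from .scores import ScoreTable, make_folds
from .segmentation import segment_lesion

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: evaluation.ModelReport
    score_tables: dict
    out_dir: Path
    features: pd.DataFrame
    labels: pd.Series
    dice: pd.Series | None = None


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}"
                                   ) from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    rois = phantom.generate_dataset(config.phantom, config.n_malignant,
                                    config.n_benign, config.rng_seed)
    phantom.write_dataset(rois, out / "phantoms")
    return rois


@_stage("segment")
def _segment(config: PipelineConfig, rois, out: Path):
    from .segmentation import dice as dice_fn

    mask_dir = out / "segmentations"
    mask_dir.mkdir(parents=True, exist_ok=True)
    segs = []
    layer_rows = []
    dice_vals = {}
    for roi in rois:
        seg = segment_lesion(roi, config.segmentation)
        segs.append(seg)
        Image.fromarray((seg.final_mask * 255).astype(np.uint8)).save(
            mask_dir / f"{roi.sample_id}.png")
        for layer in seg.layers:
            layer_rows.append({
                "sample_id": roi.sample_id, "j": layer.index_j,
                "Tj": layer.threshold_Tj, "Sj": layer.area_Sj,
                "Vj": layer.circularity_Vj, "Cj": layer.contrast_Cj,
                "terminated": seg.termination_reason
                if layer.index_j == seg.final_layer_index + 1 else ""})
        if roi.truth_mask is not None:
            dice_vals[roi.sample_id] = dice_fn(seg.final_mask, roi.truth_mask)
    pd.DataFrame(layer_rows).to_csv(out / "segmentation_layers.csv",
                                    index=False)
    dice_series = pd.Series(dice_vals, name="dice") if dice_vals else None
    if dice_series is not None:
        dice_series.rename_axis("sample_id").to_csv(out / "segmentation_dice.csv")
    return segs, dice_series


@_stage("features")
def _features(config: PipelineConfig, rois, segs, out: Path):
    feats, labels = radiomics.extract_dataset(rois, segs, config.radiomics)
    df = feats.copy()
    df.insert(0, "label", labels)
    df.to_csv(out / "features.csv")
    return feats, labels


@_stage("train-classical")
def _model_i(config: PipelineConfig, feats, labels, folds, out: Path):
    table = classical.cross_validated_scores(feats, labels, folds,
                                             config.classical)
    table.to_csv(out / "scores_model_I.csv")
    return table


@_stage("train-dl")
def _model_ii(config: PipelineConfig, rois, folds, out: Path):
    cfg = config.dl
    if cfg.rng_seed != config.rng_seed:
        cfg = dl.DLConfig(**{**cfg.__dict__, "rng_seed": config.rng_seed})
    table, history = dl.finetune_cv(rois, folds, cfg)
    table.to_csv(out / "scores_model_II.csv")
    with open(out / "dl_training_history.json", "w") as fh:
        json.dump({str(k): v for k, v in history.items()}, fh, indent=1)
    return table


@_stage("fuse")
def _fusions(config: PipelineConfig, t1: ScoreTable, t2: ScoreTable, folds,
             out: Path) -> dict:
    tables = {
        fusion.MODEL_III1: fusion.fuse_svm(t1, t2, folds),
        fusion.MODEL_III2: fusion.fuse_tables(t1, t2, "avg",
                                              config.fusion.w1),
        fusion.MODEL_III3: fusion.fuse_tables(t1, t2, "min"),
        fusion.MODEL_III4: fusion.fuse_tables(t1, t2, "max"),
    }
    for name, t in tables.items():
        t.to_csv(out / f"scores_{name.replace('-', '_').replace('.', '_')}.csv")
    return tables


def run_pipeline(config: PipelineConfig, rois=None) -> PipelineResult:
    """Run the full two-branch + fusion pipeline.

    ``rois`` may be a pre-loaded dataset; by default phantoms are simulated
    from the config.  When ``config.dl_enabled`` is false the deep branch
    and the fusion stage are skipped with a logged notice.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "effective_config.yaml")

    if rois is None:
        rois = _simulate(config, out)
    segs, dice_series = _segment(config, rois, out)
    feats, labels = _features(config, rois, segs, out)
    folds = make_folds(labels.values, k=config.classical.k,
                       rng_seed=config.rng_seed,
                       sample_ids=list(feats.index))
    tables: dict = {}
    t1 = _model_i(config, feats, labels, folds, out)
    tables[classical.MODEL_I] = t1
    if config.dl_enabled:
        t2 = _model_ii(config, rois, folds, out)
        tables[dl.MODEL_II] = t2
        tables.update(_fusions(config, t1, t2, folds, out))
    else:
        log.info("deep branch disabled: skipping Model-II and fusion stages")

    report = evaluation.summarize_models(
        list(tables.values()), threshold=config.evaluation.threshold,
        n_bins=config.evaluation.n_bins)
    report.table.to_csv(out / "report.csv", index=False)
    report.pairwise_p.to_csv(out / "report_pairwise_p.csv")
    with open(out / "report.md", "w") as fh:
        fh.write(report.to_markdown() + "\n")
    return PipelineResult(report=report, score_tables=tables, out_dir=out,
                          features=feats, labels=labels, dice=dice_series)
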