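"""Score-level fusion of the two CAD branches (Model-III.1 to III.4).

Given the per-sample malignancy scores S1 (radiomics branch) and S2 (deep
branch), the four fusion models are: a stacked SVM on the score pair
(III.1), the weighted average W1*S1 + (1-W1)*S2 with W1 = 0.5 by default
(III.2), the pointwise minimum (III.3) and the pointwise maximum (III.4).
The stacked SVM reuses the fold assignment that produced S1 and S2, so no
test score ever enters its training."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classical import fit_svm
from .scores import FoldAssignment, ScoreTable

MODEL_III1 = "Model-III.1"
MODEL_III2 = "Model-III.2"
MODEL_III3 = "Model-III.3"
MODEL_III4 = "Model-III.4"


def _check_unit(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def fuse_weighted(s1, s2, w1: float = 0.5):
    """W1*S1 + (1-W1)*S2, elementwise."""
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must lie in [0, 1]")
    a = _check_unit(s1, "s1")
    b = _check_unit(s2, "s2")
    return w1 * a + (1.0 - w1) * b


def fuse_min(s1, s2):
    """Elementwise minimum of the two branch scores."""
    return np.minimum(_check_unit(s1, "s1"), _check_unit(s2, "s2"))


def fuse_max(s1, s2):
    """Elementwise maximum of the two branch scores."""
    return np.maximum(_check_unit(s1, "s1"), _check_unit(s2, "s2"))


def _common(t1: ScoreTable, t2: ScoreTable) -> pd.DataFrame:
    a = t1.df.set_index("sample_id")
    b = t2.df.set_index("sample_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no common samples between score tables")
    m = pd.DataFrame({
        "s1": a.loc[common, "score"],
        "s2": b.loc[common, "score"],
        "fold": a.loc[common, "fold"],
        "true_label": a.loc[common, "true_label"],
    })
    lb = b.loc[common, "true_label"]
    if not np.array_equal(m["true_label"].to_numpy(), lb.to_numpy()):
        raise ValueError("true labels disagree between the two score tables")
    return m


def fuse_tables(t1: ScoreTable, t2: ScoreTable, method: str,
                w1: float = 0.5) -> ScoreTable:
    """Pointwise fusion (avg/min/max) of two aligned score tables."""
    m = _common(t1, t2)
    if method in ("avg", "weighted"):
        fused = fuse_weighted(m["s1"], m["s2"], w1)
        model_id = MODEL_III2
    elif method == "min":
        fused = fuse_min(m["s1"], m["s2"])
        model_id = MODEL_III3
    elif method == "max":
        fused = fuse_max(m["s1"], m["s2"])
        model_id = MODEL_III4
    else:
        raise ValueError(f"unknown fusion method: {method}")
    return ScoreTable.from_arrays(m.index, model_id, m["fold"],
                                  m["true_label"], fused,
                                  sources=(t1.model_id, t2.model_id), w1=w1)


def fuse_svm(t1: ScoreTable, t2: ScoreTable, folds: FoldAssignment,
             kernel_degree: int = 3, regularisation: float = 1.0
             ) -> ScoreTable:
    """Stacked SVM on the score pair (S1, S2), trained and tested under the
    same fold assignment that produced the branch scores."""
    m = _common(t1, t2)
    ids = list(m.index)
    if set(ids) - set(folds.assignments):
        raise ValueError("fold assignment does not cover the fused samples")
    X = m[["s1", "s2"]].to_numpy(dtype=float)
    y = m["true_label"].to_numpy(dtype=int)
    pos = {s: i for i, s in enumerate(ids)}
    out_ids, out_folds, out_labels, out_scores = [], [], [], []
    for fold in range(1, folds.k + 1):
        test_ids = [s for s in folds.test_ids(fold) if s in pos]
        train_ids = [s for s in folds.train_ids(fold) if s in pos]
        if not test_ids:
            continue
        tr = np.array([pos[s] for s in train_ids])
        te = np.array([pos[s] for s in test_ids])
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        scorer = fit_svm((X[tr] - mu) / sd, y[tr], kernel_degree,
                         regularisation)
        s = scorer.score((X[te] - mu) / sd)
        out_ids.extend(test_ids)
        out_folds.extend([fold] * len(te))
        out_labels.extend(y[te])
        out_scores.extend(s)
    return ScoreTable.from_arrays(out_ids, MODEL_III1, out_folds, out_labels,
                                  out_scores,
                                  sources=(t1.model_id, t2.model_id))
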