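"""Shared containers: per-sample classification scores and CV fold assignment.

A ScoreTable holds one calibrated malignancy score in [0, 1] per
(sample_id, model_id), together with the CV fold that produced it and the
true label.  All joins across pipeline stages are by sample_id, never by row
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import MALIGNANT, BENIGN

COLUMNS = ["sample_id", "model_id", "fold", "true_label", "score"]


def label_to_int(labels) -> np.ndarray:
    """malignant -> 1, benign -> 0."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iufb":
        return arr.astype(int)
    out = np.where(arr == MALIGNANT, 1, np.where(arr == BENIGN, 0, -1))
    if (out < 0).any():
        raise ValueError("labels must be 'malignant'/'benign' or 0/1")
    return out


@dataclass(frozen=True)
class FoldAssignment:
    """Maps sample_id -> fold index in 1..k."""

    assignments: dict
    k: int
    rng_seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        folds = set(self.assignments.values())
        if not folds <= set(range(1, self.k + 1)):
            raise ValueError("fold indices must lie in 1..k")

    def fold_of(self, sample_id) -> int:
        return self.assignments[sample_id]

    def test_ids(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list:
        return [s for s, f in self.assignments.items() if f != fold]


def make_folds(labels, k: int = 10, rng_seed: int = 0, stratified: bool = True,
               sample_ids=None) -> FoldAssignment:
    """Random (optionally label-stratified) k-fold partition.

    Every sample lands in exactly one fold; stratification keeps per-class
    fold sizes within one of each other.  Deterministic given rng_seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed the number of samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    sample_ids = list(sample_ids)
    rng = np.random.default_rng(rng_seed)
    assignments: dict = {}
    if stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for pos, i in enumerate(idx):
                assignments[sample_ids[i]] = pos % k + 1
    else:
        idx = rng.permutation(n)
        for pos, i in enumerate(idx):
            assignments[sample_ids[i]] = pos % k + 1
    return FoldAssignment(assignments=assignments, k=k, rng_seed=rng_seed,
                          stratified=stratified)


@dataclass
class ScoreTable:
    """Per-sample classification scores with fold and label bookkeeping."""

    df: pd.DataFrame
    fold_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"ScoreTable missing columns: {sorted(missing)}")
        s = self.df["score"].to_numpy(dtype=float)
        if np.any((s < 0) | (s > 1)) or not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite and in [0, 1]")
        if self.df.duplicated(["sample_id", "model_id"]).any():
            raise ValueError("duplicate (sample_id, model_id) rows")

    @classmethod
    def from_arrays(cls, sample_ids, model_id: str, folds, labels, scores,
                    **fold_info) -> "ScoreTable":
        df = pd.DataFrame({
            "sample_id": list(sample_ids),
            "model_id": model_id,
            "fold": np.asarray(folds, dtype=int),
            "true_label": label_to_int(labels),
            "score": np.asarray(scores, dtype=float),
        })
        return cls(df=df, fold_info=dict(fold_info))

    @property
    def model_id(self) -> str:
        ids = self.df["model_id"].unique()
        return ids[0] if len(ids) == 1 else ",".join(ids)

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return label_to_int(self.df["true_label"].to_numpy())

    @property
    def folds(self) -> np.ndarray:
        return self.df["fold"].to_numpy(dtype=int)

    @property
    def sample_ids(self) -> list:
        return self.df["sample_id"].tolist()

    def aligned_to(self, other: "ScoreTable") -> tuple[np.ndarray, np.ndarray]:
        """Scores of self and other on their common samples, sample-aligned."""
        a = self.df.set_index("sample_id")
        b = other.df.set_index("sample_id")
        common = a.index.intersection(b.index)
        return (a.loc[common, "score"].to_numpy(),
                b.loc[common, "score"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        self.df[COLUMNS].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ScoreTable":
        return cls(df=pd.read_csv(path))
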