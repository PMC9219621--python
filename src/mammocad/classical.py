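"""Radiomics branch classifier (Model-I): PCA at 95% variance + polynomial SVM.

Per cross-validation fold, feature standardisation, the PCA projection, the
SVM and its sigmoid score calibration are all fitted on the nine training
folds only; the held-out fold is scored with calibrated malignancy
likelihoods in [0, 1].  No test-fold information enters any fitting step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .scores import FoldAssignment, ScoreTable, label_to_int, make_folds

log = logging.getLogger(__name__)

MODEL_I = "Model-I"


@dataclass
class PCAModel:
    """Standardise-then-project model retaining a target variance fraction."""

    feature_means: np.ndarray
    feature_scales: np.ndarray
    kept_columns: np.ndarray        # columns with nonzero training variance
    components: np.ndarray          # (n_retained, n_kept) orthonormal rows
    explained_variance_ratios: np.ndarray
    n_retained: int
    variance_target: float = 0.95

    def standardise(self, X: np.ndarray) -> np.ndarray:
        Xk = np.asarray(X, dtype=float)[:, self.kept_columns]
        return (Xk - self.feature_means) / self.feature_scales

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.standardise(X) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Back to standardised feature space (exact when all components kept)."""
        return np.asarray(Z) @ self.components


def fit_pca(train_features: np.ndarray, variance_target: float = 0.95
            ) -> PCAModel:
    """Z-score the training features and retain the minimal number of leading
    principal components with cumulative explained variance >= the target.

    Zero-variance features are dropped (and logged) before projection.
    """
    X = np.asarray(train_features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < X.shape[1]:
        log.warning("dropping %d zero-variance features",
                    X.shape[1] - len(kept))
    if len(kept) == 0:
        raise ValueError("all features have zero variance")
    mu = X[:, kept].mean(axis=0)
    scale = sd[kept]
    Z = (X[:, kept] - mu) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    n_retained = int(np.searchsorted(cum, variance_target) + 1)
    n_retained = min(n_retained, len(ratios))
    return PCAModel(feature_means=mu, feature_scales=scale, kept_columns=kept,
                    components=pca.components_[:n_retained],
                    explained_variance_ratios=ratios,
                    n_retained=n_retained, variance_target=variance_target)


@dataclass
class SVMScorer:
    """Polynomial-kernel SVM with a monotone sigmoid calibration of its margin."""

    svc: SVC
    calibrator: LogisticRegression

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(np.asarray(X, dtype=float))

    def score(self, X: np.ndarray) -> np.ndarray:
        margins = self.decision(X).reshape(-1, 1)
        p = self.calibrator.predict_proba(margins)[:, 1]
        return np.clip(p, 0.0, 1.0)


def fit_svm(train_components: np.ndarray, labels, kernel_degree: int = 3,
            regularisation: float = 1.0) -> SVMScorer:
    """Fit the polynomial SVM plus a sigmoid (Platt-style) calibration, both
    on the training data only; returns a scorer mapping vectors to [0, 1]."""
    y = label_to_int(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = np.asarray(train_components, dtype=float)
    svc = SVC(kernel="poly", degree=kernel_degree, C=regularisation,
              coef0=1.0, gamma="scale")
    svc.fit(X, y)
    margins = svc.decision_function(X).reshape(-1, 1)
    calibrator = LogisticRegression(C=1e3)
    calibrator.fit(margins, y)
    return SVMScorer(svc=svc, calibrator=calibrator)


@dataclass(frozen=True)
class ClassicalConfig:
    variance_target: float = 0.95
    kernel_degree: int = 3
    regularisation: float = 1.0
    k: int = 10


def cross_validated_scores(features: pd.DataFrame, labels,
                           folds: FoldAssignment,
                           config: ClassicalConfig = ClassicalConfig(),
                           model_id: str = MODEL_I) -> ScoreTable:
    """10-fold CV scores for the radiomics branch.

    ``features`` is a (sample x feature) DataFrame indexed by sample_id and
    aligned with ``labels``; ``folds`` assigns each sample to one test fold.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(features.index)
    y = label_to_int(labels)
    ids = list(features.index)
    if set(ids) != set(folds.assignments):
        raise ValueError("fold assignment does not cover the feature samples")
    X = features.to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(ids)}

    out_ids, out_folds, out_labels, out_scores = [], [], [], []
    n_retained_per_fold = {}
    for fold in range(1, folds.k + 1):
        test_ids = folds.test_ids(fold)
        train_ids = folds.train_ids(fold)
        tr = np.array([pos[s] for s in train_ids])
        te = np.array([pos[s] for s in test_ids])
        if len(te) == 0:
            continue
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training folds for fold {fold} are single-class")
        pca = fit_pca(X[tr], config.variance_target)
        scorer = fit_svm(pca.transform(X[tr]), y[tr],
                         config.kernel_degree, config.regularisation)
        s = scorer.score(pca.transform(X[te]))
        n_retained_per_fold[fold] = pca.n_retained
        out_ids.extend(test_ids)
        out_folds.extend([fold] * len(te))
        out_labels.extend(y[te])
        out_scores.extend(s)
    return ScoreTable.from_arrays(out_ids, model_id, out_folds, out_labels,
                                  out_scores,
                                  n_retained_per_fold=n_retained_per_fold)
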