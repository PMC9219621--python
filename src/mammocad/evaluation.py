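"""ROC and accuracy evaluation of classifier score tables.

Two AUC estimators are provided: the empirical (Mann-Whitney) estimator with
a DeLong-style variance, and a binormal maximum-likelihood fit in the ROCKIT
model family, in which the latent decision variable is standard normal for
benign cases and N(a/b, 1/b) for malignant cases, so that
TPF = Phi(a + b * Phi^-1(FPF)) and AUC = Phi(a / sqrt(1 + b^2)).  Continuous
scores are binned into ordered categories and the ordinal-category likelihood
is maximised over (a, b) and the category cutpoints.

Accuracy uses the fixed operating threshold convention: score <= T is called
benign, score > T malignant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scores import ScoreTable

log = logging.getLogger(__name__)

EMPIRICAL = "empirical"
BINORMAL = "binormal_mle"


@dataclass
class ROCResult:
    auc: float
    auc_std: float
    method: str
    curve: np.ndarray                      # ordered (FPR, TPR) points
    binormal_a: float | None = None
    binormal_b: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must be in [0, 1]")


@dataclass
class AccuracyResult:
    acc: float
    threshold: float
    tm: int      # correctly classified malignant
    tb: int      # correctly classified benign
    n: int

    def __post_init__(self) -> None:
        assert self.n == 0 or abs(self.acc - (self.tm + self.tb) / self.n) < 1e-12


def _split_scores(table: ScoreTable) -> tuple[np.ndarray, np.ndarray]:
    y = table.labels
    s = table.scores
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(pos: np.ndarray, neg: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-case structural components V10, V01."""
    m, n = len(pos), len(neg)
    allr = _midrank(np.concatenate([pos, neg]))
    rp = _midrank(pos)
    rn = _midrank(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (allr[:m] - rp) / n                 # P(neg < pos_i) with tie credit
    v01 = 1.0 - (allr[m:] - rn) / m
    return float(auc), v10, v01


def _empirical_curve(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    thr = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thr:
        tpr.append(float((pos >= t).mean()))
        fpr.append(float((neg >= t).mean()))
    fpr.append(1.0)
    tpr.append(1.0)
    return np.column_stack([fpr, tpr])


def empirical_auc(table: ScoreTable) -> ROCResult:
    """Mann-Whitney AUC (ties get half credit) with DeLong variance."""
    pos, neg = _split_scores(table)
    auc, v10, v01 = _delong_components(pos, neg)
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    return ROCResult(auc=auc, auc_std=float(np.sqrt(var)), method=EMPIRICAL,
                     curve=_empirical_curve(pos, neg))


def compare_auc(table_a: ScoreTable, table_b: ScoreTable) -> float:
    """Two-sided p-value for the paired AUC difference (DeLong-style).

    Requires both tables to score the same samples; the covariance of the
    two AUCs is estimated from the paired structural components.
    """
    a = table_a.df.set_index("sample_id").sort_index()
    b = table_b.df.set_index("sample_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("score tables must cover the same samples")
    if not np.array_equal(a["true_label"].to_numpy(), b["true_label"].to_numpy()):
        raise ValueError("true labels disagree between tables")
    y = table_a.__class__(df=a.reset_index()).labels
    sa = a["score"].to_numpy(dtype=float)
    sb = b["score"].to_numpy(dtype=float)
    pos_mask = y == 1
    auc_a, v10a, v01a = _delong_components(sa[pos_mask], sa[~pos_mask])
    auc_b, v10b, v01b = _delong_components(sb[pos_mask], sb[~pos_mask])
    m, n = pos_mask.sum(), (~pos_mask).sum()
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# binormal maximum-likelihood fit
# ---------------------------------------------------------------------------

def _bin_counts(pos: np.ndarray, neg: np.ndarray, n_bins: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-quantile binning into ordered categories; empty bins merged."""
    pooled = np.concatenate([pos, neg])
    qs = np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    kp = np.histogram(pos, bins=np.concatenate([[-np.inf], edges, [np.inf]]))[0]
    kn = np.histogram(neg, bins=np.concatenate([[-np.inf], edges, [np.inf]]))[0]
    keep = (kp + kn) > 0
    return kp[keep], kn[keep]


def _binormal_nll(theta: np.ndarray, kp: np.ndarray, kn: np.ndarray) -> float:
    """Negative ordinal log-likelihood; theta = [a, log b, c1, log dc...]."""
    a, logb = theta[0], theta[1]
    b = np.exp(logb)
    cuts = np.concatenate([[theta[2]], theta[2] + np.cumsum(np.exp(theta[3:]))])
    cn = stats.norm.cdf(cuts)                    # benign latent ~ N(0,1)
    cp = stats.norm.cdf(b * cuts - a)            # P(malignant latent <= c)
    pn = np.diff(np.concatenate([[0.0], cn, [1.0]]))
    pp = np.diff(np.concatenate([[0.0], cp, [1.0]]))
    eps = 1e-12
    return -(np.sum(kn * np.log(pn + eps)) + np.sum(kp * np.log(pp + eps)))


def _binormal_curve(a: float, b: float, n_points: int = 200) -> np.ndarray:
    fpr = np.linspace(1e-6, 1 - 1e-6, n_points)
    tpr = stats.norm.cdf(a + b * stats.norm.ppf(fpr))
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return np.column_stack([fpr, tpr])


def binormal_auc(a: float, b: float) -> float:
    """Closed-form AUC of the binormal model: Phi(a / sqrt(1 + b^2))."""
    return float(stats.norm.cdf(a / np.sqrt(1.0 + b * b)))


def _numerical_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)) / (4 * h * h)
    return H


def binormal_fit(table: ScoreTable, n_bins: int = 10) -> ROCResult:
    """Fit the binormal ROC model by maximising the ordinal-category
    likelihood of quantile-binned scores.

    The AUC standard deviation comes from the inverse observed information
    via the delta method.  Degenerate (perfectly separated) data yields
    AUC 1.0 with ``converged=False``.
    """
    pos, neg = _split_scores(table)
    if pos.min() > neg.max():
        warnings.warn("perfect separation: binormal fit is degenerate")
        return ROCResult(auc=1.0, auc_std=0.0, method=BINORMAL,
                         curve=_binormal_curve(6.0, 1.0), binormal_a=np.inf,
                         binormal_b=1.0, converged=False)
    kp, kn = _bin_counts(pos, neg, n_bins)
    k = len(kp)
    if k < 2:
        raise ValueError("need at least two score categories")

    # moment-based initialisation from the probit-transformed empirical CDFs
    cn = np.clip(np.cumsum(kn)[:-1] / kn.sum(), 1e-4, 1 - 1e-4)
    cp = np.clip(np.cumsum(kp)[:-1] / kp.sum(), 1e-4, 1 - 1e-4)
    zn = stats.norm.ppf(cn)
    zp = stats.norm.ppf(cp)
    if len(zn) >= 2 and np.ptp(zn) > 0:
        b0 = max(np.polyfit(zn, zp, 1)[0], 0.05)
    else:
        b0 = 1.0
    a0 = float(np.mean(b0 * zn - zp))
    cuts0 = zn
    theta0 = np.concatenate([
        [a0, np.log(b0), cuts0[0]],
        np.log(np.maximum(np.diff(cuts0), 1e-3))])

    res = optimize.minimize(_binormal_nll, theta0, args=(kp, kn),
                            method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-7,
                                     "fatol": 1e-9})
    res = optimize.minimize(_binormal_nll, res.x, args=(kp, kn),
                            method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-7})
    a = float(res.x[0])
    b = float(np.exp(res.x[1]))
    auc = binormal_auc(a, b)

    # delta-method std: AUC = Phi(a / sqrt(1 + b^2)); information in (a, log b)
    auc_std = np.nan
    try:
        H = _numerical_hessian(lambda th: _binormal_nll(th, kp, kn), res.x)
        cov = np.linalg.inv(H)[:2, :2]
        s = np.sqrt(1.0 + b * b)
        phi = stats.norm.pdf(a / s)
        # gradient wrt (a, log b): d/da = phi / s ; d/dlogb = -phi*a*b^2/s^3
        g = np.array([phi / s, -phi * a * b * b / s ** 3])
        var = float(g @ cov @ g)
        auc_std = float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(auc_std):
        log.warning("binormal information matrix singular; std unavailable")
        auc_std = 0.0
    return ROCResult(auc=auc, auc_std=auc_std, method=BINORMAL,
                     curve=_binormal_curve(a, b), binormal_a=a, binormal_b=b,
                     converged=bool(res.success or res.fun < np.inf))


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def accuracy_at_threshold(table: ScoreTable, threshold: float = 0.5
                          ) -> AccuracyResult:
    """Overall accuracy ACC = (TM + TB) / N at the operating threshold.

    Convention: score <= threshold is called benign, score > threshold
    malignant (a malignant case scored exactly at the threshold counts as an
    error).
    """
    if len(table.df) == 0:
        raise ValueError("empty score table")
    y = table.labels
    s = table.scores
    called_malignant = s > threshold
    tm = int(np.sum(called_malignant & (y == 1)))
    tb = int(np.sum(~called_malignant & (y == 0)))
    n = len(y)
    return AccuracyResult(acc=(tm + tb) / n, threshold=threshold,
                          tm=tm, tb=tb, n=n)


def per_fold_accuracy(table: ScoreTable, threshold: float = 0.5
                      ) -> tuple[list[AccuracyResult], float, float]:
    """Accuracy per CV fold plus the mean and SD across folds."""
    results = []
    for fold in sorted(np.unique(table.folds)):
        sub = ScoreTable(df=table.df[table.df["fold"] == fold])
        results.append(accuracy_at_threshold(sub, threshold))
    accs = np.array([r.acc for r in results])
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return results, float(accs.mean()), sd


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Per-model AUC/ACC summary plus pairwise AUC comparison p-values."""

    table: pd.DataFrame
    pairwise_p: pd.DataFrame

    def to_markdown(self) -> str:
        lines = ["| " + " | ".join(self.table.columns) + " |",
                 "|" + "---|" * len(self.table.columns)]
        for _, row in self.table.iterrows():
            lines.append("| " + " | ".join(
                f"{v:.3f}" if isinstance(v, float) else str(v)
                for v in row) + " |")
        return "\n".join(lines)


def summarize_models(score_tables: list[ScoreTable], threshold: float = 0.5,
                     n_bins: int = 10) -> ModelReport:
    """Tabulate AUC +/- STD (empirical and binormal) and ACC +/- STD (across
    folds) for each model, plus pairwise empirical-AUC p-values."""
    rows = []
    for t in score_tables:
        emp = empirical_auc(t)
        try:
            binr = binormal_fit(t, n_bins=n_bins)
            b_auc, b_std = binr.auc, binr.auc_std
        except ValueError:
            b_auc, b_std = np.nan, np.nan
        _, acc_mean, acc_sd = per_fold_accuracy(t, threshold)
        pooled = accuracy_at_threshold(t, threshold)
        rows.append({"model_id": t.model_id, "n": len(t.df),
                     "auc": emp.auc, "auc_std": emp.auc_std,
                     "auc_binormal": b_auc, "auc_binormal_std": b_std,
                     "acc": pooled.acc, "acc_fold_mean": acc_mean,
                     "acc_fold_sd": acc_sd})
    table = pd.DataFrame(rows)
    ids = [t.model_id for t in score_tables]
    p = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for i, ta in enumerate(score_tables):
        for j, tb in enumerate(score_tables):
            if i < j:
                try:
                    pv = compare_auc(ta, tb)
                except ValueError:
                    pv = np.nan
                p.iloc[i, j] = p.iloc[j, i] = pv
    return ModelReport(table=table, pairwise_p=p)
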