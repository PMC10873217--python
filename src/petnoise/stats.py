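"""Validation statistics.

Implements the statistical battery used to validate an automated noise index
against manual measurements and reader quality labels: z-scoring, a paired
two-sample Kolmogorov–Smirnov comparison (within-pair permutation null),
Spearman rank correlation with Chan's verbal interpretation scale, and ROC
analysis with a DeLong AUC confidence interval and Youden-optimal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import (
    DegenerateLabelsError,
    UndefinedCorrelationError,
    UnpairedInputError,
    ZeroVarianceError,
)

POSITIVE_LABEL = "insufficient"
NEGATIVE_LABEL = "sufficient"

CHAN_VERY_STRONG = "very strong"
CHAN_MODERATELY_STRONG = "moderately strong"
CHAN_FAIR = "fair"
CHAN_POOR = "poor"
CHAN_UNCLASSIFIED = "unclassified"


@dataclass
class KSResult:
    d_statistic: float
    p_value: float
    n_pairs: int
    n_permutations: int
    seed: int
    p_asymptotic: float  # classical unpaired two-sample KS p, for reference


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    chan_label: str


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    positive_label_is_insufficient: bool = True


def zscore(values) -> np.ndarray:
    """Standardize a series to mean 0 and sample SD 1 (ddof=1)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ZeroVarianceError("zero variance: need at least 2 values")
    sd = np.std(values, ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero variance: constant input")
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# Paired Kolmogorov–Smirnov
# ---------------------------------------------------------------------------


def _ks_machinery(x: np.ndarray, y: np.ndarray):
    """Precompute the evaluation grid for fast KS statistics under swaps.

    The pooled value multiset is invariant under within-pair swaps, so the
    sup over ECDF differences can be evaluated on a fixed grid. With cx(t)
    the number of x-sample values ≤ t, D = max_t |2·cx(t) − tot(t)| / n.
    """
    n = x.size
    pooled = np.sort(np.concatenate([x, y]))
    ix = (x[:, None] <= pooled[None, :]).astype(np.float64)  # n × 2n
    iy = (y[:, None] <= pooled[None, :]).astype(np.float64)
    base = ix.sum(axis=0)
    diff = iy - ix
    tot = base + iy.sum(axis=0)

    def d_for_swaps(swaps: np.ndarray) -> np.ndarray:
        # swaps: B × n boolean; True means pair i contributes y to sample 1
        cx = base[None, :] + swaps.astype(np.float64) @ diff
        return np.max(np.abs(2.0 * cx - tot[None, :]), axis=1) / n

    return d_for_swaps


def paired_ks_test(x, y, n_permutations: int = 9999, seed: int = 0) -> KSResult:
    """Two-sample KS test modified for paired data.

    D is the classical sup-difference of the two ECDFs. The p-value comes
    from a permutation null that independently swaps x_i ↔ y_i within each
    pair (the exchangeability null for paired samples), using the add-one
    estimator p = (1 + #{D_perm ≥ D_obs}) / (1 + n_permutations). The
    classical asymptotic unpaired p is reported alongside for reference.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise UnpairedInputError("unpaired input: x and y must be 1-D series of equal length")
    if x.size < 3:
        raise UnpairedInputError("unpaired input: need at least 3 pairs")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    d_for_swaps = _ks_machinery(x, y)
    d_obs = float(d_for_swaps(np.zeros((1, x.size), dtype=bool))[0])

    rng = np.random.default_rng(seed)
    swaps = rng.random((n_permutations, x.size)) < 0.5
    d_perm = d_for_swaps(swaps)
    p = (1.0 + int(np.count_nonzero(d_perm >= d_obs))) / (1.0 + n_permutations)

    p_asym = float(sps.ks_2samp(x, y, method="asymp").pvalue)
    return KSResult(
        d_statistic=d_obs,
        p_value=float(p),
        n_pairs=int(x.size),
        n_permutations=int(n_permutations),
        seed=int(seed),
        p_asymptotic=p_asym,
    )


# ---------------------------------------------------------------------------
# Spearman correlation with Chan interpretation
# ---------------------------------------------------------------------------


def interpret_correlation(rho: float) -> str:
    """Chan's verbal scale applied to |rho|.

    ≥ 0.8 very strong; 0.6 up to 0.8 moderately strong; 0.3 to 0.5 fair;
    below 0.3 poor. The quoted scale leaves (0.5, 0.6) unmapped; such values
    are labeled "unclassified" rather than silently binned.
    """
    r = abs(float(rho))
    if r > 1:
        raise ValueError("|rho| must be <= 1")
    if r >= 0.8:
        return CHAN_VERY_STRONG
    if r >= 0.6:
        return CHAN_MODERATELY_STRONG
    if r > 0.5:
        return CHAN_UNCLASSIFIED
    if r >= 0.3:
        return CHAN_FAIR
    return CHAN_POOR


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise UnpairedInputError("unpaired input: series lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("undefined correlation: constant series")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    return CorrelationResult(
        rho=rho,
        p_value=float(res.pvalue),
        n=int(x.size),
        chan_label=interpret_correlation(rho),
    )


# ---------------------------------------------------------------------------
# ROC / AUC / Youden
# ---------------------------------------------------------------------------


def _delong_auc_ci(scores: np.ndarray, positive: np.ndarray) -> tuple[float, tuple[float, float]]:
    """AUC (midrank / Mann–Whitney form) with DeLong 95% CI."""
    pos = scores[positive]
    neg = scores[~positive]
    m, n = pos.size, neg.size
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_analysis(scores, labels) -> RocResult:
    """ROC of a noise score against sufficient/insufficient quality labels.

    Higher scores (more noise) are treated as evidence of insufficient
    quality, so positive class = "insufficient". A case is predicted
    positive iff score ≥ threshold. AUC is the empirical (trapezoidal) area;
    its 95% CI uses DeLong's method; the reported cutoff maximizes Youden's
    index (sensitivity + specificity − 1) over the observed thresholds.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise UnpairedInputError("unpaired input: scores and labels differ in length")
    if labels.dtype.kind in "bi":
        positive = labels.astype(bool)
    else:
        known = {POSITIVE_LABEL, NEGATIVE_LABEL}
        seen = set(np.unique(labels).tolist())
        if not seen <= known:
            raise ValueError(f"labels must be in {known}, got {seen}")
        positive = labels == POSITIVE_LABEL
    if positive.all() or not positive.any():
        raise DegenerateLabelsError("degenerate labels: both classes must be present")

    fpr, tpr, thresholds = roc_curve(positive.astype(int), scores)
    auc, ci = _delong_auc_ci(scores, positive)
    youden = tpr - fpr
    k = int(np.argmax(youden))  # thresholds are decreasing → highest cutoff among ties
    cutoff = float(thresholds[k])
    if not np.isfinite(cutoff):  # sklearn's sentinel above the max score
        cutoff = float(scores.max())
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_ci95=ci,
        youden_cutoff=cutoff,
        sens_at_cutoff=float(tpr[k]),
        spec_at_cutoff=float(1.0 - fpr[k]),
    )
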