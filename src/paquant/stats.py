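"""Nonparametric cohort statistics.

Group comparisons use the two-tailed Mann-Whitney U test (exact null
distribution for small tie-free samples, tie- and continuity-corrected
normal approximation otherwise), the Hodges-Lehmann shift estimate with a
confidence interval obtained by inverting the U test over the pairwise
differences, and ROC analysis in the "lower SO2 means malignant" direction.
The trapezoid AUC and the U statistic are two faces of the same concordance
count, and the implementation preserves that identity exactly.

Size-matched subgroup analysis enumerates every combination of per-bin case
selections, e.g. choosing 2 of 10 same-sized malignant tumours gives
C(10, 2) = 45 subgroups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ComparisonResult",
    "ROCResult",
    "SizeBin",
    "mann_whitney_u",
    "hodges_lehmann",
    "roc_lower_is_positive",
    "metrics_at_cutoff",
    "enumerate_size_matched_subgroups",
]

#: Largest n1*n2 for which the exact tie-free null distribution is used.
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison: U test plus Hodges-Lehmann shift estimate.

    ``estimate`` is median(a_i - b_j) in the units of the input samples;
    ``ci_low <= estimate <= ci_high`` always holds and both endpoints are
    elements of the pairwise-difference multiset.
    """

    groups: tuple
    n: tuple
    u_statistic: float
    p_value: float
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float


@dataclass(frozen=True)
class ROCResult:
    """ROC sweep for the rule "positive iff score <= threshold"."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    cutoff_metrics: dict  # cutoff -> (sensitivity, specificity)


def _clean(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise DataError("sample is empty after removing missing values")
    return a


@lru_cache(maxsize=64)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of tie-free arrangements with U statistic u.

    Recurrence N(u; m, n) = N(u - n; m-1, n) + N(u; m, n-1): the largest
    observation belongs either to the first sample (beating all n of the
    second) or to the second.  Counts stay below 2^53 for the cohort sizes
    this package meets, so float64 arithmetic is exact.
    """
    if n1 == 0 or n2 == 0:
        return np.ones(1)
    a = _u_null_counts(n1 - 1, n2)
    b = _u_null_counts(n1, n2 - 1)
    out = np.zeros(n1 * n2 + 1)
    out[n2 : n2 + a.size] += a
    out[: b.size] += b
    return out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple:
    """U = #(a_i > b_j) + 0.5 * #(a_i == b_j), via midranks."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size
    return u, has_ties, pooled


def mann_whitney_u(a, b) -> tuple:
    """Two-tailed Mann-Whitney U test.

    Returns ``(U, p)`` with U counting pairs where the first sample exceeds
    the second (ties at half weight).  The exact permutation distribution is
    used when the samples are tie-free and n1*n2 <= 10^4; otherwise a normal
    approximation with tie correction and continuity correction.
    """
    a, b = _clean(a), _clean(b)
    u, has_ties, pooled = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    if not has_ties and n1 * n2 <= EXACT_LIMIT:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        k = int(round(u))
        cdf = counts[: k + 1].sum() / total
        sf = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean_u = n1 * n2 / 2.0
        N = n1 + n2
        _, t = np.unique(pooled, return_counts=True)
        tie_term = (t**3 - t).sum() / (N * (N - 1.0))
        var_u = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
        if var_u <= 0:
            return u, 1.0
        z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)  # continuity-corrected
        p = min(1.0, 2.0 * norm.sf(max(z, 0.0)))
    return u, float(p)


def _ci_rank(n1: int, n2: int, alpha: float) -> int:
    """Largest k with P(U <= k) <= alpha/2 under the exact tie-free null;
    -1 when even U = 0 is too likely (the CI then spans all differences)."""
    if n1 * n2 <= EXACT_LIMIT:
        counts = _u_null_counts(n1, n2)
        cdf = np.cumsum(counts) / counts.sum()
        ks = np.nonzero(cdf <= alpha / 2.0)[0]
        return int(ks[-1]) if ks.size else -1
    mean_u = n1 * n2 / 2.0
    sd_u = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return int(np.floor(mean_u - norm.isf(alpha / 2.0) * sd_u - 0.5))


def hodges_lehmann(a, b, confidence: float = 0.95, groups=("a", "b")) -> ComparisonResult:
    """Hodges-Lehmann estimate of the shift between two samples, with CI.

    The estimate is the median of all n1*n2 pairwise differences a_i - b_j.
    The confidence interval inverts the Mann-Whitney test: its endpoints are
    the order statistics of the pairwise differences at the exact critical
    ranks, so nominal coverage is >= the requested level and the interval is
    distribution-free.
    """
    if not 0.0 < confidence < 1.0:
        raise ConfigurationError("confidence must lie in (0, 1)")
    a, b = _clean(a), _clean(b)
    u, p = mann_whitney_u(a, b)
    diffs = np.sort(np.subtract.outer(a, b).ravel())
    estimate = float(np.median(diffs))
    N = diffs.size
    k = _ci_rank(a.size, b.size, 1.0 - confidence)
    # CI = [D_(k+1), D_(N-k)] in 1-indexed order statistics, clamped to the
    # observed difference range when k = -1 (all-differences interval).
    lo = float(diffs[min(max(k, 0), N - 1)])
    hi = float(diffs[max(min(N - k - 1, N - 1), 0)])
    return ComparisonResult(
        groups=tuple(groups),
        n=(a.size, b.size),
        u_statistic=u,
        p_value=p,
        estimate=estimate,
        ci_low=lo,
        ci_high=hi,
        confidence=confidence,
    )


def _split_scores(scores, labels) -> tuple:
    s = np.asarray(scores, dtype=float).ravel()
    lab = np.asarray(labels).ravel().astype(bool)
    if s.shape != lab.shape:
        raise DataError("scores and labels must align")
    keep = np.isfinite(s)
    s, lab = s[keep], lab[keep]
    pos, neg = s[lab], s[~lab]
    if pos.size == 0 or neg.size == 0:
        raise DataError("both classes must be present")
    return pos, neg


def roc_lower_is_positive(scores, labels, cutoffs=()) -> ROCResult:
    """ROC curve with "low score calls the case positive (malignant)".

    Thresholds sweep -inf plus every distinct score; sensitivity is the
    positive fraction at or below threshold, specificity the negative
    fraction above it.  The trapezoid AUC equals the pairwise concordance
    P(pos < neg) + 0.5 P(pos = neg) — identically, not approximately.
    """
    pos, neg = _split_scores(scores, labels)
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    sens = np.array([np.mean(pos <= t) for t in thresholds])
    spec = np.array([np.mean(neg > t) for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    youden = thresholds[int(np.argmax(sens + spec - 1.0))]
    metrics = {float(c): metrics_at_cutoff(scores, labels, c) for c in cutoffs}
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_cutoff=float(youden),
        cutoff_metrics=metrics,
    )


def metrics_at_cutoff(scores, labels, cutoff: float) -> tuple:
    """(sensitivity, specificity) of the rule "positive iff score <= cutoff"."""
    pos, neg = _split_scores(scores, labels)
    return float(np.mean(pos <= cutoff)), float(np.mean(neg > cutoff))


@dataclass(frozen=True)
class SizeBin:
    """A tumour-size stratum with a selection quota.

    Cases of ``group`` whose size lies in [size_min, size_max] (inclusive)
    are eligible; each subgroup draws exactly ``quota`` of them.
    """

    group: str
    size_min: float
    size_max: float
    quota: int
    label: str = ""

    def __post_init__(self):
        if self.quota < 0:
            raise ConfigurationError("quota must be >= 0")
        if self.size_max < self.size_min:
            raise ConfigurationError("size_max must be >= size_min")


def enumerate_size_matched_subgroups(cohort: pd.DataFrame, bins) -> list:
    """All distinct subgroups formed by per-bin combinations of cases.

    ``cohort`` needs columns ``case_id``, ``group`` and a size column
    (``size_mm`` or ``size_cm``).  The result is the Cartesian product of
    per-bin C(available, quota) combinations, each subgroup a sorted tuple of
    case ids, emitted in deterministic lexicographic order.
    """
    size_col = "size_mm" if "size_mm" in cohort.columns else "size_cm"
    if size_col not in cohort.columns:
        raise DataError("cohort needs a size_mm or size_cm column")
    pools = []
    for b in bins:
        members = sorted(
            cohort.loc[
                (cohort["group"] == b.group)
                & (cohort[size_col] >= b.size_min)
                & (cohort[size_col] <= b.size_max),
                "case_id",
            ]
        )
        if b.quota > len(members):
            raise ConfigurationError(
                f"bin {b.label or (b.group, b.size_min, b.size_max)} asks for "
                f"{b.quota} cases but only {len(members)} are available"
            )
        pools.append(list(itertools.combinations(members, b.quota)))
    return [
        tuple(sorted(itertools.chain.from_iterable(combo)))
        for combo in itertools.product(*pools)
    ]
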