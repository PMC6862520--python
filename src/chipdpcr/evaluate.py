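"""Validation statistics for the screening assay.

Covers the study-design statistics applied to simulated cohorts and dilution
series: Mann-Whitney U comparison of euploid vs aneuploid ratio
distributions, ROC analysis of the dosage ratio as a classifier with a
bootstrap confidence interval on the AUROC, ordinary least-squares
regression of observed against theoretical mixture ratios, and the
mosaicism detection limit (smallest trisomic fraction whose mean ratio
clears the per-chromosome cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "DilutionSeriesResult",
    "TrisomyEvaluation",
    "CohortEvaluation",
    "mann_whitney_u",
    "auroc",
    "roc_points",
    "linear_fit",
    "detection_limit",
    "analyze_dilution_series",
    "cohort_summary",
]


@dataclass(frozen=True)
class DilutionSeriesResult:
    """Regression and detection-limit summary of one trisomy dilution series."""

    trisomy_chrom: str
    fractions: Tuple[float, ...]
    mean_ratios: Tuple[float, ...]
    ci_low: Tuple[float, ...]
    ci_high: Tuple[float, ...]
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    detection_limit_fraction: Optional[float]


@dataclass(frozen=True)
class TrisomyEvaluation:
    """Separation statistics for one trisomy against the euploid group."""

    chromosome: str
    n_aneuploid: int
    n_euploid: int
    mannwhitney_u: float
    p_two_sided: float
    auroc: float
    auroc_ci: Tuple[float, float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class CohortEvaluation:
    per_trisomy: Dict[str, TrisomyEvaluation]
    threshold: float


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U of group ``a`` versus ``b`` with a two-sided p-value.

    Uses exact enumeration when the smaller group has at most 8 observations
    and there are no ties, and the normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def auroc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> Tuple[float, float, float]:
    """Area under the ROC curve with a percentile-bootstrap 95% interval.

    The point estimate is the pair-ordering probability: the fraction of
    (positive, negative) score pairs ranked correctly, ties counting one
    half.  The interval resamples the cohort with replacement ``n_boot``
    times and takes the 2.5th/97.5th percentiles.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    point = _pair_ordering_auc(scores, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scores.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ls = labels[idx]
        if ls.min() == ls.max():  # degenerate resample: skip
            continue
        boots.append(_pair_ordering_auc(scores[idx], ls))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def _pair_ordering_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via midranks: U of the positive group over n_pos * n_neg pairs."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    u_pos = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u_pos / (n_pos * n_neg))


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> List[Tuple[float, float]]:
    """ROC curve as (false-positive rate, true-positive rate) pairs.

    One point per distinct threshold, monotone from (0, 0) to (1, 1); the
    trapezoidal integral of these points equals the AUROC point estimate.
    """
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist()))


def linear_fit(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, pearson_r, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: degenerate fit")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.rvalue**2)


def detection_limit(
    fractions: Sequence[float],
    ratio_replicates: Sequence[Sequence[float]],
    cutoff: float,
    use_ci_lower: bool = False,
    level: float = 0.95,
) -> Optional[float]:
    """Smallest mixture fraction reliably called aneuploid at ``cutoff``.

    Returns the smallest grid fraction whose mean replicate ratio (and, with
    ``use_ci_lower``, whose t-interval lower bound) exceeds the cutoff with
    every larger fraction also exceeding it; None if no fraction qualifies.
    """
    fractions = list(fractions)
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    exceeds = []
    for reps in ratio_replicates:
        reps = np.asarray(reps, dtype=float)
        crit = reps.mean()
        if use_ci_lower and reps.size > 1:
            half = stats.t.ppf(0.5 + level / 2, reps.size - 1) * stats.sem(reps)
            crit = reps.mean() - half
        exceeds.append(crit > cutoff)
    limit = None
    for f, ok in zip(reversed(fractions), reversed(exceeds)):
        if not ok:
            break
        limit = f
    return limit


def analyze_dilution_series(
    trisomy_chrom: str,
    fractions: Sequence[float],
    ratio_replicates: Sequence[Sequence[float]],
    cutoff: float,
    use_ci_lower: bool = False,
) -> DilutionSeriesResult:
    """Regress observed mean ratios on theoretical ratios and locate the detection limit.

    Theoretical ratios are ``1 + f/2``; replicates are averaged per fraction
    before the fit (mirroring technical-duplicate averaging), with a
    per-fraction t-interval on the mean.
    """
    fractions = list(fractions)
    means, lows, highs = [], [], []
    for reps in ratio_replicates:
        reps = np.asarray(reps, dtype=float)
        m = reps.mean()
        if reps.size > 1 and np.ptp(reps) > 0:
            half = stats.t.ppf(0.975, reps.size - 1) * stats.sem(reps)
        else:
            half = 0.0
        means.append(float(m))
        lows.append(float(m - half))
        highs.append(float(m + half))
    theory = [1.0 + f / 2.0 for f in fractions]
    slope, intercept, r, r2 = linear_fit(theory, means)
    limit = detection_limit(fractions, ratio_replicates, cutoff, use_ci_lower)
    return DilutionSeriesResult(
        trisomy_chrom=trisomy_chrom,
        fractions=tuple(fractions),
        mean_ratios=tuple(means),
        ci_low=tuple(lows),
        ci_high=tuple(highs),
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        r_squared=r2,
        detection_limit_fraction=limit,
    )


def cohort_summary(
    sample_scores: Mapping[str, Mapping[str, float]],
    truth: Mapping[str, str],
    threshold: float = 1.15,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> CohortEvaluation:
    """Per-trisomy diagnostic performance over a labelled cohort.

    ``sample_scores`` maps sample_id -> {chromosome -> mean dosage ratio};
    ``truth`` maps sample_id -> karyotype label (T13/T18/T21/...).  For each
    trisomy the aneuploid group is that trisomy's samples and the comparison
    group is every sample without an autosomal trisomy (euploid and
    sex-aberrant samples).  Sensitivity/specificity use ``ratio >= threshold``
    as the positive call.
    """
    missing = [s for s in sample_scores if s not in truth]
    if missing:
        raise ValueError(f"samples without truth labels: {missing[:5]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trisomy_labels = {"13": "T13", "18": "T18", "21": "T21"}
    non_trisomic = {
        s for s, lab in truth.items()
        if lab not in trisomy_labels.values() and s in sample_scores
    }
    per: Dict[str, TrisomyEvaluation] = {}
    for chrom, label in trisomy_labels.items():
        pos_ids = [s for s in sample_scores if truth[s] == label]
        neg_ids = sorted(non_trisomic)
        if not pos_ids or not neg_ids:
            continue
        pos = [sample_scores[s][chrom] for s in pos_ids]
        neg = [sample_scores[s][chrom] for s in neg_ids]
        u, p = mann_whitney_u(pos, neg)
        scores = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        auc, lo, hi = auroc(scores, labels, n_boot=n_boot, seed=rng)
        tp = sum(r >= threshold for r in pos)
        fn = len(pos) - tp
        fp = sum(r >= threshold for r in neg)
        tn = len(neg) - fp
        per[chrom] = TrisomyEvaluation(
            chromosome=chrom,
            n_aneuploid=len(pos),
            n_euploid=len(neg),
            mannwhitney_u=u,
            p_two_sided=p,
            auroc=auc,
            auroc_ci=(lo, hi),
            sensitivity=tp / len(pos) if pos else None,
            specificity=tn / len(neg) if neg else None,
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
        )
    return CohortEvaluation(per_trisomy=per, threshold=threshold)
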