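"""CV-gain statistics and linkage testing on conditioned residuals.

Cell-to-cell expression variability (the CV of corrected single-cell
fluorescence) declines with mean expression, so a raw CV difference between
strains can be a trivial consequence of a mean shift. The statistics here
remove that dependence:

* a linear reference model of CV versus mean is fitted on samples of a
  reference strain (``fit_cv_mean``);
* the *CV gain* of any sample is its observed CV minus the model
  prediction at its mean (``cv_gain``), tested for departure from zero by a
  one-tailed one-sample t-test (``gain_ttest``);
* linkage between a segregating locus and variability is tested by fitting
  CV ~ mean on *all* spores of a cross, taking the residuals as the
  quantitative trait, and comparing the two genotype groups with a
  Wilcoxon Mann-Whitney rank-sum test (``linkage_test``). The exact null
  distribution is enumerated when both groups have at most
  ``EXACT_GROUP_MAX`` spores; larger panels use the tie-corrected normal
  approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .cytometry import SampleStats

#: Largest per-group size for which the exact Mann-Whitney null is enumerated.
EXACT_GROUP_MAX = 10

DONOR = "donor"
RECIPIENT = "recipient"


@dataclass
class CVMeanModel:
    """Linear reference model ``cv = intercept + slope * mean``."""

    intercept: float
    slope: float
    n_fit: int
    reference: str = ""
    mean_range: tuple[float, float] = (float("-inf"), float("inf"))

    def predict(self, mean) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(mean, dtype=float)


@dataclass
class GainResult:
    """CV gains of a set of samples relative to a reference model."""

    gains: np.ndarray
    means: np.ndarray
    group: str = ""
    p_value: float | None = None


@dataclass
class LinkageResult:
    """Outcome of a rank-sum linkage test on conditioned CV residuals."""

    p_value: float
    u_statistic: float
    residuals_donor: np.ndarray
    residuals_recipient: np.ndarray
    method: str

    @property
    def median_difference(self) -> float:
        return float(
            np.median(self.residuals_donor) - np.median(self.residuals_recipient)
        )


def _extract(stats: Iterable[SampleStats]) -> tuple[np.ndarray, np.ndarray]:
    stats = list(stats)
    means = np.array([s.mean for s in stats], dtype=float)
    cvs = np.array([s.cv for s in stats], dtype=float)
    if not (np.isfinite(means).all() and np.isfinite(cvs).all()):
        raise ValueError("non-finite mean or CV among samples")
    return means, cvs


def fit_cv_mean(stats: Sequence[SampleStats], reference: str = "") -> CVMeanModel:
    """OLS fit of CV on mean over a set of reference samples."""
    means, cvs = _extract(stats)
    if len(means) < 2:
        raise ValueError("need >= 2 samples to fit a CV~mean model")
    if np.ptp(means) == 0.0:
        raise ValueError("all sample means identical: CV~mean fit is rank-deficient")
    design = np.column_stack([np.ones_like(means), means])
    (intercept, slope), *_ = np.linalg.lstsq(design, cvs, rcond=None)
    return CVMeanModel(
        intercept=float(intercept),
        slope=float(slope),
        n_fit=len(means),
        reference=reference,
        mean_range=(float(means.min()), float(means.max())),
    )


def cv_gain(
    stats: Sequence[SampleStats], model: CVMeanModel, group: str = ""
) -> GainResult:
    """Observed CV minus the CV predicted by the reference model.

    Samples whose mean lies outside the model's fitted range are still
    scored (extrapolation) but trigger a warning.
    """
    means, cvs = _extract(stats)
    lo, hi = model.mean_range
    outside = (means < lo) | (means > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} sample(s) outside the model's fitted mean range "
            f"[{lo:.4g}, {hi:.4g}]: gains are extrapolations",
            stacklevel=2,
        )
    gains = cvs - model.predict(means)
    return GainResult(gains=gains, means=means, group=group)


def gain_ttest(gains: Sequence[float], direction: str = "greater") -> float:
    """One-sample, one-tailed Student t-test of CV gains against zero."""
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    arr = np.asarray(gains, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 gains for a t-test")
    if np.ptp(arr) == 0.0 and arr[0] == 0.0:
        # all-zero gains: t = 0 by convention, one-tailed P = 0.5
        return 0.5
    if np.ptp(arr) == 0.0:
        raise ValueError("zero variance among gains: t-test undefined")
    res = sps.ttest_1samp(arr, popmean=0.0, alternative=direction)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Wilcoxon Mann-Whitney
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of group x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney P by enumeration of group assignments.

    Enumerates every C(n+m, n) split of the pooled (midranked) observations,
    so the null distribution is correct in the presence of ties. Returns
    ``(U, p)`` where U is the statistic of the first group and the two-sided
    P-value is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    total = math.comb(n + m, n)
    n_le = 0
    n_ge = 0
    offset = n * (n + 1) / 2.0
    eps = 1e-9
    for idx in combinations(range(n + m), n):
        u = float(ranks[list(idx)].sum() - offset)
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def mannwhitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney test: exact for small groups, else asymptotic.

    Returns ``(U, p, method)``. The exact path enumerates assignments
    (midranks, tie-safe) when both groups have <= EXACT_GROUP_MAX
    observations; otherwise the tie-corrected normal approximation with
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= EXACT_GROUP_MAX and len(y) <= EXACT_GROUP_MAX:
        u, p = mannwhitney_exact(x, y)
        return u, p, "exact"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def linkage_test(
    spore_stats: Sequence[SampleStats], genotypes: Sequence[str]
) -> LinkageResult:
    """Rank-sum linkage between a locus and conditioned CV residuals.

    CV is regressed on mean across *all* spores of the cross (not a
    reference subset); the residuals are the quantitative trait values,
    compared between donor- and recipient-genotype spores with a two-sided
    Wilcoxon Mann-Whitney test.
    """
    if len(spore_stats) != len(genotypes):
        raise ValueError("spore_stats and genotypes must align")
    if len(spore_stats) < 3:
        raise ValueError("need >= 3 spores for a linkage test")
    genotypes = [str(g) for g in genotypes]
    bad = set(genotypes) - {DONOR, RECIPIENT}
    if bad:
        raise ValueError(f"unknown genotype labels: {sorted(bad)}")
    is_donor = np.array([g == DONOR for g in genotypes])
    if not is_donor.any() or is_donor.all():
        raise ValueError("both genotype groups must be non-empty")

    model = fit_cv_mean(spore_stats, reference="all-spores")
    means, cvs = _extract(spore_stats)
    residuals = cvs - model.predict(means)
    res_d = residuals[is_donor]
    res_r = residuals[~is_donor]
    u, p, method = mannwhitney(res_d, res_r)
    return LinkageResult(
        p_value=p,
        u_statistic=u,
        residuals_donor=res_d,
        residuals_recipient=res_r,
        method=method,
    )


def classify_candidates(
    p_values: Sequence[float], alpha: float = 0.05, bonferroni: bool = False
) -> list[bool]:
    """Flag candidate loci with P below alpha.

    No multiple-testing correction is applied by default; ``bonferroni``
    divides alpha by the number of tests.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("P-values must lie in [0, 1]")
    threshold = alpha / arr.size if (bonferroni and arr.size) else alpha
    return [bool(p < threshold) for p in arr]


def additivity_gap(
    individual_gains: Sequence[float], combined_gain: float
) -> float:
    """Combined-locus CV gain minus the sum of single-locus gains.

    A value near zero indicates approximately additive locus effects.
    """
    arr = np.asarray(list(individual_gains), dtype=float)
    if arr.size < 1:
        raise ValueError("need >= 1 individual gain")
    return float(combined_gain - arr.sum())
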