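"""Resampling statistics for paired song-variability comparisons.

The study design is within-bird: each bird contributes one value per
condition (e.g. motif stereotypy after two hours of non-singing vs after
two hours of undirected singing), and inference is on the per-bird
differences.  Because song scores are not credibly Gaussian, the primary
test is a sign-flip randomization of the paired differences:

1. The test statistic M is the group mean of the per-bird differences.
2. Each iteration multiplies the difference vector elementwise by
   independent uniform +/-1 draws and records the mean, building the null
   distribution of M under "direction of each bird's difference is
   random".
3. The two-tailed p-value is the fraction of null Ms at least as far from
   the null-distribution mean as the observed M (the observed M and its
   reflection across the null mean are the critical values); counting is
   inclusive at the critical values.

A permutation one-way ANOVA on absolute deviations (between-group over
within-group absolute distances from the group/grand means) decides
whether bird or syllable is the right unit of analysis, a Wilcoxon
signed-rank test cross-checks significance calls, and a Monte-Carlo power
analysis resamples the observed differences to estimate power at
prospective sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "BootstrapTestResult",
    "GroupedSample",
    "AnovaResult",
    "PowerEstimate",
    "paired_signflip_bootstrap",
    "bootstrap_oneway_anova",
    "abs_deviation_statistic",
    "wilcoxon_crosscheck",
    "power_simulation",
]


@dataclass
class PairedSample:
    """Per-unit paired differences for one measure (UD-UD minus NS-UD)."""

    differences: np.ndarray
    unit_ids: Optional[list] = None
    measure: str = ""

    def __post_init__(self) -> None:
        self.differences = np.asarray(self.differences, dtype=float)
        if self.differences.ndim != 1 or len(self.differences) < 2:
            raise ValueError("need a 1-D vector of >= 2 paired differences")
        if self.unit_ids is not None and len(self.unit_ids) != len(self.differences):
            raise ValueError("one difference per unit required")

    @classmethod
    def from_conditions(cls, ns_values, ud_values, unit_ids=None, measure: str = ""):
        ns = np.asarray(ns_values, dtype=float)
        ud = np.asarray(ud_values, dtype=float)
        if ns.shape != ud.shape:
            raise ValueError("condition vectors must have equal length")
        return cls(differences=ud - ns, unit_ids=unit_ids, measure=measure)

    @property
    def n(self) -> int:
        return len(self.differences)


@dataclass
class BootstrapTestResult:
    m_observed: float
    null_mean: float
    p_value: float
    n_iter: int
    seed: Optional[int]
    alpha: float
    measure: str = ""
    null_ms: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def paired_signflip_bootstrap(
    sample: PairedSample,
    n_iter: int = 10_000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    keep_null: bool = True,
) -> BootstrapTestResult:
    """Two-tailed sign-flip randomization test on paired differences.

    Each of ``n_iter`` iterations multiplies the difference vector by an
    independent vector of uniform +/-1 signs and records the mean; the
    p-value is the inclusive fraction of null means at least as far from
    the empirical null mean as the observed mean M.

    A degenerate all-zero difference vector gives a point-mass null and
    p = 1 (with a warning).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    d = sample.differences
    m_obs = float(d.mean())
    rng = np.random.default_rng(seed)
    if np.all(d == 0):
        warnings.warn(
            "all paired differences are zero: degenerate null, p = 1",
            stacklevel=2,
        )
        null = np.zeros(n_iter)
        return BootstrapTestResult(
            m_observed=m_obs,
            null_mean=0.0,
            p_value=1.0,
            n_iter=n_iter,
            seed=seed,
            alpha=alpha,
            measure=sample.measure,
            null_ms=null if keep_null else None,
        )
    signs = rng.choice((-1.0, 1.0), size=(n_iter, sample.n))
    null = (signs * d).mean(axis=1)
    null_mean = float(null.mean())
    # Critical values are M and its reflection across the null-distribution
    # center.  The sign-flip null mean is exactly 0 by construction, so the
    # reflection uses that exact center rather than its Monte-Carlo estimate:
    # with the estimated center, the tie at the mirrored critical value
    # (the all-flipped sign vector, probability 2^-n) is broken by sampling
    # jitter and the p-value would not converge to the exhaustive 2^n test.
    # Counting is inclusive at both critical values.
    p = float(np.mean(np.abs(null) >= abs(m_obs)))
    return BootstrapTestResult(
        m_observed=m_obs,
        null_mean=null_mean,
        p_value=p,
        n_iter=n_iter,
        seed=seed,
        alpha=alpha,
        measure=sample.measure,
        null_ms=null if keep_null else None,
    )


@dataclass
class GroupedSample:
    """Values with group labels, for the one-way permutation ANOVA."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape != self.labels.shape or self.values.ndim != 1:
            raise ValueError("values and labels must be equal-length 1-D")
        uniq, counts = np.unique(self.labels, return_counts=True)
        if len(uniq) < 2:
            raise ValueError("need at least 2 groups")
        if (counts < 1).any():
            raise ValueError("every group must be non-empty")
        if len(self.values) < len(uniq) + 1:
            raise ValueError("total n must exceed the number of groups")

    @property
    def k(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class AnovaResult:
    statistic: float
    p_value: float
    n_iter: int
    seed: Optional[int]
    k_groups: int


def abs_deviation_statistic(
    values: np.ndarray, labels: np.ndarray, weighted: bool = True
) -> float:
    """Between/within variability ratio from absolute deviations.

    ``[sum_g n_g * |mean_g - grand_mean|] / [sum_g sum_i |x_gi - mean_g|]``
    — the absolute-deviation analogue of the F ratio.  With
    ``weighted=False`` the between term drops the group-size weights.
    Zero within-group variability makes the statistic infinite (or 0 when
    the between term is also zero).
    """
    grand = values.mean()
    between = 0.0
    within = 0.0
    for g in np.unique(labels):
        gv = values[labels == g]
        gm = gv.mean()
        between += (len(gv) if weighted else 1.0) * abs(gm - grand)
        within += np.abs(gv - gm).sum()
    if within == 0:
        return 0.0 if between == 0 else float("inf")
    return float(between / within)


def bootstrap_oneway_anova(
    sample: GroupedSample,
    n_iter: int = 10_000,
    seed: Optional[int] = None,
    weighted: bool = True,
) -> AnovaResult:
    """Permutation one-way ANOVA on absolute deviations.

    The null distribution is generated by randomly permuting group labels
    (without replacement) ``n_iter`` times; the p-value is the inclusive
    fraction of null statistics at least as large as the observed one.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    obs = abs_deviation_statistic(sample.values, sample.labels, weighted=weighted)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    labels = sample.labels.copy()
    for i in range(n_iter):
        rng.shuffle(labels)
        null[i] = abs_deviation_statistic(sample.values, labels, weighted=weighted)
    p = float(np.mean(null >= obs))
    return AnovaResult(
        statistic=obs, p_value=p, n_iter=n_iter, seed=seed, k_groups=sample.k
    )


def wilcoxon_crosscheck(sample: PairedSample) -> float:
    """Two-tailed Wilcoxon signed-rank p-value on the paired differences.

    Used only to cross-flag significance of the sign-flip bootstrap at the
    0.05 level.  All-zero differences leave the test undefined; NaN is
    returned with a warning.
    """
    d = sample.differences
    if np.all(d == 0):
        warnings.warn("Wilcoxon undefined for all-zero differences", stacklevel=2)
        return float("nan")
    res = sps.wilcoxon(d, alternative="two-sided")
    return float(res.pvalue)


@dataclass
class PowerEstimate:
    power: float
    n_prospective: int
    alpha: float
    n_outer: int
    n_inner: int
    seed: Optional[int]
    measure: str = ""


def power_simulation(
    sample: PairedSample,
    n_prospective: int,
    alpha: float = 0.05,
    n_outer: int = 1000,
    n_inner: int = 2000,
    seed: Optional[int] = None,
    parametric: bool = False,
) -> PowerEstimate:
    """Monte-Carlo power of the sign-flip test at a prospective n.

    Each of ``n_outer`` replicates draws ``n_prospective`` differences —
    with replacement from the observed difference vector (default), or
    from a Gaussian with the observed mean and SD (``parametric=True``) —
    runs the sign-flip bootstrap with ``n_inner`` iterations, and records
    whether p < alpha.  Power is the significant fraction.  Power reflects
    the within-group variability, the between-condition difference, and n.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("n_outer and n_inner must be >= 1")
    if n_prospective < 2:
        raise ValueError("n_prospective must be >= 2")
    d = sample.differences
    rng = np.random.default_rng(seed)
    hits = 0
    mu, sd = d.mean(), d.std(ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate resamples count as p=1
        for _ in range(n_outer):
            if parametric:
                draw = rng.normal(mu, sd, size=n_prospective)
            else:
                draw = rng.choice(d, size=n_prospective, replace=True)
            res = paired_signflip_bootstrap(
                PairedSample(draw),
                n_iter=n_inner,
                seed=int(rng.integers(2**31)),
                alpha=alpha,
                keep_null=False,
            )
            hits += res.p_value < alpha
    return PowerEstimate(
        power=hits / n_outer,
        n_prospective=n_prospective,
        alpha=alpha,
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
        measure=sample.measure,
    )
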