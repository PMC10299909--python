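"""Resampling and rank statistics for simulation group comparisons.

Two tools, matching how the simulation results are summarized: a seeded
percentile bootstrap of the mean (default 68% interval) and the two-sided
Mann-Whitney U test with an exact small-sample path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = [
    "GroupSample",
    "BootstrapCI",
    "MannWhitneyResult",
    "bootstrap_ci",
    "mann_whitney_u",
    "exact_u_distribution",
]

EXACT_MAX_PRODUCT = 400  # exact enumeration when n_a * n_b <= this and no ties


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValidationError("GroupSample needs >= 1 value")
        if not all(math.isfinite(v) for v in self.values):
            raise ValidationError("GroupSample values must be finite")


@dataclass
class BootstrapCI:
    mean: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float
    method: str  # "exact" | "normal_approx"
    alternative: str


def _values(sample) -> np.ndarray:
    if isinstance(sample, GroupSample):
        return np.asarray(sample.values, dtype=float)
    v = np.asarray(sample, dtype=float)
    if v.size == 0:
        raise ValidationError("empty sample")
    if not np.all(np.isfinite(v)):
        raise ValidationError("sample values must be finite")
    return v


def bootstrap_ci(values, level: float = 0.68, n_boot: int = 10000, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap interval of the mean.

    The reported mean is the plain sample mean; the interval is the
    (1-level)/2 and (1+level)/2 percentiles of ``n_boot`` resampled means,
    drawn from a generator seeded with ``seed`` (bit-reproducible).
    """
    v = _values(values)
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    boot_means = v[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [50 * (1 - level), 50 * (1 + level)])
    return BootstrapCI(
        mean=float(v.mean()), ci_low=float(lo), ci_high=float(hi),
        level=level, n_boot=n_boot, seed=seed,
    )


def exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of arrangements for each U value in 0..n1*n2 under the null.

    Dynamic program over the generating function of the Mann-Whitney
    statistic; total mass is C(n1+n2, n1).
    """
    size = n1 * n2 + 1
    # recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)
    cur = [np.zeros(size) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        cur[j][0] = 1.0  # i = 0
    for _ in range(n1):
        new = [np.zeros(size) for _ in range(n2 + 1)]
        new[0][0] = 1.0
        for j in range(1, n2 + 1):
            shifted = np.zeros(size)
            shifted[j:] = cur[j][: size - j]
            new[j] = shifted + new[j - 1]
        cur = new
    return cur[n2]


def mann_whitney_u(a, b, alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann-Whitney U with midranks.

    Exact p by enumeration when n_a*n_b <= 400 and there are no ties across
    the pooled sample; otherwise the normal approximation with tie and
    continuity corrections. The method used is recorded in the result.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError("alternative must be 'two-sided', 'less' or 'greater'")
    va, vb = _values(a), _values(b)
    n1, n2 = va.size, vb.size
    pooled = np.concatenate([va, vb])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n1 * n2 <= EXACT_MAX_PRODUCT:
        counts = exact_u_distribution(n1, n2)
        total = counts.sum()
        u_int = int(round(u1))
        cdf_le = counts[: u_int + 1].sum() / total
        cdf_ge = counts[u_int:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
        elif alternative == "greater":
            p = cdf_ge
        else:
            p = cdf_le
        return MannWhitneyResult(u=u1, p=float(p), method="exact", alternative=alternative)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(sigma2) if sigma2 > 0 else 0.0
    if sigma == 0:
        # all pooled values identical: no evidence either way
        p = 1.0
    else:
        from scipy.stats import norm

        def sf(u):
            return norm.sf((u - mu - 0.5) / sigma)

        def cdf(u):
            return norm.cdf((u - mu + 0.5) / sigma)

        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(sf(u1), cdf(u1)))
        elif alternative == "greater":
            p = sf(u1)
        else:
            p = cdf(u1)
    return MannWhitneyResult(u=u1, p=float(p), method="normal_approx", alternative=alternative)
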