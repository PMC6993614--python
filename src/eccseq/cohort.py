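"""Descriptive statistics, group comparisons and Monte-Carlo power.

Medians describe eccDNA counts (the underlying distribution is unknown);
group differences use the Mann-Whitney U test; headline fold-changes are
ratios of group medians.  Post-hoc power assumes each group is normal with
the observed sample mean and (n-1) variance, redraws both groups many
times and counts how often the Mann-Whitney test rejects at alpha.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: joint sample size at or below which the exact Mann-Whitney branch is used
EXACT_MW_LIMIT = 20


@dataclass(frozen=True)
class DescriptiveStats:
    median: float
    mean: float
    sd: float


def median(values: Sequence[float]) -> float:
    """Exact median (midpoint of the two central order statistics for even n)."""
    if len(values) == 0:
        raise ValueError("empty input")
    return float(np.median(values))


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator)."""
    if len(values) < 2:
        raise ValueError("sd undefined for n < 2")
    return float(np.std(values, ddof=1))


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Median, mean and sample SD; raises for empty input or n < 2 (SD)."""
    return DescriptiveStats(
        median=median(values),
        mean=float(np.mean(values)),
        sd=sample_sd(values),
    )


def mann_whitney(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (of the first sample) and p-value.

    Exact p for small joint samples (n1 + n2 <= 20, no ties), otherwise the
    normal approximation with tie and continuity correction.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    joint = list(a) + list(b)
    ties = len(set(joint)) < len(joint)
    method = "exact" if (len(joint) <= EXACT_MW_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def fold_change(median_a: float, median_b: float) -> float:
    """Ratio of medians; see :func:`headline_fold` for the integer headline."""
    if median_b <= 0:
        raise ValueError("denominator median must be > 0")
    return median_a / median_b


def headline_fold(median_a: float, median_b: float) -> int:
    """Integer fold-change, rounded half away from zero (8.88 -> 9)."""
    ratio = fold_change(median_a, median_b)
    return int(math.floor(abs(ratio) + 0.5)) * (1 if ratio >= 0 else -1)


def significance_stars(p: float) -> str:
    """Report-style stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# exact Mann-Whitney null distribution (used by the power simulation)


@lru_cache(maxsize=64)
def exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of U over 0..n1*n2 (no ties), by the standard recursion."""
    prev = [np.array([1.0]) for _ in range(n2 + 1)]  # i = 0 row: U = 0 only
    for i in range(1, n1 + 1):
        cur: list[np.ndarray] = []
        for j in range(n2 + 1):
            arr = np.zeros(i * j + 1)
            if j == 0:
                arr[0] = 1.0
            else:
                a = prev[j]       # f(i-1, j, u - j)
                b = cur[j - 1]    # f(i, j-1, u)
                arr[j:j + len(a)] += a
                arr[: len(b)] += b
            cur.append(arr)
        prev = cur
    counts = prev[n2]
    return counts / counts.sum()


def exact_u_two_sided_p(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p-values for U statistics (vectorized, no ties)."""
    pmf = exact_u_pmf(n1, n2)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(U >= u)
    u = np.asarray(u, dtype=int)
    return np.minimum(1.0, 2.0 * np.minimum(cdf[u], sf[u]))


# ---------------------------------------------------------------------------
# post-hoc power


@dataclass(frozen=True)
class PowerSpec:
    """Two normal group models parameterized by sample moments."""

    mean1: float
    var1: float
    n1: int
    mean2: float
    var2: float
    n2: int
    alpha: float = 0.05
    rounds: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.var1 <= 0 or self.var2 <= 0:
            raise ValueError("variances must be > 0")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    power: float
    se: float          # Monte-Carlo standard error sqrt(p(1-p)/rounds)
    rounds: int

    def __float__(self) -> float:
        return self.power


def posthoc_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of the Mann-Whitney test under two normal groups.

    Each round draws both groups from their normal models and tests at
    ``alpha`` (two-sided).  P-values come from the exact U null
    distribution (continuous draws are tie-free almost surely); for very
    large groups the normal approximation is used instead.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n1, spec.n2
    x = rng.normal(spec.mean1, math.sqrt(spec.var1), size=(spec.rounds, n1))
    y = rng.normal(spec.mean2, math.sqrt(spec.var2), size=(spec.rounds, n2))
    ranks = sps.rankdata(np.concatenate([x, y], axis=1), axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n1 * n2 <= 10_000:
        p = exact_u_two_sided_p(np.rint(u1).astype(int), n1, n2)
    else:
        mu = n1 * n2 / 2.0
        sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (np.abs(u1 - mu) - 0.5) / sigma  # continuity-corrected
        p = 2.0 * sps.norm.sf(np.maximum(z, 0.0))
    power = float(np.mean(p < spec.alpha))
    se = math.sqrt(power * (1.0 - power) / spec.rounds)
    return PowerResult(power=power, se=se, rounds=spec.rounds)


# ---------------------------------------------------------------------------
# cohort table operations


def age_correlation(
    table, age_col: str = "age", value_col: str = "normalized_ecc"
) -> dict[str, float]:
    """Pearson and Spearman correlation of eccDNA count with age.

    Returns NaN coefficients (reported as undefined) for constant columns.
    """
    import pandas as pd

    df = pd.DataFrame(table)[[age_col, value_col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 samples with age and count")
    x, y = df[age_col].to_numpy(float), df[value_col].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        nan = math.nan
        return {"pearson_r": nan, "pearson_p": nan,
                "spearman_rho": nan, "spearman_p": nan, "n": len(df)}
    pr = sps.pearsonr(x, y)
    srho = sps.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_rho": float(srho.statistic), "spearman_p": float(srho.pvalue),
        "n": len(df),
    }


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    label_a: str = "group1",
    label_b: str = "group2",
    power: bool = False,
    rounds: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Medians, Mann-Whitney test, fold-change and optional post-hoc power."""
    med_a, med_b = median(values_a), median(values_b)
    u, p = mann_whitney(values_a, values_b)
    out = {
        "group_a": label_a, "group_b": label_b,
        "n_a": len(values_a), "n_b": len(values_b),
        "median_a": med_a, "median_b": med_b,
        "U": u, "p": p, "stars": significance_stars(p),
    }
    if med_b > 0:
        out["fold"] = fold_change(med_a, med_b)
        out["fold_headline"] = headline_fold(med_a, med_b)
    if power and len(values_a) >= 2 and len(values_b) >= 2:
        spec = PowerSpec(
            mean1=float(np.mean(values_a)), var1=float(np.var(values_a, ddof=1)),
            n1=len(values_a),
            mean2=float(np.mean(values_b)), var2=float(np.var(values_b, ddof=1)),
            n2=len(values_b),
            alpha=alpha, rounds=rounds, seed=seed,
        )
        res = posthoc_power(spec)
        out["power"] = res.power
        out["power_se"] = res.se
    return out
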