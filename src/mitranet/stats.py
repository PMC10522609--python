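"""Normality-driven group comparison helpers.

Two-group comparisons use an unpaired two-tailed Student's t-test when every
group passes a Kolmogorov-Smirnov normality check, and a Mann-Whitney U test
otherwise.  Three-or-more-group comparisons use one-way ANOVA with Tukey's
post hoc test, or Kruskal-Wallis with Dunn's post hoc test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "TestDescriptor",
    "ComparisonResult",
    "ks_is_normal",
    "choose_test",
    "compare_two",
    "compare_groups",
    "dunn_posthoc",
]

#: Minimum observations per group for the normality test to be meaningful.
MIN_N_FOR_NORMALITY = 3

#: Sample-size ceiling below which the Mann-Whitney U null is enumerated
#: exactly instead of using the normal approximation.
EXACT_MW_MAX_N = 25


@dataclass(frozen=True)
class TestDescriptor:
    """Which test family applies to a set of groups and why."""

    family: str  # "two-sample" | "multi-sample"
    parametric: bool
    name: str  # e.g. "t-test", "mann-whitney", "anova+tukey", "kruskal+dunn"
    warning: str | None = None


@dataclass
class ComparisonResult:
    descriptor: TestDescriptor
    p_value: float  # omnibus p (two-sample: the test p itself)
    statistic: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def ks_is_normal(values, alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    Uses the Lilliefors null distribution, the appropriate KS variant when
    the Gaussian mean and variance are fitted from the sample.  Degenerate
    samples (zero variance or fewer than ``MIN_N_FOR_NORMALITY`` points)
    are treated as non-normal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_N_FOR_NORMALITY:
        return False
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return False
    _, p = lilliefors(x, dist="norm")
    return bool(p >= alpha)


def choose_test(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TestDescriptor:
    """Select the comparison test for named groups of observations.

    Parametric tests are chosen only when *all* groups pass normality.
    Groups too small to test normality trigger a nonparametric fallback.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two observations")

    warning = None
    too_small = [k for k, a in arrays.items() if a.size < MIN_N_FOR_NORMALITY]
    if too_small:
        parametric = False
        warning = (
            f"groups too small for normality testing ({', '.join(too_small)}); "
            "falling back to nonparametric test"
        )
        warnings.warn(warning, stacklevel=2)
    else:
        parametric = all(ks_is_normal(a, alpha=alpha) for a in arrays.values())

    if len(arrays) == 2:
        name = "t-test" if parametric else "mann-whitney"
        return TestDescriptor("two-sample", parametric, name, warning)
    name = "anova+tukey" if parametric else "kruskal+dunn"
    return TestDescriptor("multi-sample", parametric, name, warning)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    # all-constant pooled data: identical distributions by convention
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2), 1.0
    method = "exact" if max(a.size, b.size) <= EXACT_MW_MAX_N else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exact-with-ties notice
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_two(values_a, values_b, method: str = "auto", alpha: float = 0.05) -> ComparisonResult:
    """Two-sided two-sample comparison.

    ``method`` is ``auto`` (normality-driven), ``t-test`` or ``mann-whitney``.
    Identical degenerate samples yield p = 1 by the exact-tie convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")

    if method == "auto":
        desc = choose_test({"A": a, "B": b}, alpha=alpha)
    elif method in ("t-test", "mann-whitney"):
        desc = TestDescriptor("two-sample", method == "t-test", method)
    else:
        raise ValueError(f"unknown method {method!r}")

    if desc.name == "t-test":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(p):  # both groups constant and equal
            stat, p = 0.0, 1.0
        return ComparisonResult(desc, float(p), float(stat))
    stat, p = _mannwhitney(a, b)
    return ComparisonResult(desc, p, stat)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's post hoc z-test on rank sums with tie correction.

    Returns two-sided, uncorrected p-values per group pair.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = ranks[start : start + arr.size].mean()
        sizes[name] = arr.size
        start += arr.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    out: dict[tuple[str, str], float] = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            var = base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj])
            if var <= 0:
                out[(gi, gj)] = 1.0
                continue
            z = (mean_ranks[gi] - mean_ranks[gj]) / np.sqrt(var)
            out[(gi, gj)] = float(2.0 * sps.norm.sf(abs(z)))
    return out


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = list(groups)
    res = sps.tukey_hsd(*(np.asarray(groups[k], dtype=float) for k in names))
    out = {}
    for i, gi in enumerate(names):
        for j in range(i + 1, len(names)):
            out[(gi, names[j])] = float(res.pvalue[i, j])
    return out


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonResult:
    """Compare two or more named groups with the selected test.

    For ≥3 groups the omnibus p is ANOVA or Kruskal-Wallis and ``pairwise``
    holds Tukey or Dunn post hoc p-values.
    """
    desc = choose_test(groups, alpha=alpha)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if desc.family == "two-sample":
        (a, b) = arrays.values()
        res = compare_two(a, b, method=desc.name, alpha=alpha)
        return ComparisonResult(desc, res.p_value, res.statistic, res.pairwise)

    samples = list(arrays.values())
    if desc.parametric:
        stat, p = sps.f_oneway(*samples)
        pairwise = _tukey_posthoc(arrays)
    else:
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            return ComparisonResult(desc, 1.0, 0.0, {})
        stat, p = sps.kruskal(*samples)
        pairwise = dunn_posthoc(arrays)
    return ComparisonResult(desc, float(p), float(stat), pairwise)
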