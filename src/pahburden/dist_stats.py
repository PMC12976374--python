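"""Distribution characterisation, exposed/unexposed clustering, rank tests.

The simulated exposure distribution is summarised by its range, percentiles,
Pearson kurtosis (fourth standardised moment m4/m2², equal to 3 for a
normal) and the fraction of strictly positive iterations.  Exposure
prevalence for the burden chain comes from an exact one-dimensional
two-means clustering: the within-cluster sum of squares is minimised over
all sorted-order cut points, which is the global optimum any converged
Lloyd run can at best reach, and removes initialisation sensitivity
entirely.  The nonparametric tests (Mann-Whitney U between clusters,
Shapiro-Wilk and Levene as assumption checks, Kruskal-Wallis across cooking
methods) wrap scipy.stats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .tds_data import ValidationError

__all__ = [
    "DistributionSummary",
    "ClusterResult",
    "TestResult",
    "summarize",
    "kmeans2",
    "lloyd_kmeans2",
    "mann_whitney_u",
    "shapiro_wilk",
    "levene",
    "kruskal_wallis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistributionSummary:
    """Summary of a simulated exposure distribution (mg/kg bw/d).

    ``kurtosis`` uses the Pearson convention (normal → 3);
    ``proportion_positive`` is the strictly-greater-than-zero fraction.
    """

    min: float
    max: float
    median: float
    p50: float
    p95: float
    kurtosis: float
    proportion_positive: float

    def to_dict(self) -> dict[str, float]:
        return {
            "min": self.min,
            "max": self.max,
            "median": self.median,
            "p50": self.p50,
            "p95": self.p95,
            "kurtosis": self.kurtosis,
            "proportion_positive": self.proportion_positive,
        }


@dataclass
class ClusterResult:
    """Exact 1-D two-means split of an exposure distribution.

    ``threshold`` separates the clusters (values strictly above it are
    exposed); ``prevalence`` is the exposed (higher-mean) cluster's share —
    the P_exposure input of the attributable-fraction formula.
    """

    threshold: float
    exposed: np.ndarray  # boolean, per input value
    means: tuple[float, float]  # (unexposed, exposed)
    prevalence: float

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.exposed, "exposed", "unexposed")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _values(dist) -> np.ndarray:
    vals = getattr(dist, "values", dist)
    return np.asarray(vals, dtype=float)


def summarize(dist) -> DistributionSummary:
    """Summarise an exposure distribution (or any vector of values).

    Percentiles use linear interpolation; kurtosis is the population-moment
    ratio m4/m2².  Requires at least 4 values and a non-degenerate spread
    (kurtosis is undefined when m2 = 0).
    """
    x = _values(dist)
    if x.size < 4:
        raise ValidationError(f"kurtosis needs >= 4 values, got {x.size}")
    m2 = float(np.mean((x - x.mean()) ** 2))
    if m2 == 0:
        raise ValidationError("kurtosis undefined for a constant vector (m2 = 0)")
    kurt = float(sps.kurtosis(x, fisher=False, bias=True))
    return DistributionSummary(
        min=float(x.min()),
        max=float(x.max()),
        median=float(np.median(x)),
        p50=float(np.percentile(x, 50)),
        p95=float(np.percentile(x, 95)),
        kurtosis=kurt,
        proportion_positive=float(np.mean(x > 0)),
    )


def kmeans2(values, seed: int | None = None) -> ClusterResult:
    """Exact two-means clustering of a 1-D sample.

    Minimises the within-cluster sum of squares over every cut point
    between distinct consecutive sorted values — the global optimum of the
    two-means objective restricted to threshold partitions, which in 1-D is
    the full optimum.  Deterministic; ``seed`` is accepted for interface
    symmetry with :func:`lloyd_kmeans2` but unused.
    """
    x = _values(values)
    n = x.size
    if n < 2:
        raise ValidationError("two-means needs >= 2 values")
    xs = np.sort(x)
    if xs[0] == xs[-1]:
        raise ValidationError("two-means undefined: all values identical")

    cs = np.cumsum(xs)
    cs2 = np.cumsum(xs * xs)
    k = np.arange(1, n)  # size of the low cluster
    left_ss = cs2[k - 1] - cs[k - 1] ** 2 / k
    right_sum = cs[-1] - cs[k - 1]
    right_ss = (cs2[-1] - cs2[k - 1]) - right_sum**2 / (n - k)
    wcss = left_ss + right_ss

    # Only cuts between distinct values are realisable by thresholding.
    distinct = xs[:-1] < xs[1:]
    wcss = np.where(distinct, wcss, np.inf)
    best = int(np.argmin(wcss)) + 1

    threshold = 0.5 * (xs[best - 1] + xs[best])
    exposed = x > threshold
    means = (float(x[~exposed].mean()), float(x[exposed].mean()))
    return ClusterResult(
        threshold=float(threshold),
        exposed=exposed,
        means=means,
        prevalence=float(exposed.mean()),
    )


def lloyd_kmeans2(values, seed: int = 0, n_init: int = 20) -> ClusterResult:
    """Multi-start Lloyd two-means (scikit-learn) — a cross-check for
    :func:`kmeans2`, retained because Lloyd's sensitivity to outliers and
    initialisation is a known caveat of k-means on skewed exposures."""
    from sklearn.cluster import KMeans

    x = _values(values)
    if x.size < 2 or np.min(x) == np.max(x):
        raise ValidationError("two-means needs >= 2 distinct values")
    km = KMeans(
        n_clusters=2, n_init=n_init, random_state=seed, tol=1e-12, max_iter=1000
    ).fit(x.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    high = int(np.argmax(centers))
    exposed = km.labels_ == high
    threshold = float(centers.mean())
    means = (float(x[~exposed].mean()), float(x[exposed].mean()))
    return ClusterResult(
        threshold=threshold,
        exposed=exposed,
        means=means,
        prevalence=float(exposed.mean()),
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (tie-corrected; normal approximation
    for large samples)."""
    x, y = _values(x), _values(y)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney needs two nonempty samples")
    method = "asymptotic" if x.size * y.size > 10_000 else "auto"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u")


def shapiro_wilk(x, max_n: int = 5000, seed: int = 0) -> TestResult:
    """Shapiro-Wilk normality test; inputs above ``max_n`` are subsampled
    without replacement (logged), since the statistic is defined for
    n ≤ 5000."""
    x = _values(x)
    if x.size > max_n:
        logger.info("shapiro-wilk: subsampling %d of %d values", max_n, x.size)
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
    if x.size < 3:
        raise ValidationError(f"Shapiro-Wilk needs n in [3, {max_n}], got {x.size}")
    if np.min(x) == np.max(x):
        raise ValidationError("Shapiro-Wilk undefined for constant input")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue), "shapiro-wilk")


def levene(x, y) -> TestResult:
    """Levene's test for equality of variances (two groups)."""
    x, y = _values(x), _values(y)
    if x.size < 2 or y.size < 2:
        raise ValidationError("Levene needs two samples of size >= 2")
    if np.min(x) == np.max(x) and np.min(y) == np.max(y):
        raise ValidationError("Levene undefined: both inputs constant")
    res = sps.levene(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), "levene")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p-value) across
    two or more groups."""
    arrays = [_values(g) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be nonempty")
    flat = np.concatenate(arrays)
    if np.min(flat) == np.max(flat):
        # All observations tied: no evidence of any difference.
        return TestResult(0.0, 1.0, "kruskal-wallis")
    res = sps.kruskal(*arrays)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis")
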