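"""Distance-binned enrichment profiles, Monte-Carlo slope envelopes and the
nearest-neighbor exclusion test.

The enrichment profile bins cells by signed distance to the DZ-LZ boundary
(default −100 μm on the DZ side to +100 μm on the LZ side, 10-μm bins) and
averages a per-cell value in each bin — by default a 0/1 subtype indicator,
so the bin mean is the subtype fraction.  An ordinary least-squares line
through the non-empty bin means (enrichment per μm) summarizes the spatial
trend.  Its significance is judged against a Monte-Carlo null in which the
subtype label is reassigned to a uniformly random subset of the observed
cell positions (count fixed), conditioning on tissue geometry: the observed
slope above / below / inside the [2.5, 97.5] percentile envelope of the
null slopes is called increasing / decreasing / random.

The exclusion test compares observed nearest-neighbor distances from point
set A to point set B against label-permuted controls with a two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .io import GCZoneError

logger = logging.getLogger(__name__)

TRENDS = ("increasing", "decreasing", "random")
DEFAULT_RANGE = (-100.0, 100.0)
DEFAULT_BIN_WIDTH = 10.0


# ---------------------------------------------------------------------------
# binning and slope
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentProfile:
    """Binned enrichment with optional slope fit and Monte-Carlo envelope."""

    bin_edges: np.ndarray            # nbins + 1
    bin_means: np.ndarray            # nbins, NaN where empty
    bin_n: np.ndarray                # cells per bin
    slope: float | None = None       # enrichment per μm
    intercept: float | None = None
    null_slopes: np.ndarray | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    trend: str | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "bin_means": [None if np.isnan(v) else float(v) for v in self.bin_means],
            "bin_n": self.bin_n.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "trend": self.trend,
        }


def _bin_index(distances, value_range, bin_width):
    """Half-open bins [edge, edge + width), last bin closed at the top edge.

    Returns (bin index array with -1 for out-of-range cells, edges).
    """
    lo, hi = value_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    nbins = len(edges) - 1
    d = np.asarray(distances, float)
    idx = np.floor((d - lo) / bin_width).astype(int)
    idx[d == hi] = nbins - 1  # closure of the last bin
    idx[(d < lo) | (d > hi)] = -1
    return idx, edges


def enrichment_profile(
    distances,
    values,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EnrichmentProfile:
    """Bin mean of ``values`` by signed distance; out-of-range cells excluded."""
    d = np.asarray(distances, float)
    v = np.asarray(values, float)
    if d.shape != v.shape:
        raise GCZoneError("distances and values must be aligned")
    idx, edges = _bin_index(d, value_range, bin_width)
    nbins = len(edges) - 1
    ok = idx >= 0
    if not ok.any():
        raise GCZoneError("no cell falls inside the distance range; all bins empty")
    bin_n = np.bincount(idx[ok], minlength=nbins)
    sums = np.bincount(idx[ok], weights=v[ok], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(bin_n > 0, sums / np.maximum(bin_n, 1), np.nan)
    return EnrichmentProfile(bin_edges=edges, bin_means=means, bin_n=bin_n)


def fit_slope(profile: EnrichmentProfile) -> tuple[float, float]:
    """Unweighted OLS of non-empty bin means on bin centers (per μm)."""
    ok = profile.bin_n > 0
    if ok.sum() < 2:
        raise GCZoneError("need at least 2 non-empty bins to fit a slope")
    res = stats.linregress(profile.bin_centers[ok], profile.bin_means[ok])
    return float(res.slope), float(res.intercept)


# ---------------------------------------------------------------------------
# Monte-Carlo envelope
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloEnvelope:
    """Null slope sample under complete spatial randomness of the subtype."""

    null_slopes: np.ndarray
    ci_low: float
    ci_high: float
    alpha: float
    subtype_count: int


def _slopes_for_counts(counts, bin_n, centers):
    """Vectorized OLS slopes for (n_sim, nbins) subtype counts per bin."""
    ok = bin_n > 0
    x = centers[ok]
    y = counts[:, ok] / bin_n[ok]
    xc = x - x.mean()
    denom = (xc**2).sum()
    return (y @ xc) / denom


def mc_envelope(
    distances,
    subtype_count: int,
    n_sim: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> MonteCarloEnvelope:
    """Null slope distribution from random subtype reassignment.

    Each replicate marks a uniformly random subset of the observed cell
    positions, of fixed size ``subtype_count``, as the subtype, recomputes
    the binned fraction profile and refits the slope.  The envelope is the
    [alpha/2, 1 − alpha/2] percentile interval of the null slopes.
    """
    d = np.asarray(distances, float)
    n = len(d)
    if subtype_count <= 0:
        raise GCZoneError("subtype_count must be positive")
    if subtype_count > n:
        raise GCZoneError("subtype_count exceeds number of cells")
    if n_sim < 100:
        raise GCZoneError("n_sim must be at least 100")
    idx, edges = _bin_index(d, value_range, bin_width)
    nbins = len(edges) - 1
    in_range = idx >= 0
    if not in_range.any():
        raise GCZoneError("no cell falls inside the distance range")
    bin_n = np.bincount(idx[in_range], minlength=nbins)
    if (bin_n > 0).sum() < 2:
        raise GCZoneError("need at least 2 non-empty bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # out-of-range cells keep an extra scratch bin so selections stay aligned
    idx_ext = np.where(idx >= 0, idx, nbins)

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_sim)
    chunk = max(1, min(n_sim, int(2e6 // max(n, 1)) or 1))
    done = 0
    while done < n_sim:
        b = min(chunk, n_sim - done)
        keys = rng.random((b, n))
        sel = np.argpartition(keys, subtype_count - 1, axis=1)[:, :subtype_count]
        picked_bins = idx_ext[sel]
        flat = picked_bins + (np.arange(b) * (nbins + 1))[:, None]
        counts = np.bincount(
            flat.ravel(), minlength=b * (nbins + 1)
        ).reshape(b, nbins + 1)[:, :nbins]
        slopes[done:done + b] = _slopes_for_counts(counts, bin_n, centers)
        done += b
    ci_low, ci_high = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MonteCarloEnvelope(
        null_slopes=slopes,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        alpha=alpha,
        subtype_count=subtype_count,
    )


def call_trend(slope: float, envelope: MonteCarloEnvelope) -> str:
    """Three-way trend call against the Monte-Carlo envelope."""
    if slope > envelope.ci_high:
        return "increasing"
    if slope < envelope.ci_low:
        return "decreasing"
    return "random"


def analyze_gradient(
    distances,
    indicator,
    n_sim: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> EnrichmentProfile:
    """Full profile for a 0/1 subtype indicator: bins, slope, envelope, trend."""
    ind = np.asarray(indicator)
    profile = enrichment_profile(distances, ind.astype(float), value_range, bin_width)
    profile.slope, profile.intercept = fit_slope(profile)
    d = np.asarray(distances, float)
    idx, _ = _bin_index(d, value_range, bin_width)
    k = int(ind[idx >= 0].astype(bool).sum())
    env = mc_envelope(
        d, k, n_sim=n_sim, seed=seed, alpha=alpha,
        value_range=value_range, bin_width=bin_width,
    )
    profile.null_slopes = env.null_slopes
    profile.ci_low, profile.ci_high = env.ci_low, env.ci_high
    profile.trend = call_trend(profile.slope, env)
    return profile


# ---------------------------------------------------------------------------
# nearest-neighbor exclusion test
# ---------------------------------------------------------------------------

@dataclass
class ExclusionResult:
    """Observed vs permutation-null nearest-neighbor distances (A -> B)."""

    observed_nn: np.ndarray
    null_nn: np.ndarray
    p_value: float
    direction: str                   # excluded / attracted / neutral
    alpha: float = 0.05
    n_rand: int = 0


def _wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p: exact for small tie-free samples, else normal
    approximation with continuity correction."""
    exact = (
        max(len(a), len(b)) <= 20
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.pvalue)


def nn_exclusion_test(
    points_a,
    points_b,
    n_rand: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ExclusionResult:
    """Are A cells farther from B cells than random labeling predicts?

    The null pools the observed positions of both sets and permutes the A/B
    labels (counts fixed) ``n_rand`` times, recomputing nearest-neighbor
    distances each time.  Direction is ``excluded`` when the observed median
    exceeds the null median at p < alpha, ``attracted`` for the reverse, and
    ``neutral`` otherwise.
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise GCZoneError("point sets must be (n, 2) arrays")
    if len(a) == 0 or len(b) == 0:
        raise GCZoneError("both point sets must be non-empty")
    if n_rand < 1:
        raise GCZoneError("n_rand must be at least 1")

    observed, _ = cKDTree(b).query(a)
    pooled = np.vstack([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    null_parts = []
    for _ in range(n_rand):
        perm = rng.permutation(len(pooled))
        ra, rb = pooled[perm[:na]], pooled[perm[na:]]
        dist, _ = cKDTree(rb).query(ra)
        null_parts.append(dist)
    null = np.concatenate(null_parts)

    p = _wilcoxon_rank_sum(observed, null)
    med_obs, med_null = np.median(observed), np.median(null)
    if p < alpha and med_obs > med_null:
        direction = "excluded"
    elif p < alpha and med_obs < med_null:
        direction = "attracted"
    else:
        direction = "neutral"
    return ExclusionResult(
        observed_nn=observed,
        null_nn=null,
        p_value=p,
        direction=direction,
        alpha=alpha,
        n_rand=n_rand,
    )


def empirical_cdf(values):
    """Right-continuous ECDF of finite values; F(max) = 1.

    Returns a vectorized callable built on :func:`scipy.stats.ecdf`.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise GCZoneError("cannot build an ECDF from no values")
    if not np.isfinite(v).all():
        raise GCZoneError("ECDF input must be finite")
    cdf = stats.ecdf(v).cdf

    def evaluate(x):
        out = cdf.evaluate(np.asarray(x, float))
        return float(out) if np.isscalar(x) else out

    evaluate.sample = np.sort(v)
    return evaluate
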