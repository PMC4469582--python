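"""Global Moran's I with great-circle-distance weights.

Spatial autocorrelation of cell-level quantities (abundance-weighted trait
proportions, climate layers, regression residuals) is measured with Global
Moran's I,

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

where the weights ``w_ij`` derive from great-circle distances between raster
cell centres.  Distant pairs should matter less than close pairs, so the
default scheme is inverse great-circle distance; raw distance and a binary
distance threshold are available for sensitivity analyses.  Expectation and
variance of I under the normality null follow the classical formulas, giving
a two-sided normal-approximation p-value.

The module also provides the differencing partition: the share of a trait's
spatial autocorrelation accounted for by climate is the drop from the trait's
Moran's I to the Moran's I of its trait-climate model residuals, expressed as
a percentage of the former.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "SpatialWeights",
    "build_weights",
    "MoranResult",
    "morans_i",
    "morans_i_bruteforce",
    "PartitionResult",
    "partition_autocorrelation",
]


def great_circle_distance(lon1, lat1, lon2, lat2):
    """Haversine distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of WGS84 decimal degrees.
    """
    lat1a, lat2a = np.asarray(lat1, float), np.asarray(lat2, float)
    if np.any(np.abs(lat1a) > 90.0) or np.any(np.abs(lat2a) > 90.0):
        raise ValueError("latitude outside [-90, 90] degrees")
    phi1, phi2 = np.radians(lat1a), np.radians(lat2a)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, float) - np.asarray(lon1, float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards roundoff at antipodal points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.isscalar(lon1) and np.isscalar(lon2) and np.isscalar(lat1) and np.isscalar(lat2):
        return float(d)
    return d


def distance_matrix(lons, lats):
    """Pairwise great-circle distances (km) between points, zero diagonal."""
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    d = great_circle_distance(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SpatialWeights:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    w: np.ndarray
    scheme: str
    s0: float = field(init=False)

    def __post_init__(self):
        w = np.asarray(self.w, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("weight matrix diagonal must be zero")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0.0):
            raise ValueError("weights must be nonnegative")
        self.w = w
        self.s0 = float(w.sum())
        if self.s0 <= 0.0:
            raise ValueError("sum of weights must be positive")

    @property
    def n(self) -> int:
        return self.w.shape[0]


def build_weights(lons, lats, scheme: str = "inverse_distance",
                  threshold_km: float | None = None) -> SpatialWeights:
    """Build great-circle-distance weights between cell centres.

    Parameters
    ----------
    lons, lats : array-like, degrees
        Coordinates of the n cells (n >= 3, all distinct).
    scheme : {"inverse_distance", "raw_distance", "binary_threshold"}
        ``inverse_distance`` (default): w_ij = 1 / d_ij.
        ``raw_distance``: w_ij = d_ij (sensitivity option; weights distant
        pairs most, kept for comparison with a literal distances-as-weights
        reading).
        ``binary_threshold``: w_ij = 1 if d_ij <= threshold_km.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if lons.shape != lats.shape or lons.ndim != 1:
        raise ValueError("lons and lats must be 1-d arrays of equal length")
    n = lons.size
    if n < 3:
        raise ValueError("need at least 3 cells")
    d = distance_matrix(lons, lats)
    off = ~np.eye(n, dtype=bool)
    if scheme == "inverse_distance":
        if np.any(d[off] == 0.0):
            i, j = np.argwhere((d == 0.0) & off)[0]
            raise ValueError(
                f"coincident coordinates for cells {i} and {j}: "
                "inverse-distance weights undefined"
            )
        w = np.zeros_like(d)
        w[off] = 1.0 / d[off]
    elif scheme == "raw_distance":
        w = d.copy()
    elif scheme == "binary_threshold":
        if threshold_km is None:
            raise ValueError("binary_threshold scheme requires threshold_km")
        w = ((d <= threshold_km) & off).astype(float)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return SpatialWeights(w=w, scheme=scheme)


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    p_value: float
    n: int

    @property
    def z(self) -> float:
        return (self.I - self.expected) / math.sqrt(self.variance)


def morans_i(x, weights: SpatialWeights) -> MoranResult:
    """Global Moran's I with analytic (normality) significance.

    Uses the weight matrix as given (no row standardization).  The variance
    is the classical normality-assumption formula; the p-value is two-sided
    from the normal approximation.
    """
    x = np.asarray(x, float)
    w = weights.w
    n = weights.n
    if x.shape != (n,):
        raise ValueError("x length must match weights")
    if n < 3:
        raise ValueError("need n >= 3")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: Moran's I undefined for constant x")
    s0 = weights.s0
    i_stat = (n / s0) * float(z @ w @ z) / denom

    # moments under the normality null
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    rs = w.sum(axis=1) + w.sum(axis=0)
    s2 = float((rs ** 2).sum())
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (s0 * s0 * (n * n - 1.0)) - e_i ** 2
    if var <= 0.0:
        raise ValueError("non-positive Moran variance (degenerate weights)")
    zscore = (i_stat - e_i) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(I=i_stat, expected=e_i, variance=var, p_value=p, n=n)


def morans_i_bruteforce(x, w) -> float:
    """Literal double-loop Moran's I (independent check, O(n^2) python loops)."""
    x = [float(v) for v in x]
    n = len(x)
    xbar = sum(x) / n
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += w[i][j]
            num += w[i][j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((v - xbar) ** 2 for v in x)
    return (n / s0) * num / den


def morans_i_permutation_p(x, weights: SpatialWeights, n_perm: int = 999,
                           seed: int = 0) -> float:
    """Permutation p-value (two-sided) as an alternative to the normal one."""
    rng = np.random.default_rng(seed)
    obs = morans_i(x, weights).I
    e_i = -1.0 / (weights.n - 1)
    x = np.asarray(x, float)
    count = 0
    for _ in range(n_perm):
        perm = morans_i(rng.permutation(x), weights).I
        if abs(perm - e_i) >= abs(obs - e_i):
            count += 1
    return (count + 1) / (n_perm + 1)


@dataclass
class PartitionResult:
    """Share of a trait's spatial autocorrelation accounted for by climate."""

    i_total: float
    i_residual: float
    explained_autocorrelation_pct: float
    valid: bool
    reason: str = ""
    clipped: bool = False


def partition_autocorrelation(i_total: MoranResult, i_residual: MoranResult,
                              alpha: float = 0.05) -> PartitionResult:
    """Subtract residual Moran's I from total and express as a percentage.

    explained% = 100 * (I_total - I_residual) / I_total, defined only when
    I_total is positive and significant at ``alpha``; values outside [0, 100]
    are clipped with a flag.
    """
    if i_total.n != i_residual.n:
        raise ValueError("total and residual Moran results use different cell sets")
    if i_total.I <= 0.0:
        return PartitionResult(i_total.I, i_residual.I, float("nan"), False,
                               reason="total autocorrelation non-positive")
    if i_total.p_value > alpha:
        return PartitionResult(i_total.I, i_residual.I, float("nan"), False,
                               reason="total autocorrelation not significant")
    pct = 100.0 * (i_total.I - i_residual.I) / i_total.I
    clipped = False
    reason = ""
    if pct < 0.0:
        pct, clipped, reason = 0.0, True, "residual autocorrelation exceeds total"
    elif pct > 100.0:
        pct, clipped, reason = 100.0, True, "residual autocorrelation non-positive"
    return PartitionResult(i_total.I, i_residual.I, pct, True,
                           reason=reason, clipped=clipped)
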