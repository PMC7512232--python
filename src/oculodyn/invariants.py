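"""Correlation-sum based invariants of reconstructed dynamics.

This module carries the quantitative core of the package:

* the Grassberger-Procaccia correlation sum ``C(m, r)`` with a Theiler
  window ``w`` excluding temporally close pairs,

      C(r) = 2 / ((N-w)(N-w-1)) * sum_{i} sum_{j >= i+1+w} H(r - ||y_i - y_j||),

* the correlation dimension D2 as the slope of log C(r) vs log r inside a
  linear scaling region, aggregated over embedding dimensions that agree
  (an m-plateau),
* the correlation entropy K2 = ln( C(m, r) / C(m+1, r) ), averaged over the
  scaling region and aggregated over the m-plateau,
* the largest Lyapunov exponent by Rosenstein's mean-log-divergence method,
* the data-length bounds D2 <= 2 log10 N and N >= 10^(D2/2).

The radius grid follows the study convention rmin = stdev/10,
rmax = 10 stdev with (by default) 100 log-spaced radii.

Pair counting is done in a single jitted pass over admissible pairs,
accumulating squared distances incrementally across embedding dimensions;
the observable result is identical to direct pair enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist, pdist
from scipy.stats import linregress

from .core import TimeSeries
from .embedding import DelayEmbedding
from .exceptions import (
    DegenerateInputError,
    InsufficientPairsError,
    InvalidParameterError,
)

__all__ = [
    "RadiusGrid",
    "CorrelationSumResult",
    "InvariantEstimate",
    "radius_grid",
    "correlation_sum",
    "correlation_sums",
    "scaling_exponents",
    "estimate_d2",
    "k2_entropy",
    "lle_rosenstein",
    "sample_size_bound",
    "required_n",
    "takens_minimum_dim",
]


@dataclass
class RadiusGrid:
    """Increasing grid of neighbourhood radii spanning [stdev/10, 10 stdev]."""

    radii: np.ndarray
    rmin: float
    rmax: float

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or r.size < 2:
            raise InvalidParameterError("radius grid needs at least 2 radii")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise InvalidParameterError("radii must be positive and increasing")
        self.radii = r

    @property
    def n_radii(self) -> int:
        return self.radii.size

    @classmethod
    def from_bounds(cls, rmin: float, rmax: float, n_radii: int = 100) -> "RadiusGrid":
        if not (0 < rmin < rmax):
            raise InvalidParameterError("need 0 < rmin < rmax")
        return cls(np.geomspace(rmin, rmax, n_radii), rmin, rmax)


def radius_grid(series: TimeSeries | np.ndarray, n_radii: int = 100) -> RadiusGrid:
    """Log-spaced radii between stdev/10 and 10 stdev of the series."""
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateInputError("constant series has no radius scale")
    return RadiusGrid.from_bounds(sd / 10.0, 10.0 * sd, n_radii)


@dataclass
class CorrelationSumResult:
    """C(m, r) over a radius grid for one or more embedding dimensions."""

    radii: RadiusGrid
    m_values: np.ndarray
    C: np.ndarray  # shape (len(m_values), n_radii), values in [0, 1]
    theiler_w: int
    n_vectors: np.ndarray
    tau: int | None = None

    def row(self, m: int) -> np.ndarray:
        idx = np.nonzero(self.m_values == m)[0]
        if not idx.size:
            raise InvalidParameterError(f"m={m} not present in result")
        return self.C[idx[0]]


@dataclass
class InvariantEstimate:
    """A D2, K2 or LLE estimate with its scaling region and diagnostics."""

    kind: str  # "D2" | "K2" | "LLE"
    value: float
    scaling_region: tuple[float, float]
    per_m_values: dict[int, float] = field(default_factory=dict)
    fit_quality: float = float("nan")  # R^2 of the (mean) slope fit
    plateau_found: bool | None = None
    flags: list[str] = field(default_factory=list)


@njit(cache=True, fastmath=True)
def _pair_count_kernel(emb, m_list, w, rsq):  # pragma: no cover - jitted
    """Counts of admissible pairs falling in each inter-radius bin, per m.

    ``emb`` holds the aligned delay vectors at the largest dimension, one
    row per vector.  For every pair (i, j) with j >= i + 1 + w the squared
    Euclidean distance is accumulated coordinate by coordinate; whenever the
    running dimension reaches an entry of ``m_list`` the pair is binned at
    the first grid radius whose square is >= the running distance.  The bin
    index is non-decreasing in m (distances only grow with added
    coordinates), so after one binary search the bin pointer just advances.
    """
    big_m = emb.shape[0]
    n_m = m_list.shape[0]
    n_r = rsq.shape[0]
    counts = np.zeros((n_m, n_r + 1), dtype=np.int64)
    for i in range(big_m):
        for j in range(i + 1 + w, big_m):
            dsq = 0.0
            for k in range(m_list[0]):
                d = emb[i, k] - emb[j, k]
                dsq += d * d
            # first index with rsq[idx] >= dsq (n_r if beyond the grid)
            lo = 0
            hi = n_r
            while lo < hi:
                mid = (lo + hi) >> 1
                if rsq[mid] < dsq:
                    lo = mid + 1
                else:
                    hi = mid
            counts[0, lo] += 1
            m = m_list[0]
            for k_m in range(1, n_m):
                for k in range(m, m_list[k_m]):
                    d = emb[i, k] - emb[j, k]
                    dsq += d * d
                m = m_list[k_m]
                while lo < n_r and rsq[lo] < dsq:
                    lo += 1
                counts[k_m, lo] += 1
    return counts[:, :n_r]


def _norm_pairs(big_m: int, w: int) -> int:
    return (big_m - w) * (big_m - w - 1) // 2


def correlation_sums(
    series: TimeSeries | np.ndarray,
    tau: int,
    m_values,
    radii: RadiusGrid | None = None,
    theiler_w: int = 100,
    min_pairs: int = 10,
) -> CorrelationSumResult:
    """Theiler-windowed correlation sums for several embedding dimensions.

    All dimensions share the vector count of the largest m (the delay
    vectors are aligned), so ``C(m+1, r) <= C(m, r)`` holds exactly and the
    K2 ratio is well defined.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    m_arr = np.asarray(sorted(set(int(m) for m in m_values)), dtype=np.int64)
    if m_arr.size == 0 or m_arr[0] < 1:
        raise InvalidParameterError("m_values must be positive integers")
    if tau < 1:
        raise InvalidParameterError("tau must be >= 1")
    if theiler_w < 0:
        raise InvalidParameterError("theiler_w must be >= 0")
    if radii is None:
        radii = radius_grid(x)
    big_m = x.size - (int(m_arr[-1]) - 1) * tau
    n_adm = _norm_pairs(big_m, theiler_w) if big_m > theiler_w else 0
    if n_adm < min_pairs:
        raise InsufficientPairsError(
            f"only {max(n_adm, 0)} admissible pairs with M={big_m}, w={theiler_w}"
        )
    rsq = (radii.radii * radii.radii).astype(np.float64)
    m_max = int(m_arr[-1])
    emb = np.empty((big_m, m_max))
    for k in range(m_max):
        emb[:, k] = x[k * tau : k * tau + big_m]
    counts = _pair_count_kernel(emb, m_arr, theiler_w, rsq)
    C = np.cumsum(counts, axis=1) / n_adm
    return CorrelationSumResult(
        radii=radii,
        m_values=m_arr,
        C=C,
        theiler_w=theiler_w,
        n_vectors=np.full(m_arr.size, big_m, dtype=np.int64),
        tau=tau,
    )


def correlation_sum(
    embedding: DelayEmbedding,
    radii: RadiusGrid,
    theiler_w: int = 0,
    min_pairs: int = 1,
) -> CorrelationSumResult:
    """Correlation sum of a single embedding (direct pairwise counting).

    ``min_pairs`` defaults to 1 here (tiny worked examples are legitimate);
    the multi-m analysis entry point :func:`correlation_sums` keeps the
    stricter default of 10 admissible pairs.
    """
    big_m = embedding.n_vectors
    if theiler_w < 0:
        raise InvalidParameterError("theiler_w must be >= 0")
    n_adm = _norm_pairs(big_m, theiler_w) if big_m > theiler_w else 0
    if n_adm < min_pairs:
        raise InsufficientPairsError(
            f"only {max(n_adm, 0)} admissible pairs with M={big_m}, w={theiler_w}"
        )
    dsq = pdist(embedding.vectors, "sqeuclidean")
    if theiler_w:
        iu, ju = np.triu_indices(big_m, k=1)
        dsq = dsq[(ju - iu) > theiler_w]
    rsq = radii.radii * radii.radii
    bins = np.searchsorted(rsq, dsq, side="left")
    hist = np.bincount(bins[bins < radii.n_radii], minlength=radii.n_radii)
    C = np.cumsum(hist) / n_adm
    return CorrelationSumResult(
        radii=radii,
        m_values=np.array([embedding.m], dtype=np.int64),
        C=C[None, :],
        theiler_w=theiler_w,
        n_vectors=np.array([big_m], dtype=np.int64),
        tau=embedding.tau,
    )


def scaling_exponents(result: CorrelationSumResult) -> np.ndarray:
    """Local slopes d log C / d log r per m (centred differences).

    Entries are NaN wherever a required C value is zero (no pairs yet).
    """
    log_r = np.log10(result.radii.radii)
    with np.errstate(divide="ignore"):
        log_c = np.log10(result.C)
    log_c[~np.isfinite(log_c)] = np.nan
    slopes = np.full_like(log_c, np.nan)
    slopes[:, 1:-1] = (log_c[:, 2:] - log_c[:, :-2]) / (log_r[2:] - log_r[:-2])
    slopes[:, 0] = (log_c[:, 1] - log_c[:, 0]) / (log_r[1] - log_r[0])
    slopes[:, -1] = (log_c[:, -1] - log_c[:, -2]) / (log_r[-1] - log_r[-2])
    return slopes


def _default_region(radii: RadiusGrid) -> tuple[float, float]:
    """Lower third of the grid in log space (small-radius scaling zone)."""
    r = radii.radii
    return float(r[0]), float(r[min(r.size - 1, r.size // 3)])


def _region_fit(radii: np.ndarray, c_row: np.ndarray, region, min_points=3):
    lo, hi = region
    mask = (radii >= lo) & (radii <= hi) & (c_row > 0)
    if int(mask.sum()) < min_points:
        return None
    fit = linregress(np.log10(radii[mask]), np.log10(c_row[mask]))
    return float(fit.slope), float(fit.rvalue**2)


def _plateau(values: dict[int, float], tol: float):
    """Longest run of consecutive-m values whose successive gaps are < tol."""
    ms = sorted(values)
    best: list[int] = []
    run: list[int] = []
    for m in ms:
        if run and (m - run[-1] == 1) and abs(values[m] - values[run[-1]]) < tol:
            run.append(m)
        else:
            run = [m]
        if len(run) > len(best):
            best = list(run)
    return best


def estimate_d2(
    result: CorrelationSumResult,
    region: tuple[float, float] | None = None,
    plateau_tol: float = 0.2,
    min_points: int = 3,
) -> InvariantEstimate:
    """Correlation dimension from log-log slopes inside a scaling region.

    A least-squares slope of log C(m, r) vs log r is fitted per embedding
    dimension over radii in ``region`` where C > 0; the reported value is
    the median slope over the longest run of consecutive m whose successive
    slopes differ by less than ``plateau_tol`` (the m-plateau).  Plateau
    membership additionally requires slope < m: a genuine attractor
    dimension is below every embedding dimension that resolves it, which
    rejects the spurious flat runs produced by space-filling noise once its
    slopes saturate.  If no run of length >= 2 exists the median of all
    valid slopes is reported with ``plateau_found=False``.
    """
    if region is None:
        region = _default_region(result.radii)
    slopes: dict[int, float] = {}
    r2s: dict[int, float] = {}
    flags: list[str] = []
    for k, m in enumerate(result.m_values):
        fit = _region_fit(result.radii.radii, result.C[k], region, min_points)
        if fit is None:
            flags.append(f"m={int(m)}: fewer than {min_points} radii with C>0 in region")
            continue
        slopes[int(m)], r2s[int(m)] = fit
    if not slopes:
        return InvariantEstimate(
            kind="D2",
            value=float("nan"),
            scaling_region=region,
            plateau_found=False,
            flags=flags + ["no_valid_fit"],
        )
    physical = {m: s for m, s in slopes.items() if s < m}
    plateau = _plateau(physical, plateau_tol)
    found = len(plateau) >= 2
    chosen = plateau if found else sorted(slopes)
    value = float(np.median([slopes[m] for m in chosen]))
    quality = float(np.mean([r2s[m] for m in chosen]))
    return InvariantEstimate(
        kind="D2",
        value=value,
        scaling_region=region,
        per_m_values=slopes,
        fit_quality=quality,
        plateau_found=found,
        flags=flags,
    )


def k2_entropy(
    result: CorrelationSumResult,
    region: tuple[float, float] | None = None,
    plateau_tol: float = 0.02,
) -> InvariantEstimate:
    """Correlation entropy K2 = ln( C(m, r) / C(m+1, r) ).

    The ratio is averaged over the region radii where both sums are
    positive, giving one K2 value per m; the estimate is the median over
    the m-plateau (consecutive m with gaps < ``plateau_tol``, in nats).
    Divergence with m (no plateau) is the stochastic-signal signature.
    """
    if region is None:
        region = _default_region(result.radii)
    lo, hi = region
    radii = result.radii.radii
    in_region = (radii >= lo) & (radii <= hi)
    k2s: dict[int, float] = {}
    flags: list[str] = []
    m_list = list(result.m_values)
    for k, m in enumerate(m_list):
        if int(m) + 1 not in [int(v) for v in m_list]:
            continue
        k1 = m_list.index(m + 1)
        valid = in_region & (result.C[k] > 0) & (result.C[k1] > 0)
        if not valid.any():
            flags.append(f"m={int(m)}: C(m+1, r) vanishes on the region")
            continue
        k2s[int(m)] = float(np.mean(np.log(result.C[k][valid] / result.C[k1][valid])))
    if not k2s:
        raise InsufficientPairsError(
            "C(m+1, r) vanishes throughout the region for every m"
        )
    plateau = _plateau(k2s, plateau_tol)
    found = len(plateau) >= 2
    chosen = plateau if found else sorted(k2s)
    value = float(np.median([k2s[m] for m in chosen]))
    return InvariantEstimate(
        kind="K2",
        value=value,
        scaling_region=region,
        per_m_values=k2s,
        plateau_found=found,
        flags=flags,
    )


def lle_rosenstein(
    embedding: DelayEmbedding,
    dt: float = 1.0,
    theiler_w: int = 0,
    max_steps: int = 30,
    fit_range: tuple[int, int] | None = None,
    min_pairs: int = 10,
) -> InvariantEstimate:
    """Largest Lyapunov exponent by Rosenstein's method.

    Each vector is paired with its nearest neighbour outside the Theiler
    window; the mean over pairs of ln d_j(k) is tracked for k = 0..max_steps
    and lambda is the least-squares slope of that curve over its initial
    (assumed linear) segment, divided by ``dt``.  Pairs with zero initial
    separation are excluded, not divided by.
    """
    x_vec = embedding.vectors
    big_m = embedding.n_vectors
    n_base = big_m - max_steps
    if n_base <= theiler_w + 10:
        raise InsufficientPairsError(
            f"M - max_steps = {n_base} leaves too few base points for w={theiler_w}"
        )
    base = x_vec[:n_base]
    scale = float(np.std(base))
    floor = 1e-9 * scale if scale > 0 else 0.0  # duplicates / rounding noise
    nn = np.empty(n_base, dtype=np.int64)
    chunk = 512
    for start in range(0, n_base, chunk):
        stop = min(start + chunk, n_base)
        d = cdist(base[start:stop], base)
        d[d <= floor] = np.inf
        for r_local, r in enumerate(range(start, stop)):
            lo = max(0, r - theiler_w)
            hi = min(n_base, r + theiler_w + 1)
            d[r_local, lo:hi] = np.inf
        nn[start:stop] = np.argmin(d, axis=1)
    ii = np.arange(n_base)
    jj = nn
    d0 = np.linalg.norm(x_vec[ii] - x_vec[jj], axis=1)
    keep = d0 > floor
    n_zero = int(np.sum(~keep))
    ii, jj = ii[keep], jj[keep]
    if ii.size < min_pairs:
        raise InsufficientPairsError(f"only {ii.size} non-degenerate neighbour pairs")
    steps = np.arange(max_steps + 1)
    mean_log = np.empty(steps.size)
    for s in steps:
        d_s = np.linalg.norm(x_vec[ii + s] - x_vec[jj + s], axis=1)
        good = d_s > 0
        mean_log[s] = float(np.mean(np.log(d_s[good]))) if good.any() else np.nan
    if fit_range is None:
        fit_range = (0, min(8, max_steps))
    s0, s1 = fit_range
    seg = slice(s0, s1 + 1)
    valid = np.isfinite(mean_log[seg])
    fit = linregress(steps[seg][valid] * dt, mean_log[seg][valid])
    flags = [f"{n_zero} zero-distance pairs excluded"] if n_zero else []
    return InvariantEstimate(
        kind="LLE",
        value=float(fit.slope),
        scaling_region=(s0 * dt, s1 * dt),
        fit_quality=float(fit.rvalue**2),
        plateau_found=None,
        flags=flags,
    )


def sample_size_bound(n: int) -> float:
    """Largest correlation dimension reliably estimable from n samples:
    D2 <= 2 log10 n."""
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    return 2.0 * math.log10(n)


def required_n(d2: float) -> int:
    """Smallest sample count supporting a reliable estimate of d2:
    N >= 10^(D2/2)."""
    if d2 < 0:
        raise InvalidParameterError("d2 must be >= 0")
    return int(math.ceil(10.0 ** (d2 / 2.0)))


def takens_minimum_dim(d: float) -> int:
    """Minimum embedding dimension guaranteeing reconstruction: m >= 2d + 1."""
    if d < 0:
        raise InvalidParameterError("attractor dimension must be >= 0")
    return int(2 * math.ceil(d) + 1)
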