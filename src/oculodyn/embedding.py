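"""Phase-space reconstruction: time-lag selection by averaged mutual
information (AMI), embedding-dimension selection by false nearest neighbours
(FNN), and delay embedding itself.

Takens' theorem guarantees that the delay vectors

    y(i) = (x(i), x(i + tau), ..., x(i + (m-1) tau)),  i = 1..M,
    M = N - (m - 1) tau

preserve the invariants of the underlying dynamics for suitable (tau, m).
The lag is read off the first local minimum of the AMI profile (1/e decay as
fallback); the dimension is the smallest m at which the FNN fraction
collapses below a tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import psi

from .core import TimeSeries
from .exceptions import DegenerateInputError, InvalidParameterError, TooShortError

__all__ = [
    "AMIProfile",
    "FNNProfile",
    "DelayEmbedding",
    "freedman_diaconis_bins",
    "ami_profile",
    "select_lag",
    "fnn_profile",
    "select_embedding_dim",
    "delay_embed",
]


@dataclass
class AMIProfile:
    """Averaged mutual information (bits) as a function of lag."""

    lags: np.ndarray
    ami: np.ndarray
    n_bins: int


@dataclass
class FNNProfile:
    """False-nearest-neighbour fraction as a function of embedding dimension."""

    dims: np.ndarray
    fnn_fraction: np.ndarray
    threshold_r: float
    n_zero_distance: int = 0


@dataclass
class DelayEmbedding:
    """M x m matrix of delay vectors built with lag ``tau`` from N samples."""

    vectors: np.ndarray
    tau: int
    m: int
    source_length: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.m:
            raise InvalidParameterError("vectors must be an (M, m) matrix")
        if self.vectors.shape[0] != self.source_length - (self.m - 1) * self.tau:
            raise InvalidParameterError("M must equal N - (m-1)*tau")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]


def freedman_diaconis_bins(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Freedman-Diaconis histogram assignment: width ``2 IQR n^(-1/3)``.

    Returns (bin index per sample, number of bins).  Raises on zero IQR.
    """
    x = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise DegenerateInputError("zero interquartile range; cannot bin")
    width = 2.0 * iqr * x.size ** (-1.0 / 3.0)
    lo, hi = x.min(), x.max()
    n_bins = max(1, int(np.ceil((hi - lo) / width)))
    idx = np.minimum((np.floor((x - lo) / width)).astype(np.int64), n_bins - 1)
    return idx, n_bins


def _entropy_bits(counts: np.ndarray, n: int, bias_correction: bool) -> float:
    """Histogram entropy in bits.

    With ``bias_correction`` the Grassberger psi-function estimator is used
    (``H = ln n - (1/n) sum c (psi(c) + (-1)^c / (c+1))``), which removes
    most of the downward plug-in bias of sparse histograms; otherwise the
    plug-in ``-sum p log p``.
    """
    c = counts[counts > 0].astype(float)
    if bias_correction:
        g = psi(c) + ((-1.0) ** c) / (c + 1.0)
        h_nats = np.log(n) - float(np.sum(c * g)) / n
        return h_nats / np.log(2.0)
    p = c / n
    return float(-np.sum(p * np.log2(p)))


def _mutual_information_bits(
    a_idx: np.ndarray, b_idx: np.ndarray, n_bins: int, bias_correction: bool = True
) -> float:
    """MI of two binned samples in bits, ``I = H_a + H_b - H_ab``.

    The plug-in estimator over-states MI for sparse joint histograms;
    ``bias_correction`` computes each entropy with the Grassberger
    estimator instead.  The result is clipped at zero.
    """
    n = a_idx.size
    codes = a_idx * n_bins + b_idx
    _, c_joint = np.unique(codes, return_counts=True)
    c_a = np.bincount(a_idx, minlength=n_bins)
    c_b = np.bincount(b_idx, minlength=n_bins)
    mi = (
        _entropy_bits(c_a, n, bias_correction)
        + _entropy_bits(c_b, n, bias_correction)
        - _entropy_bits(c_joint, n, bias_correction)
    )
    return max(0.0, mi)


def ami_profile(
    series: TimeSeries | np.ndarray,
    max_lag: int = 30,
    n_bins: int | None = None,
    bias_correction: bool = True,
) -> AMIProfile:
    """Averaged mutual information profile over lags 0..max_lag.

    ``I(tau) = sum_{h,k} P_hk log2( P_hk / (P_h P_k) )`` over a 2-D
    histogram whose bin width follows the Freedman-Diaconis rule applied to
    the full series (override with ``n_bins``).  Marginals are taken from
    the lagged pair sample, so I >= 0 and I is symmetric in the pair order.
    The Grassberger entropy estimator (on by default) removes most of the
    plug-in estimator's positive finite-sample MI bias.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    if x.size <= max_lag + 2:
        raise TooShortError(f"need more than {max_lag + 2} samples for max_lag={max_lag}")
    if n_bins is None:
        idx, n_bins = freedman_diaconis_bins(x)
    else:
        if np.ptp(x) == 0:
            raise DegenerateInputError("constant series")
        lo, hi = x.min(), x.max()
        width = (hi - lo) / n_bins
        idx = np.minimum((np.floor((x - lo) / width)).astype(np.int64), n_bins - 1)
    lags = np.arange(max_lag + 1)
    ami = np.empty(lags.size)
    for i, lag in enumerate(lags):
        a = idx[: x.size - lag]
        b = idx[lag:]
        ami[i] = _mutual_information_bits(a, b, n_bins, bias_correction)
    return AMIProfile(lags=lags, ami=ami, n_bins=n_bins)


def select_lag(profile: AMIProfile) -> int:
    """Choose the embedding lag from an AMI profile.

    Rule: the earlier of (a) the smallest lag that is a strict local
    minimum of the AMI and (b) the smallest lag where AMI drops to
    ``I(0)/e``.  Monotonically decaying profiles have no local minimum
    before the decay criterion, and small-sample fluctuations deep in the
    tail can fake one after it, so combining the two criteria keeps the
    choice in the informative part of the profile.  If the profile never
    decays that far and has no minimum, the largest lag is returned with a
    warning.
    """
    ami = profile.ami
    lags = profile.lags
    if lags.size < 3:
        raise InvalidParameterError("profile must cover at least 3 lags")
    local_min = None
    for i in range(1, lags.size - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            local_min = int(lags[i])
            break
    threshold = ami[0] / np.e
    below = np.nonzero(ami[1:] <= threshold)[0]
    decay = int(lags[1 + below[0]]) if below.size else None
    candidates = [c for c in (local_min, decay) if c is not None]
    if candidates:
        return min(candidates)
    warnings.warn("AMI profile shows no minimum and no 1/e decay; using max lag")
    return int(lags[-1])


def delay_embed(series: TimeSeries | np.ndarray, tau: int, m: int) -> DelayEmbedding:
    """Build the delay embedding (Takens reconstruction) of a series."""
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    if tau < 1 or m < 1:
        raise InvalidParameterError("tau and m must be >= 1")
    n = x.size
    required = (m - 1) * tau + 1
    if n < required:
        raise TooShortError(f"need N >= {required} samples for m={m}, tau={tau}; got {n}")
    big_m = n - (m - 1) * tau
    vectors = np.empty((big_m, m))
    for k in range(m):
        vectors[:, k] = x[k * tau : k * tau + big_m]
    return DelayEmbedding(vectors=vectors, tau=tau, m=m, source_length=n)


def _nearest_neighbours(
    points: np.ndarray, theiler_w: int = 0, chunk: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """Index and distance of each point's nearest neighbour (Euclidean).

    Self-matches, temporal neighbours within ``theiler_w``, and effective
    duplicates (distance below a relative floating-point noise floor) are
    excluded; ties break to the smallest index (argmin convention).  A
    point whose every candidate is excluded gets distance inf.
    """
    n = points.shape[0]
    scale = float(np.std(points))
    floor = 1e-9 * scale if scale > 0 else 0.0
    nn_idx = np.empty(n, dtype=np.int64)
    nn_dist = np.empty(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(points[start:stop], points)
        d[d <= floor] = np.inf
        rows = np.arange(start, stop)
        for r_local, r in enumerate(rows):
            lo = max(0, r - theiler_w)
            hi = min(n, r + theiler_w + 1)
            d[r_local, lo:hi] = np.inf
        nn_idx[start:stop] = np.argmin(d, axis=1)
        nn_dist[start:stop] = d[np.arange(stop - start), nn_idx[start:stop]]
    return nn_idx, nn_dist


def fnn_profile(
    series: TimeSeries | np.ndarray,
    tau: int,
    m_range=range(1, 11),
    threshold_r: float = 10.0,
    theiler_w: int = 0,
) -> FNNProfile:
    """False-nearest-neighbour fractions over candidate dimensions.

    For each m the nearest neighbour of every delay vector (with its extra
    (m+1)-th coordinate available) is found; the pair is a *false* neighbour
    when ``|x[i+m tau] - x[nn+m tau]| / ||y_i - y_nn||`` exceeds
    ``threshold_r``.  Zero-distance duplicate neighbours are excluded from
    the ratio and counted.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, dtype=float)
    dims = np.asarray(sorted(m_range), dtype=int)
    n = x.size
    if n < dims[-1] * tau + 2:
        raise TooShortError(f"series too short for m={dims[-1]} at tau={tau}")
    fractions = np.empty(dims.size)
    n_zero = 0
    for j, m in enumerate(dims):
        n_vec = n - m * tau  # vectors whose (m+1)-th coordinate exists
        emb = delay_embed(x, tau, m).vectors[:n_vec]
        nn_idx, nn_dist = _nearest_neighbours(emb, theiler_w=theiler_w)
        valid = np.isfinite(nn_dist)
        n_zero += int(np.sum(~valid))
        extra_self = x[np.arange(n_vec) + m * tau]
        extra_nn = x[nn_idx + m * tau]
        ratio = np.abs(extra_self - extra_nn)[valid] / nn_dist[valid]
        fractions[j] = float(np.mean(ratio > threshold_r)) if valid.any() else np.nan
    return FNNProfile(dims=dims, fnn_fraction=fractions, threshold_r=threshold_r, n_zero_distance=n_zero)


def select_embedding_dim(profile: FNNProfile, tol: float = 0.01) -> int:
    """Smallest m whose FNN fraction is <= tol; max of range with a warning
    if the fraction never collapses."""
    ok = np.nonzero(profile.fnn_fraction <= tol)[0]
    if ok.size:
        return int(profile.dims[ok[0]])
    warnings.warn(f"FNN fraction never fell below {tol}; using largest m")
    return int(profile.dims[-1])
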