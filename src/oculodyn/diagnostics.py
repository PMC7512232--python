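"""Space-time separation plots (Theiler-window justification) and
recurrence matrices.

The space-time separation plot shows, for every temporal separation dt,
percentile contours of the distances between state pairs exactly dt apart.
For temporally correlated data the contours rise with dt before saturating;
pairs closer in time than the saturation point would bias the correlation
sum, which is why they are excluded by the Theiler window.

The recurrence matrix is the unthresholded pairwise-distance matrix of a
series (or embedding), normalised to [0, 1]: 0 = identical states (black in
the conventional rendering), 1 = maximally distant (white).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import TimeSeries
from .embedding import DelayEmbedding
from .exceptions import InvalidParameterError, TooShortError

__all__ = [
    "SpaceTimeSeparation",
    "TheilerSuggestion",
    "RecurrenceMatrix",
    "space_time_separation",
    "suggest_theiler",
    "recurrence_matrix",
    "plot_recurrence",
]

DECILES = tuple(range(10, 100, 10))


@dataclass
class SpaceTimeSeparation:
    """Percentile contours of pair distances vs temporal separation."""

    dt_values: np.ndarray
    percentiles: np.ndarray
    contours: np.ndarray  # shape (n_percentiles, n_dt)


@dataclass
class TheilerSuggestion:
    """Suggested Theiler window with its provenance."""

    window: int
    by_saturation: int | None
    three_tau: int | None
    saturated: bool


@dataclass
class RecurrenceMatrix:
    """Symmetric pairwise-distance matrix normalised by its maximum."""

    distances: np.ndarray
    normalisation: float


def space_time_separation(
    embedding: DelayEmbedding,
    max_dt: int = 500,
    percentiles=DECILES,
) -> SpaceTimeSeparation:
    """Distance percentiles between vector pairs separated by exactly dt,
    for dt = 1..max_dt."""
    vectors = embedding.vectors
    big_m = embedding.n_vectors
    if max_dt >= big_m:
        raise InvalidParameterError(f"max_dt={max_dt} must be below M={big_m}")
    pct = np.asarray(percentiles, dtype=float)
    dts = np.arange(1, max_dt + 1)
    contours = np.empty((pct.size, dts.size))
    for k, dt in enumerate(dts):
        d = np.linalg.norm(vectors[dt:] - vectors[:-dt], axis=1)
        contours[:, k] = np.percentile(d, pct)
    return SpaceTimeSeparation(dt_values=dts, percentiles=pct, contours=contours)


def suggest_theiler(
    stsep: SpaceTimeSeparation, tol: float = 0.10, tau: int | None = None
) -> TheilerSuggestion:
    """Smallest dt beyond which the median contour stays within ``tol`` of
    its long-dt level; falls back to the 3*tau rule when no saturation is
    found inside the analysed range."""
    if stsep.contours.size == 0:
        raise InvalidParameterError("empty space-time separation contours")
    med_idx = int(np.argmin(np.abs(stsep.percentiles - 50.0)))
    median = stsep.contours[med_idx]
    n = median.size
    level = float(np.median(median[-max(1, n // 4) :]))
    if level <= 0:
        return TheilerSuggestion(1, 1, 3 * tau if tau else None, True)
    within = np.abs(median - level) <= tol * level
    # smallest dt from which the contour never leaves the tolerance band
    stays = np.flip(np.logical_and.accumulate(np.flip(within)))
    idx = np.nonzero(stays)[0]
    three_tau = 3 * tau if tau is not None else None
    if idx.size and idx[0] < n - 1:
        dt = int(stsep.dt_values[idx[0]])
        return TheilerSuggestion(dt, dt, three_tau, True)
    fallback = three_tau if three_tau is not None else int(stsep.dt_values[-1])
    return TheilerSuggestion(fallback, None, three_tau, False)


def recurrence_matrix(obj: TimeSeries | DelayEmbedding) -> RecurrenceMatrix:
    """Unthresholded recurrence (distance) matrix, normalised to [0, 1].

    Scalar series use absolute differences; embeddings use Euclidean
    distances between delay vectors.  Scale-invariant by construction.
    """
    if isinstance(obj, DelayEmbedding):
        points = obj.vectors
    else:
        if obj.n < 2:
            raise TooShortError("recurrence matrix needs at least 2 elements")
        points = obj.values[:, None]
    d = cdist(points, points)
    peak = float(d.max())
    if peak > 0:
        d = d / peak
    return RecurrenceMatrix(distances=d, normalisation=peak)


def plot_recurrence(matrix: RecurrenceMatrix, path: str) -> None:
    """Render a recurrence matrix as a grayscale PNG (origin lower-left).

    Requires matplotlib (the optional ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(matrix.distances, cmap="gray", origin="lower", vmin=0.0, vmax=1.0)
    ax.set_xlabel("sample index")
    ax.set_ylabel("sample index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
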