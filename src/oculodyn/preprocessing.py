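"""Position -> analysed velocity series: differentiation, ideal low-pass
filtering (BNR -> ANR), fixation splitting and windowing.

The analysed object of the study is the horizontal eye-movement *velocity*
during each stimulus-locked fixation: 3000 position samples differentiate to
2999 velocity samples; the ideal (DFT brick-wall) low-pass filter with a
50 Hz cutoff produces the "after noise reduction" (ANR) counterpart of each
"before noise reduction" (BNR) series.
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_WINDOWS, TimeSeries, WindowSpec
from .exceptions import (
    InvalidParameterError,
    SegmentationError,
    TooShortError,
    WindowBoundsError,
)
from .synthetic import SessionRecording

__all__ = [
    "differentiate",
    "lowpass_ideal",
    "segment",
    "split_fixations",
    "DEFAULT_WINDOWS",
]


def differentiate(position: TimeSeries) -> TimeSeries:
    """Two-point (forward-difference) differentiation.

    ``v[i] = (x[i+1] - x[i]) / dt`` with dt in milliseconds, so degrees
    become deg/ms.  The output is one sample shorter than the input; a raw
    position series yields a velocity series labelled ``BNR``.
    """
    if position.n < 2:
        raise TooShortError("differentiation needs at least 2 samples")
    v = np.diff(position.values) / position.dt_ms
    units = f"{position.units}/ms" if "/" not in position.units else position.units
    condition = "BNR" if position.condition == "raw" else position.condition
    return TimeSeries(v, rate=position.rate, units=units, condition=condition)


def lowpass_ideal(series: TimeSeries, cutoff: float = 50.0) -> TimeSeries:
    """Ideal (brick-wall) low-pass filter via the DFT.

    Frequency bins strictly above ``cutoff`` Hz are zeroed; the bin at
    exactly the cutoff and the DC bin are kept, so the mean is preserved.
    The filter is a spectral projection, hence idempotent.  Output condition
    is ``ANR``.
    """
    if not cutoff < series.rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {series.rate / 2} Hz"
        )
    spectrum = np.fft.rfft(series.values)
    freqs = np.fft.rfftfreq(series.n, d=series.dt_s)
    spectrum[freqs > cutoff * (1 + 1e-12)] = 0.0
    filtered = np.fft.irfft(spectrum, n=series.n)
    return TimeSeries(filtered, rate=series.rate, units=series.units, condition="ANR")


def segment(series: TimeSeries, windows: tuple[WindowSpec, ...] | None = None) -> list[TimeSeries]:
    """Cut a series into the given 1-based inclusive windows (copies).

    Default windows are the three fixation scopes <1...700>, <700...1500>,
    <1500...2999>.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    out = []
    for w in windows:
        if w.end > series.n:
            raise WindowBoundsError(
                f"window {w.label()} exceeds series length {series.n}"
            )
        out.append(series.with_values(series.values[w.slice()].copy()))
    return out


def split_fixations(recording: SessionRecording) -> list[TimeSeries]:
    """Split a session into its stimulus-locked position segments.

    Returns one position series per scheduled location (29 segments of 3000
    samples for the default schedule).
    """
    ts = recording.horizontal_position
    n_per = recording.samples_per_fixation
    n_expected = n_per * recording.schedule.n_points
    if ts.n != n_expected:
        raise SegmentationError(
            f"recording has {ts.n} samples but the schedule demands "
            f"{recording.schedule.n_points} x {n_per} = {n_expected}"
        )
    return [
        ts.with_values(ts.values[k * n_per : (k + 1) * n_per].copy())
        for k in range(recording.schedule.n_points)
    ]
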