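"""Core containers: uniformly sampled scalar signals and analysis windows.

A :class:`TimeSeries` is the object every stage of the package consumes and
produces: a 1-D array of finite samples together with its sampling rate, its
physical units (``deg`` for gaze position, ``deg/ms`` for velocity) and a
``condition`` label distinguishing raw position from velocity before (``BNR``)
and after (``ANR``) noise reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidParameterError, TooShortError, WindowBoundsError

__all__ = ["TimeSeries", "WindowSpec", "DEFAULT_WINDOWS"]


@dataclass
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : array-like of float
        The samples, in temporal order.  Must be 1-D, finite, length >= 2.
    rate : float
        Sampling rate in Hz (1000 Hz for the jumping-point recordings).
    units : str
        Physical units of the samples, e.g. ``"deg"`` or ``"deg/ms"``.
    condition : str
        One of ``"raw"``, ``"BNR"``, ``"ANR"``.
    """

    values: np.ndarray
    rate: float = 1000.0
    units: str = "deg"
    condition: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidParameterError("TimeSeries values must be 1-D")
        if v.size < 2:
            raise TooShortError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("TimeSeries values must be finite")
        if not self.rate > 0:
            raise InvalidParameterError("sampling rate must be positive")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt_s(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.rate

    @property
    def dt_ms(self) -> float:
        """Sample interval in milliseconds."""
        return 1000.0 / self.rate

    def std(self) -> float:
        """Sample standard deviation (n-1 denominator, as in R's ``sd``)."""
        return float(np.std(self.values, ddof=1))

    def with_values(self, values: np.ndarray, **changes) -> "TimeSeries":
        """Copy of this series with new samples (and optional field changes)."""
        out = replace(self, values=np.asarray(values, dtype=float))
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class WindowSpec:
    """A 1-based, inclusive-on-both-ends sample window ``<start...end>``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise WindowBoundsError(f"window start must be >= 1, got {self.start}")
        if self.end <= self.start:
            raise WindowBoundsError(
                f"window end must exceed start, got <{self.start}...{self.end}>"
            )

    @property
    def length(self) -> int:
        """Number of samples covered (inclusive endpoints)."""
        return self.end - self.start + 1

    def slice(self) -> slice:
        """0-based half-open slice equivalent to the 1-based inclusive window."""
        return slice(self.start - 1, self.end)

    def label(self) -> str:
        return f"<{self.start}...{self.end}>"


#: The three fixation analysis windows, written exactly as bracketed in the
#: study design: <1...700>, <700...1500>, <1500...2999> (1-based inclusive,
#: hence lengths 700, 801 and 1500 with one shared boundary sample).
DEFAULT_WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec(1, 700),
    WindowSpec(700, 1500),
    WindowSpec(1500, 2999),
)
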