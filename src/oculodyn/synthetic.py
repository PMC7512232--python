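"""Synthetic jumping-point sessions and canonical reference signals.

The experiment this package analyses shows a small dot at 29 successive
screen locations, each displayed for 3000 ms, while gaze position is sampled
at 1000 Hz.  No public recordings exist, so this module emulates the study
conditions: stimulus-locked fixations preceded by a saccadic-latency period
(90-120, 135-170 or 200-220 ms), a short ballistic saccade, fixational
micro-motion (drift and band-limited tremor) and broadband measurement noise
whose energy extends well above the 50 Hz noise-reduction cutoff.

It also generates canonical reference signals (Henon, Lorenz, sine, white
noise, AR(1)) whose dynamical invariants are known, used to validate the
estimators downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries
from .exceptions import (
    InvalidParameterError,
    NumericOverflowError,
    SegmentationError,
)

__all__ = [
    "ScreenGeometry",
    "StimulusSchedule",
    "OculomotorParams",
    "SessionRecording",
    "REFERENCE_PROPERTIES",
    "default_schedule",
    "generate_session",
    "generate_reference",
    "write_session",
    "read_session",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used to map screen coordinates to degrees.

    Defaults: 370 mm x 295 mm screen viewed from 450 mm, i.e. roughly
    40 x 32 degrees of visual angle.
    """

    width_mm: float = 370.0
    height_mm: float = 295.0
    distance_mm: float = 450.0

    def x_to_deg(self, x: np.ndarray | float) -> np.ndarray | float:
        """Horizontal screen coordinate in [0, 1] -> degrees of visual angle.

        The screen centre maps to 0 deg; the mapping is the exact
        flat-screen geometry ``atan((x - 0.5) * width / distance)``.
        """
        return np.degrees(np.arctan2((np.asarray(x) - 0.5) * self.width_mm, self.distance_mm))


@dataclass
class StimulusSchedule:
    """Locations and timing of the jumping point.

    ``locations`` are (x, y) pairs in the universal screen scale
    [0,1] x [0,1] with (0,0) the top-left corner; ``onset_times`` in ms are
    strictly increasing; each location is displayed for ``display_duration``
    ms (3000 by default).
    """

    locations: np.ndarray
    onset_times: np.ndarray
    display_duration: float = 3000.0

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        ons = np.asarray(self.onset_times, dtype=float)
        if loc.ndim != 2 or loc.shape[1] != 2:
            raise InvalidParameterError("locations must be an (n, 2) array")
        if np.any(loc < 0) or np.any(loc > 1):
            raise InvalidParameterError("locations must lie in [0,1] x [0,1]")
        if ons.shape != (loc.shape[0],):
            raise InvalidParameterError("one onset time per location required")
        if np.any(np.diff(ons) <= 0):
            raise InvalidParameterError("onset times must be strictly increasing")
        if not self.display_duration > 0:
            raise InvalidParameterError("display duration must be positive")
        self.locations = loc
        self.onset_times = ons

    @property
    def n_points(self) -> int:
        return self.locations.shape[0]


def default_schedule(
    n_points: int = 29, display_duration: float = 3000.0, seed: int = 2901
) -> StimulusSchedule:
    """The default 29-location schedule.

    The published layout is not tabulated, so locations are a fixed
    pseudo-random spread over the central [0.05, 0.95]^2 region of the
    screen, reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    locations = 0.05 + 0.9 * rng.random((n_points, 2))
    onsets = np.arange(n_points) * display_duration
    return StimulusSchedule(locations, onsets, display_duration)


@dataclass
class OculomotorParams:
    """Kinematic and noise parameters of the emulated oculomotor signal.

    Parameters
    ----------
    latency_ranges : tuple of (lo, hi) pairs, ms
        Saccadic latency is drawn uniformly within one of these ranges,
        the range itself chosen uniformly per saccade.  Defaults are the
        three classical latency bands 90-120, 135-170 and 200-220 ms.
    saccade_duration_ms : float
        Duration of the minimum-jerk saccade profile (40 ms).
    fixation_drift_sd : float
        Per-sample standard deviation (deg) of the random-walk drift
        during fixation; at 1000 Hz this is deg/ms.
    tremor_amplitude : float
        RMS amplitude (deg) of the band-limited tremor component.
    tremor_band : (float, float)
        Tremor frequency band in Hz; the default 60-100 Hz lies above the
        50 Hz cutoff, so noise reduction should remove it.
    measurement_noise_sd : float
        Standard deviation (deg) of white (flat to Nyquist) sensor noise.
    """

    latency_ranges: tuple = ((90.0, 120.0), (135.0, 170.0), (200.0, 220.0))
    saccade_duration_ms: float = 40.0
    fixation_drift_sd: float = 1e-4
    tremor_amplitude: float = 1e-3
    tremor_band: tuple = (60.0, 100.0)
    measurement_noise_sd: float = 1.5e-3

    def __post_init__(self) -> None:
        for a in (
            self.saccade_duration_ms,
            self.fixation_drift_sd,
            self.tremor_amplitude,
            self.measurement_noise_sd,
        ):
            if a < 0:
                raise InvalidParameterError("amplitudes and durations must be >= 0")
        for lo, hi in self.latency_ranges:
            if lo < 0 or hi < lo:
                raise InvalidParameterError("latency ranges must satisfy 0 <= lo <= hi")
        if not (0 <= self.tremor_band[0] < self.tremor_band[1]):
            raise InvalidParameterError("tremor band must be an increasing pair of Hz")


@dataclass
class SessionRecording:
    """One recorded session: horizontal gaze position plus its schedule."""

    horizontal_position: TimeSeries
    schedule: StimulusSchedule
    subject_id: str = "s00"
    session_id: str = "r00"

    @property
    def samples_per_fixation(self) -> int:
        return int(round(self.schedule.display_duration * self.horizontal_position.rate / 1000.0))


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on u in [0, 1]."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _band_limited_noise(rng, n: int, rate: float, band, rms: float) -> np.ndarray:
    """Gaussian noise restricted to a frequency band, scaled to a target RMS."""
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    shaped = np.fft.irfft(spec, n=n)
    power = np.sqrt(np.mean(shaped**2))
    if power == 0:
        return np.zeros(n)
    return shaped * (rms / power)


def generate_session(
    schedule: StimulusSchedule,
    params: OculomotorParams,
    seed: int,
    geometry: ScreenGeometry = ScreenGeometry(),
    rate: float = 1000.0,
    subject_id: str = "s00",
    session_id: str = "r00",
) -> SessionRecording:
    """Simulate one jumping-point session.

    For each stimulus onset the eye holds its previous position for the
    sampled saccadic latency, executes a minimum-jerk saccade to the new
    target, then fixates there; random-walk drift, band-limited tremor and
    white measurement noise are superimposed on the whole trace.  The output
    is a pure function of ``(schedule, params, geometry, seed)``.
    """
    if not rate > 0:
        raise InvalidParameterError("rate must be positive")
    dt_ms = 1000.0 / rate
    n_per = int(round(schedule.display_duration / dt_ms))
    if n_per <= 0:
        raise InvalidParameterError("display duration shorter than one sample")
    n_total = n_per * schedule.n_points
    sac_samples = int(round(params.saccade_duration_ms / dt_ms))
    for lo, hi in params.latency_ranges:
        if hi + params.saccade_duration_ms >= schedule.display_duration:
            raise InvalidParameterError(
                "latency + saccade duration must fit within the display window"
            )

    rng = np.random.default_rng(seed)
    targets_deg = np.asarray(geometry.x_to_deg(schedule.locations[:, 0]), dtype=float)

    # deterministic piecewise trajectory: hold -> minimum-jerk saccade -> hold
    trace = np.empty(n_total)
    prev = float(geometry.x_to_deg(0.5))
    for k in range(schedule.n_points):
        lo, hi = params.latency_ranges[rng.integers(len(params.latency_ranges))]
        latency_samples = int(round(rng.uniform(lo, hi) / dt_ms))
        start = k * n_per
        s0 = start + latency_samples
        s1 = min(s0 + sac_samples, n_total)
        trace[start:s0] = prev
        if s1 > s0:
            u = (np.arange(s0, s1) - s0 + 1) / (s1 - s0)
            trace[s0:s1] = prev + (targets_deg[k] - prev) * _minimum_jerk(u)
        trace[s1 : start + n_per] = targets_deg[k]
        prev = targets_deg[k]

    drift = np.cumsum(rng.normal(0.0, params.fixation_drift_sd, n_total))
    tremor = _band_limited_noise(rng, n_total, rate, params.tremor_band, params.tremor_amplitude)
    noise = rng.normal(0.0, params.measurement_noise_sd, n_total) if params.measurement_noise_sd else 0.0

    position = TimeSeries(trace + drift + tremor + noise, rate=rate, units="deg", condition="raw")
    return SessionRecording(position, schedule, subject_id=subject_id, session_id=session_id)


#: Literature invariants of the reference systems, used as sanity bands in
#: tests (they are not computed by this package).
REFERENCE_PROPERTIES: dict[str, dict[str, float]] = {
    "henon": {"d2": 1.22, "lle_per_iterate": 0.419},
    "lorenz": {"d2": 2.06, "lle_per_time_unit": 0.906},
    "sine": {"d2": 1.0, "k2": 0.0},
    "white_noise": {"k2": math.inf},
    "ar1": {},
}


def _henon(n: int, a: float, b: float, x0: float, y0: float, discard: int) -> np.ndarray:
    out = np.empty(n)
    x, y = x0, y0
    for i in range(-discard, n):
        x, y = 1.0 - a * x * x + y, b * x
        if abs(x) > 1e6:
            raise NumericOverflowError("henon trajectory diverged")
        if i >= 0:
            out[i] = x
    return out


def _lorenz(n: int, sigma: float, rho: float, beta: float, state0, dt: float, transient: float) -> np.ndarray:
    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    s = np.asarray(state0, dtype=float)
    n_transient = int(round(transient / dt))
    out = np.empty(n)
    for i in range(-n_transient, n):
        # classical fixed-step 4th-order Runge-Kutta
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(s)) or np.any(np.abs(s) > 1e6):
            raise NumericOverflowError("lorenz trajectory diverged")
        if i >= 0:
            out[i] = s[0]
    return out


def generate_reference(
    kind: str,
    n: int,
    params: dict | None = None,
    seed: int = 0,
    rate: float = 1000.0,
) -> TimeSeries:
    """Generate a canonical reference signal of known dynamical character.

    Kinds
    -----
    ``sine``
        ``sin(2 pi f t)`` sampled at ``rate``; ``params``: ``frequency``
        (default 10 Hz), ``amplitude`` (1.0).
    ``white_noise``
        i.i.d. Gaussian samples, ``params``: ``sd`` (1.0).
    ``ar1``
        Gaussian AR(1), ``params``: ``phi`` (0.9), ``sd`` (innovation, 1.0).
    ``henon``
        x-iterates of the Henon map ``x' = 1 - a x^2 + y, y' = b x``
        (a=1.4, b=0.3), 1000 transients discarded, initial condition jittered
        from ``seed``.
    ``lorenz``
        x-coordinate of the Lorenz-63 flow (sigma=10, rho=28, beta=8/3),
        RK4 at fixed step 0.01, sampled every step after a 10-time-unit
        transient; the returned ``rate`` is 1/0.01 = 100 samples per unit.
    """
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    if kind == "sine":
        f = p.get("frequency", 10.0)
        amp = p.get("amplitude", 1.0)
        t = np.arange(n) / rate
        return TimeSeries(amp * np.sin(2 * np.pi * f * t), rate=rate, units="a.u.")
    if kind == "white_noise":
        sd = p.get("sd", 1.0)
        return TimeSeries(rng.normal(0.0, sd, n), rate=rate, units="a.u.")
    if kind == "ar1":
        phi = p.get("phi", 0.9)
        sd = p.get("sd", 1.0)
        eps = rng.normal(0.0, sd, n + 100)
        x = np.empty(n + 100)
        x[0] = eps[0] / math.sqrt(max(1e-12, 1 - phi**2))
        for i in range(1, n + 100):
            x[i] = phi * x[i - 1] + eps[i]
        return TimeSeries(x[100:], rate=rate, units="a.u.")
    if kind == "henon":
        a = p.get("a", 1.4)
        b = p.get("b", 0.3)
        x0 = 0.1 + 1e-3 * rng.standard_normal()
        y0 = 0.1 + 1e-3 * rng.standard_normal()
        return TimeSeries(_henon(n, a, b, x0, y0, discard=1000), rate=rate, units="a.u.")
    if kind == "lorenz":
        state0 = np.array([1.0, 1.0, 20.0]) + 0.1 * rng.standard_normal(3)
        values = _lorenz(
            n,
            p.get("sigma", 10.0),
            p.get("rho", 28.0),
            p.get("beta", 8.0 / 3.0),
            state0,
            dt=p.get("dt", 0.01),
            transient=p.get("transient", 10.0),
        )
        return TimeSeries(values, rate=1.0 / p.get("dt", 0.01), units="a.u.")
    raise InvalidParameterError(f"unknown reference kind: {kind!r}")


def write_session(recording: SessionRecording, out_dir: str | Path) -> Path:
    """Write a session as CSV (time_ms, x_position_deg) + JSON schedule sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{recording.subject_id}_{recording.session_id}"
    ts = recording.horizontal_position
    df = pd.DataFrame(
        {"time_ms": np.arange(ts.n) * ts.dt_ms, "x_position_deg": ts.values}
    )
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "rate_hz": ts.rate,
        "display_duration_ms": recording.schedule.display_duration,
        "locations": recording.schedule.locations.tolist(),
        "onset_times_ms": recording.schedule.onset_times.tolist(),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path


def read_session(csv_path: str | Path) -> SessionRecording:
    """Read a session written by :func:`write_session`."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SegmentationError(f"missing schedule sidecar for {csv_path.name}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    ts = TimeSeries(
        df["x_position_deg"].to_numpy(), rate=meta["rate_hz"], units="deg", condition="raw"
    )
    schedule = StimulusSchedule(
        np.asarray(meta["locations"]),
        np.asarray(meta["onset_times_ms"]),
        meta["display_duration_ms"],
    )
    return SessionRecording(
        ts, schedule, subject_id=meta["subject_id"], session_id=meta["session_id"]
    )
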