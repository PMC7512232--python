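"""FFT surrogate data and the linear-stochastic null-hypothesis test.

A phase-randomised (FFT) surrogate keeps the amplitude spectrum of the
original series and scrambles all phase information, so it is a realisation
of the null hypothesis "the series is a linear Gaussian stochastic process".
If the original series shows a convergent correlation-dimension plateau
across embedding dimensions while its surrogates do not, that null is
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TimeSeries
from .exceptions import OculodynError, TooShortError
from .invariants import InvariantEstimate, correlation_sums, estimate_d2, radius_grid

__all__ = [
    "SurrogateEnsemble",
    "D2AnalysisConfig",
    "SurrogateTestResult",
    "fft_surrogate",
    "surrogate_ensemble",
    "surrogate_d2_test",
]


@dataclass
class SurrogateEnsemble:
    """A set of FFT surrogates of one original series."""

    original_id: str
    surrogates: list[TimeSeries]
    seed: int


def fft_surrogate(series: TimeSeries, seed: int | np.random.Generator = 0) -> TimeSeries:
    """Phase-randomised surrogate preserving the amplitude spectrum.

    The DFT magnitudes are kept; phases of all non-DC, non-Nyquist bins are
    replaced by uniform random phases (Hermitian symmetry is implicit in the
    real inverse transform).  The DC and Nyquist coefficients are left
    untouched, so the mean is preserved exactly.
    """
    if series.n < 8:
        raise TooShortError("surrogate generation needs at least 8 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectrum = np.fft.rfft(series.values)
    n_bins = spectrum.size
    randomise = slice(1, n_bins - 1) if series.n % 2 == 0 else slice(1, n_bins)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_bins)
    new = spectrum.copy()
    new[randomise] = np.abs(spectrum[randomise]) * np.exp(1j * phases[randomise])
    values = np.fft.irfft(new, n=series.n)
    return series.with_values(values)


def surrogate_ensemble(
    series: TimeSeries, n_surrogates: int = 5, seed: int = 0, original_id: str = "series"
) -> SurrogateEnsemble:
    """Generate a deterministic ensemble of FFT surrogates (default 5)."""
    children = np.random.SeedSequence(seed).spawn(n_surrogates)
    surrogates = [fft_surrogate(series, np.random.default_rng(c)) for c in children]
    return SurrogateEnsemble(original_id=original_id, surrogates=surrogates, seed=seed)


@dataclass
class D2AnalysisConfig:
    """Parameters of the correlation-dimension analysis run on original and
    surrogates in the null test."""

    tau: int = 1
    m_values: tuple = (2, 3, 4, 5, 6)
    theiler_w: int = 10
    n_radii: int = 100
    region: tuple[float, float] | None = None  # None -> lower third of each grid
    plateau_tol: float = 0.2
    required_nonplateau: int = 4  # of 5 surrogates, rebased if members fail


@dataclass
class SurrogateTestResult:
    """Decision record of one surrogate test."""

    rejected: bool
    original: InvariantEstimate
    surrogate_estimates: list[InvariantEstimate]
    n_excluded: int
    k_required: int
    config: D2AnalysisConfig = field(repr=False, default_factory=D2AnalysisConfig)


def _d2_with_config(series: TimeSeries, config: D2AnalysisConfig) -> InvariantEstimate:
    radii = radius_grid(series, config.n_radii)
    result = correlation_sums(
        series, config.tau, config.m_values, radii=radii, theiler_w=config.theiler_w
    )
    return estimate_d2(result, region=config.region, plateau_tol=config.plateau_tol)


def surrogate_d2_test(
    series: TimeSeries,
    ensemble: SurrogateEnsemble | None = None,
    config: D2AnalysisConfig | None = None,
    seed: int = 0,
) -> SurrogateTestResult:
    """Test the linear-stochastic null via correlation-dimension convergence.

    The null is REJECTED when the original series shows an m-plateau of
    log-log slopes (``plateau_found``) while at least ``k`` of the
    surrogates do not (default 4 of 5).  Members on which the estimator
    fails are excluded and ``k`` is rebased to 80% of the surviving ones.
    """
    config = config or D2AnalysisConfig()
    if ensemble is None:
        ensemble = surrogate_ensemble(series, seed=seed)
    original = _d2_with_config(series, config)
    estimates: list[InvariantEstimate] = []
    n_excluded = 0
    for surrogate in ensemble.surrogates:
        try:
            estimates.append(_d2_with_config(surrogate, config))
        except OculodynError:
            n_excluded += 1
    n_valid = len(estimates)
    if n_valid == len(ensemble.surrogates):
        k = config.required_nonplateau
    else:
        k = max(1, int(round(0.8 * n_valid)))
    n_nonplateau = sum(1 for e in estimates if not e.plateau_found)
    rejected = bool(original.plateau_found) and n_valid > 0 and n_nonplateau >= k
    return SurrogateTestResult(
        rejected=rejected,
        original=original,
        surrogate_estimates=estimates,
        n_excluded=n_excluded,
        k_required=k,
        config=config,
    )
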