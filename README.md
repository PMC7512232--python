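# oculodyn

Nonlinear time-series analysis of eye-movement velocity signals: delay-space
reconstruction, correlation dimension, correlation entropy, Lyapunov
exponents, surrogate-data testing and session-level statistics — plus a
synthetic "jumping point" experiment generator so the entire pipeline runs
and is testable without any recordings.

## The problem

During a fixation the eye is never still: drift, tremor and microsaccades
keep the gaze velocity fluctuating. Whether those fluctuations are best
described as filtered noise or as low-dimensional deterministic (possibly
chaotic) dynamics is an open question in oculomotor research. The standard
way to ask it of a scalar signal x(t) sampled at rate 1/Δt is phase-space
reconstruction: form delay vectors

    y(i) = ( x(i), x(i+τ), …, x(i+(m−1)τ) ),   i = 1…M,  M = N − (m−1)τ,

with the lag τ chosen from the first minimum (or 1/e decay) of the averaged
mutual information and the dimension m from the collapse of the
false-nearest-neighbour fraction, then estimate invariants of the
reconstructed dynamics from the Theiler-windowed correlation sum

    C(m, r) = 2 / ((N−w)(N−w−1)) · Σ_i Σ_{j ≥ i+1+w} H( r − ‖y(i) − y(j)‖ ).

* **Correlation dimension** D2 = slope of log C vs log r in its linear
  scaling region, aggregated over embedding dimensions where the slope has
  converged (an m-plateau). Low, non-integer, m-independent values indicate
  a deterministic attractor; slopes that track m indicate space-filling
  noise. The bound D2 ≤ 2 log₁₀ N limits what a finite series can support.
* **Correlation entropy** K2 = ln( C(m, r) / C(m+1, r) ): ~0 for periodic
  signals, positive and finite for chaos, divergent with m for noise.
* **Largest Lyapunov exponent** λ from the mean log-divergence of nearest
  neighbours (Rosenstein's method); λ > 0 signals exponential sensitivity.
* **FFT surrogates** (phase-randomised copies preserving the amplitude
  spectrum) embody the null hypothesis "linear Gaussian stochastic
  process": the null is rejected when the original shows a D2 plateau and
  the surrogates do not.

The package applies this battery to horizontal eye velocity during
stimulus-locked fixations: a dot jumps between 29 screen locations, each
shown 3000 ms at a 1000 Hz sampling rate; two-point differentiation of each
3000-sample position segment gives a 2999-sample velocity series, analysed
both before (BNR) and after (ANR) noise reduction by an ideal 50 Hz
low-pass filter. Per session, fixation-level D2 (at series lengths
1000/1500/2999) and windowed K2 (windows `<1…700>`, `<700…1500>`,
`<1500…2999>`) are compared across conditions with paired Wilcoxon
signed-rank tests, reported as the percentage of significant sessions.

## Worked example

Recovering the invariants of the Hénon map from a single observable:

```python
from oculodyn import (correlation_sums, delay_embed, estimate_d2,
                      generate_reference, lle_rosenstein, sample_size_bound)

henon = generate_reference("henon", 5000, seed=1)
sums = correlation_sums(henon, tau=1, m_values=[2, 3, 4, 5], theiler_w=10)
d2 = estimate_d2(sums)
lle = lle_rosenstein(delay_embed(henon, tau=1, m=2), dt=1.0, theiler_w=10)
print(f"D2  = {d2.value:.3f}  (plateau over m: {sorted(d2.per_m_values)})")
print(f"LLE = {lle.value:.3f} per iterate  (fit R^2 = {lle.fit_quality:.3f})")
print(f"max reliable D2 at N=5000: {sample_size_bound(5000):.2f}")
```

prints

```
D2  = 1.199  (plateau over m: [2, 3, 4, 5])
LLE = 0.403 per iterate  (fit R^2 = 0.999)
max reliable D2 at N=5000: 7.40
```

— the slope plateau near 1.2 (the literature value for the Hénon attractor
is ≈ 1.22) across m = 2…5 is the deterministic signature; the positive
Lyapunov exponent (≈ 0.42 in the literature) confirms chaos; and 5000
samples comfortably support a dimension-1.2 estimate.

The full pipeline runs from the shell:

```bash
oculodyn simulate --sessions 4 --seed 0 --out runs/raw
oculodyn all --sessions 4 --seed 0 --out runs/report
```

`runs/report/` then holds `session_table.csv` (one row per fixation ×
condition × length/window estimate), the four cohort summary tables
(`table_d2_means.csv`, `table_d2_length_significance.csv`,
`table_k2_means.csv`, `table_k2_window_significance.csv`) and a JSON
manifest recording every parameter, estimate and skip reason.

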