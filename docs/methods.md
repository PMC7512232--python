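# Methods

This note documents the estimators, conventions and default parameters the
package uses, the design choices that were genuinely open, and what the
synthetic data can and cannot establish.

## Signals and preprocessing

The analysed object is horizontal eye velocity during stimulus-locked
fixations. A position series (degrees of visual angle, 1000 Hz) is split
into one 3000-sample segment per stimulus location; two-point forward
differencing, `v[i] = (x[i+1] − x[i]) / Δt` with Δt in ms, yields a
2999-sample velocity series in deg/ms — the forward difference is the only
two-point stencil that produces 2999 samples from 3000. Noise reduction is
an ideal (DFT brick-wall) low-pass at 50 Hz applied per velocity series:
bins strictly above the cutoff are zeroed, the bin at exactly the cutoff
and the DC bin are kept, so the filter preserves the mean and is an exact
spectral projection (idempotent). Velocity-domain filtering (rather than
filtering positions before differencing) matches the analysed object being
the velocity series itself.

The three analysis windows are taken literally as printed bracket ranges,
1-based and inclusive on both ends — `<1…700>`, `<700…1500>`,
`<1500…2999>`, lengths 700/801/1500 with one shared boundary sample; the
single-sample overlap is immaterial to the estimators. Length comparisons
(1000/1500/2999) use the leading prefix of each velocity series, the
natural stimulus-locked choice.

## Phase-space reconstruction

**Lag (τ).** Averaged mutual information over lags 0…30, on a 2-D histogram
with Freedman–Diaconis bin width `2·IQR·n^(−1/3)` computed from the full
series. Histogram MI is biased upward for sparse joint histograms
(≈ bins²/(2N ln 2) under independence, ~0.2 bits at n = 5000 here), so each
entropy in I = H_a + H_b − H_ab is computed with the Grassberger
ψ-function estimator and the result clipped at zero; marginals come from
the lagged pair sample, making I symmetric in the pair order. The selected
lag is the *earlier* of the first strict local minimum of the profile and
the lag where AMI falls to I(0)/e. Monotonically decaying profiles have no
minimum before the 1/e point, and sampling fluctuations deep in the tail
can fake one after it; taking the earlier criterion keeps the choice in
the informative part of the profile. In the pipeline τ is additionally
capped so that the largest embedding retains at least half the samples.

**Dimension (m).** False nearest neighbours with the distance-ratio
criterion: the neighbour of y(i) is false when
`|x[i+mτ] − x[nn+mτ]| / ‖y(i) − y(nn)‖ > R`, with R = 10 and Euclidean
norms throughout. The selected m is the smallest with a false fraction
≤ 1%. Nearest-neighbour ties break to the smallest index; candidates
closer than a relative floor of 1e−9 × scale are treated as duplicates and
excluded (exactly periodic signals otherwise produce floating-point
duplicate states whose ~1e−16 distances amplify rounding noise into
spurious ratios). A known limitation: the ratio-only criterion loses power
against pure noise at high m on finite samples (the false fraction decays
once neighbours become uniformly distant); the tests therefore pin the
noise behaviour at small m only.

## Correlation sum and invariants

The Theiler-windowed correlation sum counts pairs (i, j) with
j ≥ i + 1 + w and Euclidean distance ≤ r, normalised by
(M−w)(M−w−1)/2 so that C → 1 at large r; w = 0 recovers the plain sum.
Radii follow the convention r_min = stdev/10, r_max = 10·stdev (sample
stdev, n−1 denominator) with 100 log-spaced values; defaults w = 100 and
m = 3…15 for the cohort analysis. All dimensions in one run share the
vector count of the largest m, so C(m+1, r) ≤ C(m, r) holds exactly and
the K2 ratio is well defined. Counting is a single jitted pass over
admissible pairs that accumulates squared distances coordinate by
coordinate and advances a per-pair bin pointer (the bin index is monotone
in m); its observable output is identical to direct pair enumeration,
which the test suite verifies exactly on random instances. The
multi-dimension entry point requires ≥ 10 admissible pairs; the
single-embedding function accepts tiny inputs (down to one pair) so that
hand-checkable worked examples remain computable.

**D2.** Least-squares slope of log C vs log r per m over radii in the
scaling region where C > 0 (≥ 3 points); the reported value is the median
slope over the longest run of consecutive m whose successive slopes differ
by < 0.2, with the additional self-consistency requirement slope < m — an
attractor dimension is below every embedding dimension that resolves it,
and without this constraint space-filling noise occasionally produces
spurious flat runs once its slopes saturate. If no run of length ≥ 2
survives, the median of all valid slopes is reported with
`plateau_found=False` (that flag, not the value, carries the
determinism/stochasticity verdict). Default scaling regions: BNR
(0.00055, 0.0018) deg/ms and ANR (0.001, 0.003) deg/ms. The BNR pair is
taken from the log-scale form of the printed bounds (−3.26…−2.74), which
contradicts the printed linear pair (0.0018–0.0055); the log form is
internally consistent and is the default, the other reading remains
available through configuration. When a configured absolute region
intersects fewer than 3 radii of a particular series' grid (velocity
scales vary with saccade amplitude), the pipeline falls back to a relative
region — the lower third of that series' grid in log space — and flags the
estimate; one fixed region cannot suit every series, and per-series
adjustment is part of the analysis design.

**K2.** `K2(m) = ln( C(m, r) / C(m+1, r) )` averaged over the region radii
where both sums are positive, then the median over the m-plateau
(successive gaps < 0.02 nats). Values are in nats per embedding step
(i.e., per τ·Δt), unscaled. Note a finite-m property of Euclidean norms:
adding a coordinate inflates distances by ≈ √((m+1)/m), so even an exactly
periodic signal shows K2 ≈ 1/(2m) rather than 0 at moderate m; the
zero-entropy limit is reached only for m of order tens. Cohort K2 values
at m = 3…15 therefore carry this small positive offset by construction —
comparisons across conditions and windows, which is what the statistics
layer tests, are unaffected.

**λ (largest Lyapunov exponent).** Rosenstein's method: each vector is
paired with its nearest neighbour outside the Theiler window (duplicate
states excluded by the same relative floor as above), the mean over pairs
of ln d(k) is tracked for k = 0…30 steps, and λ is the least-squares slope
of that curve over its initial segment (default steps 0…8) divided by Δt.

**Data-length bounds.** `D2 ≤ 2 log₁₀ N` and its inverse
`N ≥ 10^(D2/2)`; the pipeline flags any length-1000 estimate exceeding the
bound 6.

## Surrogate testing

FFT surrogates keep the DFT magnitudes and randomise all non-DC,
non-Nyquist phases (mean preserved exactly; spectrum preserved to machine
precision), embodying the linear-Gaussian null. The decision rule
operationalises "the original converges, the surrogates do not": reject
when the original D2 estimate has `plateau_found=True` while at least k of
the 5 surrogates do not (default k = 4; if estimator failures exclude
members, k rebases to 80% of the survivors). No quantitative
original-vs-surrogate D2 distance is claimed.

## Statistics layer

Shapiro–Wilk p-values are reported as the normality gate that motivates a
non-parametric test; they never branch the analysis. The paired comparison
is the two-sided Wilcoxon signed-rank test over the ≤ 29 fixation-level
estimates within each session — the only pairing unit consistent with one
test per session. Zero differences are dropped (Wilcoxon's original
treatment), ties share average ranks, and the null distribution is
enumerated exactly by dynamic programming for n ≤ 25 (ties included, on a
doubled-rank integer lattice); above that the tie-corrected,
continuity-corrected normal approximation is used. Significance is
summarised as the percentage of sessions with p < α (default 0.05) plus a
p-value histogram in bins of 0.05. No multiple-testing correction by
default, matching raw-α reporting; a Benjamini–Hochberg helper exists but
is off.

## Synthetic sessions

The generator emulates the jumping-point protocol: 29 locations on a
[0,1]² screen (the published layout is not tabulated; a fixed
pseudo-random spread over the central 90% of the screen stands in), each
displayed 3000 ms, sampled at 1000 Hz. Screen geometry (370 × 295 mm at
450 mm, ≈ 40° × 32°) maps screen x to degrees exactly via
atan((x−0.5)·W/D). Per stimulus: saccadic latency drawn uniformly from one
of the three classical bands (90–120, 135–170, 200–220 ms; the band itself
chosen uniformly — no band probabilities are established), a 40 ms
minimum-jerk saccade (any smooth monotone profile suffices; saccade
kinematics are not the object of study), then fixation at the target.
Superimposed on the whole trace: random-walk drift (1e−4 deg per sample),
band-limited tremor (0.001 deg RMS in 60–100 Hz — above the cutoff, so
noise reduction must remove it) and white measurement noise. The noise sd
of 0.0015 deg was chosen once so the resulting velocity-series stdev
(~0.002 deg/ms) is consistent with the printed radius scales of the
analysis (stdev-derived grids vs absolute scaling regions in deg/ms).

What the generator does *not* emulate: microsaccades, oculomotor-plant
dynamics, blink/calibration artefacts, any genuinely chaotic fixational
core, or vertical gaze (generated positions are horizontal only, matching
the analysed channel). Consequently, pipeline runs on synthetic cohorts
validate the *machinery* — counting identities, estimator contracts, table
structure, statistical calibration — not any claim about real eye
movements; estimator validity itself is established on the canonical
reference systems (Hénon, Lorenz, sine, AR(1), white noise) whose
invariants are known. Reference generators are deterministic in
(kind, params, seed); Hénon discards 1000 transients, Lorenz is integrated
with fixed-step classical RK4 (dt = 0.01, 10 time units of transient) to
keep generation dependency-free and bit-reproducible.

## Numerical choices and degenerate inputs

- Constant series raise degenerate-input errors (no radius scale, zero
  IQR); all-zero difference vectors in the Wilcoxon test return p = 1 with
  a degenerate flag.
- Distance comparisons use squared radii (no square roots in the hot
  path); a pair at exactly r counts as within r.
- The correlation-sum kernel runs in float64; numba's fastmath may reorder
  additions, which matters only within ~1 ulp of a radius boundary.
- The pipeline never aborts a cohort: any estimator failure on a series
  records a flagged NaN row and a skip reason in the manifest. Manifests
  contain no timestamps, so identical (config, seed) runs are
  byte-identical.
- Problem sizes in tests and the acceptance script (5000-sample reference
  series, 2–4 session cohorts, 500-session null resamples) were chosen as
  the smallest sizes at which the estimators' asymptotic behaviour is
  already clean.

## Known limitations

- The fixed-region D2/K2 readout assumes comparable velocity scales across
  series; the relative-region fallback (flagged) is the pragmatic remedy.
- K2 carries the finite-m Euclidean offset described above.
- The FNN noise criterion weakens at high m (ratio-only variant).
- The surrogate decision is a plateau-based operationalisation of a
  qualitative convergence judgement; k and the plateau tolerance are
  configurable.
- Session-level percentages on 2–4 synthetic sessions are structural
  smoke checks, not calibrated estimates; the statistical calibration test
  uses 500 simulated null sessions.
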