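# Methods

## Model and assumptions

The package treats the metal⋯¹H(water) distance d(t) sampled along an
MD trajectory as a stationary signal whose fluctuation autocorrelation
carries the motional information needed for dipolar relaxation. Under
the model-free assumption that overall tumbling and internal motion
decorrelate independently, the total correlation function factorizes:

    C(t) = C_O(t) C_I(t)
    C_O(t) = (1/5) exp(−t/τc)
    C_I(t) = S² + (1−S²) exp(−t/τe)

Expanding the product gives the two-exponential normalized form that is
actually fitted to the sample autocorrelation:

    5·C(t) = S² exp(−t/τc) + (1−S²) exp(−t/τ),  1/τ = 1/τc + 1/τe.

The 1/5 prefactor is deliberately kept out of the fit: a normalized
sample ACF starts at 1, so fitting it to C(t) directly would
double-count the prefactor once the spectral-density constants are
applied. `evaluate_model_c` is the only place the 1/5 reappears.

The spectral density is the exact cosine transform of C(t),

    J(ω) = (2/5)[S²τc/(1+τc²ω²) + (1−S²)τ/(1+τ²ω²)]   (seconds),

verified in the tests against adaptive-quadrature cosine transformation
of C(t). Relaxation rates combine J at 0, ω0 and 2ω0, scaled by the
dipolar constant

    K = (μ0/4π)² (3/2) ħ² γ⁴ I(I+1) / φ⁶   (s⁻²),

with φ the mean metal⋯¹H distance (converted from Å to m only here),
and γ the angular gyromagnetic ratio 2π·42.58×10⁶ rad s⁻¹ T⁻¹ of ¹H.

### Equation sets

Two labelled J-combinations are implemented:

* `as_printed` (default):
  R1 = K[J(ω0) + J(2ω0)], R2 = K[4J(0) + 10J(ω0) + J(2ω0)].
  Because J is non-negative and non-increasing, this set satisfies
  R1/R2 ≤ 2/15 for *any* valid parameters (shown by the inequality
  13·J(2ω0) ≤ 8·J(0) + 5·J(ω0); asserted as a property test on random
  parameters). Published R1/R2 values for contrast agents are typically
  ≈ 0.6–0.8, which this combination cannot produce; the bound is
  therefore documented and tested rather than hidden.
* `standard_like_spin`: the conventional like-spin dipolar expressions
  R1 = K[J(ω0) + 4J(2ω0)], R2 = (K/2)[3J(0) + 5J(ω0) + 2J(2ω0)],
  with R1/R2 ≤ 1 and R1/R2 → 1 in extreme narrowing.

The choice is a config/CLI switch; both appear in the artifact metadata
so reported numbers are always attributable to a specific equation set.
`planck_mode` similarly selects ħ² (default, standard dipolar theory)
or h² in K, and `frequency_convention` selects angular ω0 = 2πγB0
(default — the Lorentzians require angular frequency) or cyclic
ν0 = γB0. Temperature is metadata only; it enters none of the formulas.

A `gamma_partner` override replaces γ⁴ by γ²γ_partner² for exploring
heteronuclear coupling; the default keeps the proton-only γ⁴ form.

## Synthetic data generator

No MD trajectories ship with the package, so validation runs on
synthetic distance series with known truth:

    d(t) = φ + σ(√S²·X₁(t) + √(1−S²)·X₂(t)),

with X₁, X₂ independent unit-variance stationary Ornstein–Uhlenbeck
processes with correlation times τc and τ. The normalized fluctuation
ACF is then exactly S²e^(−t/τc) + (1−S²)e^(−t/τ). The OU update is the
exact AR(1) recursion x_{k+1} = x_k·e^(−dt/τ) + ξ√(1−e^(−2dt/τ)), so the
discrete autocorrelation is unbiased at any stride. Both noise streams
are always drawn, so the slow component's path is independent of S².

Defaults: n = 2000 frames at dt = 100 ps (200 ns total — the sampling
regime of a production contrast-agent simulation, with the stride
chosen so that 2000 stored conformations span the run), φ = 3.2 Å,
σ = 0.15 Å, S² = 0.85, τc = 1000 ps, τe = 50 ps. The distance scale
matches hydration distances at a vanadyl site (≈3.2–5.6 Å); the
dynamical parameters are plausible for a small solvated complex and are
synthetic choices, not measured values.

What the generator does *not* emulate: excluded-volume effects (the
Gaussian fluctuation model allows, with vanishing probability under the
default φ > 3σ constraint, unphysically short distances), proton
exchange between hydration shells, periodic-boundary artifacts, and any
protein-induced non-stationarity. Passing tests therefore demonstrate
correctness of the estimators on the stated stochastic model, not the
fidelity of any force field.

The coordinate-frame generator places the vanadium site at the origin
and one proton at the trajectory distance per frame, with decoy protons
at least 2 Å farther (unambiguous minimum), and writes multi-model PDB
and XYZ through MDAnalysis; nearest-proton extraction then recovers the
generating series to format precision (≈5×10⁻⁴ Å for fixed-width PDB).

## Wavelet selection (OWSCA)

The distance signal is edge-padded to the next power of two (edge
replication avoids the spurious boundary detail coefficients that
zero-padding creates) and decomposed with the orthonormal Haar (db1)
wavelet at full depth via PyWavelets' periodization mode, which makes
the transform exactly orthonormal: Parseval holds to 1e−9 relative and
reconstruction to 1e−10, both asserted.

Selection ranks detail coefficients globally by squared magnitude and
keeps the smallest prefix reaching `energy_fraction` of the total
*detail* (fluctuation) energy; the coarsest approximation coefficients
are always kept, since they carry the mean level rather than dynamics.
Each retained coefficient maps to the frame at the midpoint of its
dyadic support [k·2ʲ, (k+1)·2ʲ); midpoints falling in the padded tail
clamp to the last real frame; the mapped set is deduplicated and
sorted, and the count is clamped to [min_keep, max_keep] by adding or
dropping the next-ranked detail mappings. Everything is deterministic;
magnitude ties break toward finer levels and earlier positions via a
stable sort.

The shipped default `energy_fraction = 0.65` is a calibration: it is
the value at which the median retained count over twenty seeded default
trajectories sits at ≈108, the centre of the ≈100-conformation band a
2000-frame trajectory is expected to compress into, and it is stable
(≈104–117) across independent seed sets. The calibration experiment is
itself a test. Raising the fraction never decreases the count
(monotonicity is asserted). Compressed-signal error obeys the Parseval
bound: dropping coefficients carrying a fraction ε of the energy costs
at most √ε relative L2 error.

## Autocorrelation estimation and fitting

The sample ACF of the mean-centred distances is computed via FFT
(Wiener–Khinchin) with zero-padding to ≥2N so the circular correlation
never wraps, per-lag pair-count ("unbiased") normalization, and
normalization by the lag-0 value; the O(N²) direct lag-sum estimator is
kept as an independent oracle and both agree to 1e−10. Lags default to
N/2. A series whose fluctuations are below 1e−12 of its magnitude is
rejected as constant ("no fluctuations to correlate").

For wavelet-selected (non-uniformly spaced) frames, two estimates are
available:

* **lag-binned** (default): all pairs among selected frames, binned by
  true time lag. Selected frames remain on the parent grid, so with the
  parent stride as bin width each bin is an exact lag class — no
  timescale distortion; empty interior bins are interpolated and carry
  zero weight in the fit.
* **re-grid**: the selection re-labelled onto the endpoint-preserving
  uniform stride dt_eff = (t_last − t_first)/(m−1), then the FFT
  estimator. Simple, but relabelling non-uniform samples distorts
  apparent timescales; it is kept as an explicit option
  (`selected_acf_mode="regrid"`), not the default.

The model-free fit minimizes pair-count-weighted (√n_pairs) least
squares of the two-exponential form over lags up to
`max_lag_fraction = 0.2` of the observation span (sample-ACF variance
grows with lag). Bounds: S² ∈ [0,1], τc ∈ [dt, 10T], τe ∈ [dt/10, 10T];
τ < min(τc, τe) holds automatically through the harmonic relation.
Because a noisy sample ACF offers a degenerate ridge — S² → 0 with τc
absorbed into τ mimics the rigid solution — the fit is multi-start
(five spread initializations, including τc at the 1/e crossing of the
ACF), keeping the best-cost solution; among solutions of numerically
equal cost (within rms 1e−9) the largest-S² (rigid) reading is
preferred, which also resolves the exactly-degenerate single-exponential
case. S² ≥ 0.99 or any parameter at a bound sets the `at_boundary`
flag; at the S² boundary τe is unidentifiable and flagged as a
placeholder.

On noiseless model curves the fit recovers all three parameters to
0.1%; at ACF noise of sd 0.01 on a lag grid resolving τ, τc and S² come
back within 5% in ≥90 of 100 seeds (in practice 100/100). When the lag
grid does not resolve τ (e.g. τ ≈ 48 ps sampled at 100 ps), τe is
legitimately unidentifiable and only τc and S² are recoverable — the
Monte-Carlo tests therefore use a resolving grid for the three-parameter
claim.

### Statistical precision at the default sampling

With n·dt/(2τc) ≈ 100 effective samples, a single default trajectory
determines τc (hence R1, R2) only to roughly 10–30%. End-to-end
accuracy claims are therefore made for the *median* over twenty seeded
runs, which tracks the analytic ground-truth rates within 10%; the
same aggregation is used when comparing the full-trajectory and
selected-subset routes (medians of fitted τc agree within a few
percent, asserted at 20%).

## Pipeline

`run_pipeline` chains read → select → ACF → fit → rates and is a pure
composition of the module operations (asserted by re-running stages by
hand). φ is taken over the same frame set the ACF uses (full trajectory
or selection). Every artifact records the SHA-256 configuration hash
and seed; deterministic stages are bit-identical on rerun. Stage
failures propagate with the stage name (`PipelineStageError`).
`acf_source` defaults to `full`; the selected route is one switch away
and is the route an OWSCA-reduced analysis would take.

## Numerical choices and degenerate inputs

* Distance series must have ≥8 frames, uniform stride (1e−6 relative),
  strictly positive distances; violations name the offending row.
* Constant series are accepted as trajectories (and by the selection)
  but rejected by the ACF with a clear message; the pipeline aborts at
  the ACF stage for σ = 0 inputs.
* Sparse lag-class values are clipped to [−1, 1] before validation;
  their fit weight is proportionally small, so the clipping is
  inconsequential.
* Only the Haar wavelet is supported; other names are rejected rather
  than silently accepted, because the dyadic-support frame mapping and
  the discontinuity-friendly profile are Haar-specific.

## Known limitations

* No binary trajectory formats (DCD/XTC/NetCDF) and no minimum-image
  handling — synthetic fixtures are aperiodic; real periodic
  trajectories should be unwrapped or distance-extracted upstream.
* The coefficient-to-conformation rule (support midpoints) and the
  global (not per-level) energy thresholding are design choices; other
  published wavelet-selection implementations may differ in both.
* Electron-spin (Solomon–Bloembergen–Morgan) theory, chemical exchange
  and outer-sphere contributions are out of scope: the rate expressions
  here are the two labelled dipolar J-combinations only.
* The fit assumes a single slow timescale; multi-exponential (>2)
  internal motion is not modelled.
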