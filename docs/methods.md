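# Methods notes

This document records the models implemented in `nrf2net`, the assumptions
behind them, and the design choices made where the underlying experimental
protocols leave the numerical procedure open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Binding equilibrium

All simulated binding follows 1:1 mass action.  For totals *A*, *B* and
dissociation constant *K* the complex concentration is the physical root of
the quadratic `C² − (A+B+K)C + AB = 0`, evaluated in the cancellation-safe
form `C = 2AB/(A+B+K+√((A+B+K)²−4AB))`.  Mass balance holds to 1e-9
relative and the K_d relation (`free·free/complex = K`) to 1e-6 relative
over nine orders of magnitude; both are enforced by tests.  The limits are
exact: `K = 0` gives the limiting total, `K → ∞` gives zero complex.

## 2. FCCS

### 2.1 Correlation models

Autocorrelations use the two-component 3D diffusion model with a triplet
factor; cross-correlations use the same diffusion law with the triplet term
forced off, because dark-state blinking is uncorrelated between spectrally
distinct fluorophores.  The structure parameter *s* (axial/lateral ratio)
is carried by the `ConfocalVolume` and treated as a calibration constant,
not a free fit parameter: floating *s* against single curves is poorly
identified, and instrument calibration fixes it in practice.

### 2.2 Multi-tau correlator

`multitau_correlate` evaluates the exact single-lag estimator
`G(k) = Σₜ δa(t)δb(t+k) / ((n−k)·ā·b̄)` on a multi-tau lag ladder (dense
up to `m` lags, spacing doubling per level, capped at n/4).  Classical
multi-tau hardware averages products of progressively binned traces, which
triangularly smooths long-lag values; here the ladder only defines the lag
schedule and each value is computed exactly (via FFT), so the estimator is
bit-comparable to a direct correlator.  This choice makes the correlator
verifiable against a brute-force oracle to 1e-12 and removes an estimator
bias at no relevant cost at desk scale.  Zero-mean traces raise a
`CorrelationNormalizationError` rather than propagating NaN.

### 2.3 Curve fitting

Weighted least squares (weights 1/sem where all sem > 0, else unweighted)
using `scipy.optimize.least_squares` (trust-region reflective with bounds —
the same Gauss–Newton/LM family as classical FCS fitting).  Initialisation:
amplitude from the mean of the three smallest lags, diffusion time from the
half-amplitude lag, T = 0.1, τ_T = 5 µs.  Because the two-component model
has fast/slow permutation minima, up to six perturbed restarts are run; a
solution is accepted early when the residual is exactly zero (noise-free
data) or, for weighted fits, when the reduced chi-square falls below 3.
Components are re-ordered so `τ_fast ≤ τ_slow` after fitting.
Non-convergence (iteration budget exhausted) is flagged on the result, not
raised; a singular Gauss–Newton covariance is flagged likewise.

### 2.4 Amplitudes to concentrations

`c_total = 1/(V_eff·N_A·G_auto(0))` per channel,
`c_complex = G_cross(0)/(V_eff·N_A·G_g(0)·G_r(0))`, bound fractions
`G_cross(0)/G_other(0)`.  Fractions are clipped to [0, 1] with a `clipped`
flag; an apparent complex exceeding the limiting total beyond 1e-6 relative
raises an `inconsistent` flag and is clipped so mass balance is preserved
(clipping rather than exclusion keeps weak-expression cells in the isotherm
with a visible audit trail).

### 2.5 K_d isotherm

Bound fractions are fitted against the *same cell's* free-partner
concentration (no pooling or binning across cells), separately in both
labelling orientations; K_d is the unweighted arithmetic mean of the two
one-parameter fits.  Each one-dimensional fit is solved by bounded scalar
minimisation over log10 K in [−3, 9], which is robust (no starting value)
and fast enough to sit inside the bootstrap.  The 95% CI is a nonparametric
bootstrap over cells (percentile method, default 1000 resamples, seeded).
A partner whose bound fractions never rise above noise returns the
non-binder sentinel (`K_d = ∞`, `binder_flag = False`).  The positive-binder
threshold defaults to 10,000 nM, the conventional boundary below which
partners are treated as genuine (weak binders sit above it).

### 2.6 Quality control

Default inclusion rules: positive autocorrelation amplitudes, counts per
molecule ≥ 0.5 kHz on every curve that reports one (half the ~1 kHz
operating point), all supplied fits converged, no amplitude inconsistency.
Failures carry reason codes and are excluded from the isotherm.

## 3. Synthetic data

The generators state a fixed world and are not tuned to tests:

* **Expression**: per-cell totals are log-normal per channel, default
  `10^N(2.5, 0.5)` nM (centre ≈ 300 nM, one order of magnitude across
  cells).  Low-amount transient transfection produces broad cell-to-cell
  variation; the exact in-vivo range is not published, so this default is a
  field-plausible choice documented here rather than an inferred value.
* **Curve noise**: zero-mean Gaussian per lag with
  `sd = noise_sd_scale·(G(0)/√n_segments)·(1+τ/τ_D)^(−1/2)`, where τ_D is
  the fraction-weighted mean diffusion time.  This is the standard
  amplitude-proportional FCS noise shape; the vendor-software export noise
  model is not documented anywhere, so a simple declared model keeps the
  fitting weights well defined.  `n_segments = 5` represents the averaging
  of five repeated 2 s measurements per cell as a 1/√5 noise factor rather
  than as literal time-resolved segments.
* **Brownian oracle**: point emitters in a periodic box ≥ 10 beam waists
  wide, Gaussian detection profile `exp(−2(x²+y²)/w0² − 2z²/(s·w0)²)`,
  Poisson counts per bin; complexes emit in both channels.  Photophysics
  (blinking, bleaching, afterpulsing) is deliberately absent — the oracle
  validates diffusion and correlation, and triplet behaviour enters only
  through the analytic model term.  Desk-scale guards: ≤ 200 particles,
  ≤ 2^20 steps.
* **DULIP wells**: input luminescence ∝ total tagged protein, bound
  luminescence ∝ captured bait and equilibrium complex, multiplicative
  log-normal well noise (default CV 10%).  Unit gains and full capture make
  assay units coincide numerically with nM, so recovery is checkable
  without a gain-calibration step.  The default prey saturation series is
  centred on K_d but clipped to 10 nM–30 µM, the attainable expression
  range.
* **Reporter screens**: every plate carries all condition × cell-line
  combinations; the latent well value is the fixed-effect sum plus
  `N(0, σ_plate²)` per plate and `N(0, σ_resid²)` per well.  Raw `fl`/`rl`
  columns are emitted consistently so the normalisation step can be
  exercised on the same data.
* **Y2H**: a true edge grows in a replicate with probability *p*; both
  reporters then score growth (one shared activation event per replicate),
  so the expected positive rate under the two-replicate rule is *p²*.

What a green test does *not* establish: real curves have correlated
residuals, photobleaching trends, background and cross-talk; real DULIP
has plate-position and capture-chemistry effects; real screens have
non-Gaussian outliers.  None of these are modelled, so recovery here
validates the estimators' correctness, not their robustness to every
laboratory artefact.

## 4. DULIP quantification

NIR = (bound FL/RL)/(input FL/RL); cNIR divides by a negative-control
pair's NIR.  The published protocol defers the exact normalisation to its
methodological lineage and notes modifications without detail, so both
formulas are explicit, documented functions that can be swapped.

The assay-unit K estimate fits `b = S_free/(S_free + K)` with
`b = FL_bound/(α·RL_bound)` (capture normalisation) and
`S_free = FL_input − β·FL_bound` (depletion correction); α and β are
instrument-gain conversion factors with default 1.  The estimator is a
declared reconstruction of a saturation-binding analysis — the published
procedure is unstated.  A series with no curvature inside the sampled range
(fitted K more than 4 decades above the largest free signal, or all bound
signal at background) returns the unbounded-K sentinel (`None`).

Cross-platform scaling regresses log10(FCCS K_d, nM) on log10(DULIP K):
a line `Y = aX + b` on log10 scale maps decades onto decades, which is the
only reading under which published-style coefficients (slope ≈ 0.2,
intercept ≈ 2.1) put scaled values in a physically sensible nanomolar
range; a raw-scale mapping would not.  Pearson r and its two-sided p come
from the same regression.  `apply_scaling` and `invert_scaling` are exact
inverses.

Mutant-effect testing averages triplicates within each independent
experiment first (N = experiments, not wells), then applies a two-sided
one-sample t-test of log2 cNIR against zero.  Zero-variance inputs are
handled exactly (p = 1 if the common value is 0, else p = 0 with a
degenerate flag) instead of emitting NaN.

## 5. Reporter mixed model

For one random intercept per plate the REML criterion is one-dimensional in
the variance ratio λ = σ_plate²/σ²: given λ, the GLS fixed effects and the
residual variance have closed forms (per-plate rank-one updates via the
Sherman–Morrison structure of `I + λJ`).  The fit maximises the profiled
criterion by bounded scalar search over log λ and checks the λ = 0 boundary
explicitly, so a truly-zero plate variance is estimated as exactly zero and
the fixed effects then equal OLS.  The log-likelihood constant matches the
standard REML definition (validated against statsmodels `MixedLM` to 1e-4
in the test suite; statsmodels serves as the independent reference, never
as the implementation).

Satterthwaite degrees of freedom: `df = 2(c'Vc)²/Var(c'Vc)` with the
delta-method variance from (i) the gradient of `c'V(θ)c` in
θ = (σ_plate², σ²), central differences with step 1e-6·θ, and (ii) the
inverse observed information of the REML log-likelihood (numerical Hessian,
step 1e-4·θ).  The df is clipped to [1, n−p]; when the plate variance is
estimated at zero the classical residual df n−p is returned directly.

The model includes condition × cell-line interactions although main-effect
descriptions of such screens are common: the scientific contrasts of
interest — "how does the partner's effect change in an edited line
relative to wild type" — are exactly the interaction coefficients, and a
main-effects-only model cannot express them.  This is an assumption
documented here, not a published specification.

Partner classification (α = 0.05 on Bonferroni-adjusted p-values):
significant wild-type effect → activator/inhibitor by sign; significant
opposing interaction in *both* NRF2-null lines → NRF2-dependent; no
wild-type effect but a significant interaction in ≥ 1 derepressed line
(T80K homozygous, T80K hemizygous, or KEAP1-null) → derepression-dependent;
otherwise no effect.  Labels other than `no_effect` may co-occur.  The rule
set is a declared reconstruction: how the original analysis formally tested
"dampening" is not fully specified.

## 6. Y2H scoring and network assembly

A (partner, fragment) pair is positive iff growth was observed in ≥ 2
independent assay replicates and neither clone auto-activates.  Growth on
*either* reporter (ADE2 or HIS3) counts for that replicate: the published
rule names both reporters without an AND/OR convention; OR is chosen (and
documented) because the two reporters are redundant read-outs of the same
activation event with different sensitivities.  Single-replicate pairs are
reported as untested-incomplete, never positive.

Conditional affinity uses the strict rule: `K_KO/K_WT > 1.25` is a loss of
affinity in the knockout, `< 1/1.25` a gain, the boundary itself unchanged.

Edge weights operationalise "average normalised binding affinity": per
assay, log10 K_d is min–max normalised across the partners that assay
quantified; an edge's weight is the mean of its available normalised
values (0 = strongest binder, 1 = weakest).  A degenerate assay (all K_d
equal, or a single partner) yields 0.5 by convention with a flag.  The
published network figure describes edge weighting only qualitatively, so
this normalisation is the package's own definition.

Gene symbols are upper-cased and matched by symbol only; colliding
duplicates raise.  Exports: GraphML with full node/edge attribute sets
(absent values as the explicit string `"NA"`, since GraphML has no null),
SIF with relationship `pp`, and node/edge TSV tables.  Export → import
round trips preserve all attributes.

## 7. Numerical conventions and limitations

* All randomness flows through one seeded `numpy.random.Generator` per
  simulation call; identical configurations are bit-identical.
* Isotherm log10 K search range [−3, 9] (nM); values at the upper bound
  become the non-binder sentinel.
* Bootstrap CIs use the percentile method; the interval is widened to
  include the point estimate if resampling noise would exclude it.
* The acceptance recovery study uses 300 bootstrap resamples per run
  (default 1000) to stay inside its runtime budget; CI coverage there is
  insensitive to the resample count.
* Fits assume independent per-lag noise; real exported curves violate this
  mildly, biasing sem-based weights but not the amplitudes that drive K_d.
* The DULIP scaling regression treats the FCCS axis as error-free (OLS,
  not errors-in-variables), consistent with its use as a calibration onto
  the FCCS scale.
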