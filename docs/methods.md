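# Methods

This note documents the models, numerical choices and known limitations of
`nirstherm`. It covers what the code computes and why the defaults are what
they are; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## 1. Synthetic data model

No broadband-NIRS hypothermia recordings are publicly deposited, so the
package generates its own. The generator is first-class, tested code, and
its defaults *are* the study conditions used throughout the tests.

### 1.1 Extinction spectra

The parametric extinction table models, on any 600–1000 nm grid:

* **Water reference spectrum** ε_ref(λ): a 0.020 cm⁻¹ baseline plus three
  Gaussian bands at the NIR water absorption peaks —
  (740 nm, σ 22 nm, 0.030 cm⁻¹), (840 nm, σ 28 nm, 0.055 cm⁻¹),
  (970 nm, σ 40 nm, 0.50 cm⁻¹) — in units of 1/cm per unit water volume
  fraction. Relative band sizes follow the qualitative shape of the NIR
  water spectrum (970 ≫ 840 > 740).
* **Temperature coefficient** κ(λ): a band-sharpening feature per band,
  amp·[G(λ; c, σ) − 0.5·G(λ; c, 1.8σ)], positive at the band centre with
  shallow negative wings (isosbestic-like points), so warming increases
  extinction at the peaks. Amplitudes: 1.0e-3 (740 nm), 1.4e-3 (840 nm)
  and 4.0e-5 (970 nm) cm⁻¹/°C. The deliberately near-zero 970 nm
  coefficient makes single-wavelength calibration at 970 nm carry almost no
  usable temperature signal — the generator's analogue of the empirical
  unreliability of the 970 nm band for temperature prediction, where
  absorption uncertainty swamps the temperature response. This is a design
  choice of the synthetic stand-in, not a claim about pure-water physics
  (in water itself the 970 nm band has a strong temperature dependence).
* **Hemoglobins**: smooth synthetic curves in 1/(mM·cm) — HHb dominated by
  a broad 740 nm feature, O2Hb rising towards the red — crossing near
  800 nm like the real oxy/deoxy spectra. No attempt is made to reproduce
  tabulated extinction values; a CSV loader accepts measured tables
  (columns `wavelength_nm, epsilon_o2hb, epsilon_hhb, epsilon_h2o_ref,
  kappa_h2o`, linear interpolation, no extrapolation).

The water model is **linear in T** around T_ref = 35 °C and is accepted on
[28, 48] °C, the widest range over which NIR water thermometry has been
demonstrated; the table validates that extinction stays non-negative over
that whole domain.

### 1.2 Recordings

Attenuation is the noiseless forward model

A(t, λ) = L·[ε_O2Hb(λ)c_O2Hb(t) + ε_HHb(λ)c_HHb(t) + ε_H2O(λ, T_eff(t))c_H2O(t)]
          + systemic leakage + N(0, noise_sd²),

with effective pathlength L = 14.97 cm by default (3 cm × DPF 4.99, the
newborn-head value) and baselines c_O2Hb = 50 µM, c_HHb = 20 µM (tissue
oxygenation ≈ 71 %), c_H2O = 0.85 volume fraction; optional linear drifts.

Two protocols are built in:

* **Continuous cooling** (piglet-style): linear ramp 37 → 33.5 °C, default
  30 min at 0.1 Hz on the 662–984 nm / 322-wavelength grid (cohort
  fixtures vary the duration over 10–56 min).
* **Stepwise rewarming** (infant-style): staircase 33.5 → 37 °C in equal
  steps. The tissue response to each jump is a first-order relaxation
  lagging the protocol by one sample (time constant configurable), so
  step-extraction has kinetics to detect; the recorded reference
  temperature stays the un-relaxed staircase. Systemic channels (heart
  rate ~160 bpm, mean blood pressure ~45 mmHg, slow sinusoids + jitter)
  leak linearly into attenuation through a smooth spectral profile
  (default 1e-3 OD per channel SD).

The instruments' true noise floor and drift are unknown; the default noise
is zero and every run records its parameters in `meta`. Fixed seeds give
bitwise-identical recordings (NumPy `default_rng`).

**Scaled sizes.** The default human preset runs a time-scaled protocol
(600-s steps at 0.2 Hz, 7.5 step intervals ⇒ 7 steps of +0.5 °C, relaxation
τ = 10 s) rather than the bedside 2-h/1-Hz/14-h schedule; the physics is
time-invariant and the full-scale parameters remain reachable through the
`Protocol` type. All test and acceptance problem sizes (180 × 322 cooling
matrices, 20-replicate cohorts, 101-level calibration sets) were chosen as
comfortable desk-scale conditions.

### 1.3 What the generator does *not* emulate

Scattering changes (only a scalar DPF), motion and ambient-light artifacts,
correlated/1-f noise (i.i.d. Gaussian only; hooks exist in config),
nonlinear temperature dependence of water absorption, wavelength dependence
of the DPF (exposed as a user-supplied correction vector defaulting to 1),
and lipid/cytochrome chromophores. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under a clean linear
forward model — not performance on real tissue data.

## 2. Preprocessing

* **Savitzky–Golay smoothing**: default 60-point window (forced to the next
  odd integer, 61) along wavelength, polynomial order 3 — order 3 preserves
  water-band curvature; whether the original smoothing ran along wavelength
  or time is not knowable, so the axis is a flag.
* **Decile binning**: samples (or band wavelengths) are sorted and split
  into 10 equal-count bins, remainder to the lowest bins — deterministic
  and partition-exact (13 samples → 2,2,2,1,…,1). Difference attenuation is
  referenced to the sample at minimum measured temperature. The
  attenuation–temperature R² regresses bin means on bin index 1–10 (the
  bin-label variant is available).
* **Systemic regression**: per-wavelength OLS residuals on
  [intercept, channels]; the intercept makes the operation idempotent and
  the residuals orthogonal to every channel (< 1e-10 in tests).
* **Step extraction**: for each detected jump (> 0.2 °C between samples),
  the signed largest absolute excursion from the window-start value within
  a 60-s window. "Peak minus baseline" is ambiguous; the
  largest-absolute-excursion rule is sign-agnostic and robust to response
  direction. The output keeps one sample per step, labelled with the
  post-step plateau temperature.
* **Wavelength selection**: nearest grid point for 740/840/970 nm (refused
  beyond 5 nm, so a 770–906 nm grid cannot silently satisfy a 740 nm
  request), inclusive [720, 880] nm band (refused when the grid does not
  cover the band within the same tolerance).

## 3. UCLn inversion

Per time point, ΔA(λ)/L(λ) is least-squares fitted by the extinction matrix
E = [ε_O2Hb, ε_HHb, ε_H2O(·, T_ref)]. The pseudoinverse handles non-square
E (e.g. the 160-wavelength band) and degenerates to matrix inversion for
exactly three wavelengths; rank deficiency raises an error naming the most
collinear chromophore pair. Two dialects: `raw_change` (fit attenuation
changes directly) and `second_derivative` (SG second derivative along the
full wavelength grid applied to both ΔA and the columns of E before
restriction to the selection; requires grid spacing uniform to 1 %).
Δ[H2O] is reported in water-volume-fraction units — the unit convention is
set by the extinction table. Δ[tHb] = Δ[O2Hb] + Δ[HHb] by construction.

## 4. Calibration

* **Training set**: pure-water extinction on the selected wavelengths at
  101 evenly spaced temperatures in [30, 40] °C, times a scalar `gain`
  mapping extinction to the recording's attenuation units. Baseline
  anchoring absorbs any level offset, but `gain` sets the predicted
  temperature *scale*: for the package's own forward model the matching
  value is L × c_H2O, which the pipeline reads from the simulation
  metadata. For real data gain is an instrument property; a mismatch
  rescales predicted temperature *changes* proportionally.
* **Fits**: CLS (forward model per wavelength, prediction by projection on
  the temperature-slope spectrum), ILS (pseudoinverse with a relative
  singular-value cutoff of 1e-10 — directions below it carry no usable
  training variance and would only amplify noise), PCR (top-k PCs of
  mean-centred spectra) and PLSR (single-response NIPALS with deflation;
  components orthogonal). All methods export an equivalent calibration
  vector + intercept. The NIPALS implementation is cross-checked against
  scikit-learn's `PLSRegression` in the test suite.
* **Component choice**: 10-fold CV by default (leave-one-out by flag), fold
  assignment contiguous or seeded-random and recorded; k_best is the
  smallest k within 1e-8 relative (+1e-12 absolute) of the minimum CV
  error — parsimony, since extra components beyond the spectral rank never
  help. Inside CV, k is silently capped at the training-fold rank.
* **Rank accounting.** "Rank" means the rank of the *mean-centred* training
  spectra, which is what centred PLSR/PCR can extract. Because the water
  model is exactly linear in T, the water calibration set has uncentred
  rank 2 but centred rank 1: one component recovers the training
  temperatures to machine precision and CV selects k = 1. The
  two-component behaviour (k_best = 2, flat CV error beyond) is exercised
  on calibration sets with a second, curved (quadratic-in-T) spectral
  direction, built directly in the tests and acceptance script.
* **A consequence of exact linearity**: on a noiseless rank-1-centred
  calibration set, CLS, ILS, PCR and PLSR all produce the *same*
  calibration vector (proportional to the temperature-slope spectrum), so
  the method-comparison ordering PLSR ≥ PCR ≥ ILS ≥ CLS holds as numerical
  ties on synthetic data. The non-degenerate part of the method comparison
  is the wavelength effect: with 2e-3 OD noise, mean R² over 20 replicates
  is ≈ 0.999 (720–880 nm band), ≈ 0.95 (840 nm), ≈ 0.87 (740 nm) and
  ≈ 0.006 (970 nm analogue) — the band wins, the near-zero-κ wavelength
  loses, strictly.
* **Prediction**: raw prediction is the dot product with the calibration
  vector; anchoring (predicted[0] = first measured temperature, or an
  explicit value) makes the prediction invariant to constant attenuation
  offsets. Measured attenuation enters raw (no centring/derivative) by
  default, with a `pre_transform` hook. When the pipeline smooths the
  recording, it applies the same SG filter to the training water spectra,
  so training and prediction share one linear pre-treatment.

## 5. Evaluation

R² defaults to the squared Pearson correlation — anchored predictions can
carry a level offset that the 1 − SS_res/SS_tot form would punish; the
explained-variance definition is a flag. MEB = mean(predicted − measured);
|MEB| ≤ MAE ≤ √MSE by convexity/Cauchy–Schwarz (property-tested on fuzzed
errors).

RROC curves are computed on a shift grid that always contains the exact
breakpoints −e_i, where OVER/UNDER are piecewise linear, so the trapezoidal
AOC is exact (it matches a 500 001-point brute-force sweep to ~1e-11
relative). OVER/UNDER are reported **per sample** so subjects with
different recording lengths are comparable on one plot and in AOC — an
absolute-total convention would let the sample count drive dominance.
Dominance compares curves on the merged OVER grid with linear
interpolation and a 1e-9 °C tolerance; coinciding curves report
"crossing". Per-sample AOC tracks the error variance (r > 0.95 across
Gaussian cohorts), which is what makes it useful as a variance surrogate.

## 6. Pipeline and reproducibility

`run_pipeline` executes simulate → smooth → (systemic regression + step
extraction for stepwise runs) → UCLn → wavelength selection → PLSR
calibration with CV → anchored prediction → metrics + RROC, writing
per-stage CSV/JSON artifacts and a manifest with the SHA-256 of each file;
identical configs give byte-identical outputs. For stepwise runs the
prediction input is the per-plateau attenuation reconstructed as the
pre-step baseline plus the cumulative sum of step differences — the
per-step differences themselves carry no cumulative rewarming trend, while
their running sum recovers the plateau levels the staircase temperature
corresponds to. Group statistics (repeated-measures ANOVA, t-tests) are
out of scope.

## 7. Known limitations

* The linear water model makes the four calibration methods coincide on
  noiseless training data (see the calibration section); separating them
  requires curvature or
  training noise that the default study conditions deliberately exclude.
* Gain matching between training (extinction) and prediction (attenuation)
  units is exact only because the simulator's forward model is known; on
  real data the predicted temperature scale inherits any gain error.
* The RROC AOC normalisation (per sample) is a package convention chosen
  for cross-subject comparability; absolute AOC values are not comparable
  to conventions that report unnormalised totals.
* Step extraction assumes non-overlapping windows and steps detectable
  from the reference temperature channel.
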