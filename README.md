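# nirstherm

Non-invasive brain tissue thermometry from **broadband near-infrared
spectroscopy (NIRS)**. Water is the one major NIR tissue chromophore whose
absorption spectrum shifts measurably with temperature — its bands around
740, 840 and 970 nm grow and sharpen as tissue warms. `nirstherm`
calibrates that dependence and turns broadband attenuation recordings
acquired during therapeutic hypothermia (cooling to ~33.5 °C and staged
rewarming to 37 °C) into a predicted tissue temperature, evaluated against
the measured core (rectal) reference.

The package is aimed at neuromonitoring researchers who want a tested,
scriptable implementation of the full analysis chain, and ships a
synthetic-data generator that emulates both recording protocols so
everything runs offline.

## What it computes

**Calibration (PLSR on simulated water spectra).** A training set is built
from the temperature-dependent pure-water extinction spectrum
ε_H2O(λ, T) = ε_ref(λ) + (T − T_ref)·κ(λ) at temperatures T ∈ [30, 40] °C.
Partial least squares regression (single-response NIPALS; CLS, ILS and PCR
are also provided) compresses the spectra into latent components and yields
a calibration vector **b** with intercept b₀, the number of components
chosen by 10-fold (or leave-one-out) cross-validation. A measured spectrum
**a**(t) then gives the anchored prediction

T̂(t) = **a**(t)·**b** + b₀ − (**a**(0)·**b** + b₀) + T_anchor,

where the baseline anchor T_anchor (the measured temperature at recording
onset) absorbs the unknown offset between tissue attenuation and the
pure-water training scale.

**Chromophore inversion (UCLn / modified Beer–Lambert).** Attenuation
changes divided by the effective optical pathlength (optode separation ×
differential pathlength factor; 3 cm × 4.99 = 14.97 cm on the newborn head)
are least-squares inverted against the extinction matrix of O2Hb, HHb and
H2O — optionally on second-derivative spectra — giving Δ[O2Hb], Δ[HHb],
Δ[H2O] and Δ[tHb].

**Evaluation (RROC).** Besides R², MAE and MSE, predictions are scored by
regression-ROC curves: sweeping a constant shift s over the errors
e_i = T̂_i − T_i traces total over-estimation Σ max(e_i+s, 0) against total
under-estimation Σ min(e_i+s, 0) (both per sample). The mean error bias
MEB = mean(e) summarises over- vs under-estimation, the area over the curve
(AOC) acts as an error-variance surrogate, and curves can be compared for
dominance.

## Worked example

Simulate a piglet-style cooling run (322 wavelengths, 662–984 nm, 0.1 Hz,
37 → 33.5 °C over 30 min) with 0.002 OD measurement noise and push it
through the whole chain:

```sh
nirstherm run --preset animal --seed 1 --noise-sd 0.002 --out demo_run
```

prints

```json
{
 "aoc": 0.0005204075084880434,
 "cv_error_by_k": [
  1.6895682278951413e-28
 ],
 "mae": 0.02548766732791334,
 "meb": -0.0011065504409270626,
 "mse": 0.0010420394708544026,
 "n_components": 1,
 "r2": 0.9989816015239278,
 "selection_label": "band_720_880",
 "subject_id": "animal_seed1"
}
```

Reading the numbers: the 720–880 nm water-band calibration tracks the
measured cooling trajectory with R² = 0.999 and a mean absolute error of
0.025 °C; the near-zero MEB (−0.001 °C) says the prediction is essentially
unbiased on this synthetic subject, and the per-sample AOC of 5.2e-4 °C²
is the RROC error-variance surrogate. One latent component suffices
(`cv_error_by_k` is at numerical zero) because the synthetic water model is
exactly linear in temperature. `demo_run/` holds the per-stage artifacts
(recording, smoothed spectra, chromophore series, model, prediction, RROC
curve) plus a manifest with the SHA-256 of each file; rerunning the same
command reproduces them byte for byte.

The human-style preset (`--preset human`) rewarms in +0.5 °C steps on the
770–906 nm grid, removes heart-rate/blood-pressure confounds by regression,
collapses each step to one sample and calibrates at 840 nm only — asking it
for the 720–880 nm band fails at wavelength selection, since that grid
cannot cover the band.

Python API equivalents live in `nirstherm` (see the module docstrings):
`simulate_recording`, `smooth_spectra`, `ucln_invert`,
`build_calibration_set`, `fit_plsr`, `select_num_components`,
`predict_temperature`, `rroc_curve`, `run_pipeline`, `make_fixtures`.

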