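"""End-to-end pipeline: simulate -> preprocess -> calibrate -> predict -> evaluate.

``run_pipeline`` executes the full analysis chain on a simulated subject and
writes per-stage CSV/JSON artifacts plus a manifest (config + SHA-256 of
every artifact), so a rerun with the same config is byte-identical.
``make_fixtures`` writes a small synthetic cohort (four cooling-protocol and
four rewarming-protocol subjects) for tests and demos.

Presets
-------
``animal``  662-984 nm / 322 wavelengths / 0.1 Hz, continuous cooling
            37 -> 33.5 degC over 30 min, calibrated on the 720-880 nm band.
``human``   770-906 nm / 136 wavelengths, stepwise rewarming 33.5 -> 37 degC
            in +0.5 degC steps with systemic confounds, calibrated at 840 nm
            only (the grid does not cover 720-880 nm). Default sizes are a
            time-scaled version of the bedside protocol (600-s steps at
            0.2 Hz) so a run completes in seconds; full-scale parameters are
            reachable through ``duration_s``/``step_interval_s``/``sampling_hz``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import (
    build_calibration_set,
    fit_plsr,
    predict_temperature,
    select_num_components,
)
from .chromophores import PathlengthSpec, ucln_invert
from .evaluation import prediction_metrics, rroc_curve
from .exceptions import PipelineStageError
from .preprocessing import (
    detect_steps,
    extract_step_responses,
    regress_out_systemic,
    select_wavelengths,
    smooth_spectra,
)
from .synthetic import (
    Protocol,
    SpectralRecording,
    SystemicSpec,
    WavelengthGrid,
    make_extinction_table,
    simulate_recording,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "PRESETS"]

PRESETS = {
    "animal": {
        "grid": (662.0, 984.0, 322),
        "sampling_hz": 0.1,
        "protocol_kind": "continuous_cooling",
        "t_start_c": 37.0,
        "t_end_c": 33.5,
        "duration_s": 1800.0,
        "step_interval_s": None,
        "selection_label": "band_720_880",
        "systemic": False,
        "relaxation_tau_s": 0.0,
    },
    "human": {
        "grid": (770.0, 906.0, 136),
        "sampling_hz": 0.2,
        "protocol_kind": "stepwise_rewarming",
        "t_start_c": 33.5,
        "t_end_c": 37.0,
        "duration_s": 4500.0,  # 7.5 step intervals -> 7 steps of +0.5 degC
        "step_interval_s": 600.0,
        "selection_label": "840",
        "systemic": True,
        "relaxation_tau_s": 10.0,
    },
}


@dataclass
class PipelineConfig:
    """Self-describing configuration for one pipeline run."""

    preset: str = "animal"
    seed: int = 1
    noise_sd: float = 0.0
    out_dir: str = "nirstherm_run"
    selection_label: str | None = None  # None -> preset default
    smooth_window: int = 61
    smooth_polyorder: int = 3
    k_max: int = 10
    folds: int = 10
    max_components: int = 3
    anchor: str | float = "first_measured"
    cal_t_min_c: float = 30.0
    cal_t_max_c: float = 40.0
    cal_levels: int = 101
    duration_s: float | None = None
    sampling_hz: float | None = None
    step_interval_s: float | None = None
    step_window_s: float = 60.0
    step_threshold_c: float = 0.2
    rroc_shifts: int = 512
    pathlength: dict = field(default_factory=lambda: {"separation_cm": 3.0, "dpf": 4.99})

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def resolved(self) -> dict:
        p = dict(PRESETS[self.preset])
        if self.duration_s is not None:
            p["duration_s"] = self.duration_s
        if self.sampling_hz is not None:
            p["sampling_hz"] = self.sampling_hz
        if self.step_interval_s is not None:
            p["step_interval_s"] = self.step_interval_s
        if self.selection_label is not None:
            p["selection_label"] = self.selection_label
        return p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_subject(cfg: PipelineConfig, seed: int) -> SpectralRecording:
    p = cfg.resolved()
    grid = WavelengthGrid.linspace(*p["grid"])
    table = make_extinction_table(grid)
    if p["protocol_kind"] == "continuous_cooling":
        protocol = Protocol.continuous_cooling(
            p["t_start_c"], p["t_end_c"], p["duration_s"], p["sampling_hz"])
    else:
        protocol = Protocol.stepwise_rewarming(
            p["t_start_c"], p["t_end_c"], p["duration_s"], p["sampling_hz"],
            p["step_interval_s"])
    path = PathlengthSpec(**cfg.pathlength)
    return simulate_recording(
        table, protocol,
        noise_sd=cfg.noise_sd,
        systemic_spec=SystemicSpec() if p["systemic"] else None,
        seed=seed,
        pathlength_cm=float(path.separation_cm * path.dpf),
        relaxation_tau_s=p["relaxation_tau_s"],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.resolved()
    artifacts: dict[str, str] = {}
    manifest: dict = {"config": asdict(config), "resolved_preset": p,
                      "stages": [], "artifacts": {}, "metrics": None}

    def stage(name, fn, input_path=None):
        try:
            result = fn()
        except Exception as exc:  # annotate with the failing stage
            raise PipelineStageError(name, str(exc), input_path) from exc
        manifest["stages"].append(name)
        return result

    # 1. simulate
    recording = stage("simulate", lambda: _simulate_subject(config, config.seed))
    rec_path = out / "recording.csv"
    recording.to_csv(rec_path)
    artifacts["recording"] = rec_path.name

    # 2. smooth
    def _smooth():
        window = min(config.smooth_window, len(recording.grid))
        return smooth_spectra(recording, window, config.smooth_polyorder, "wavelength")
    smoothed = stage("smooth", _smooth, rec_path)
    sm_path = out / "recording_smoothed.csv"
    smoothed.to_csv(sm_path)
    artifacts["recording_smoothed"] = sm_path.name

    # 3. systemic removal + step extraction (stepwise protocols only)
    prediction_input = smoothed
    if p["protocol_kind"] == "stepwise_rewarming":
        def _steps():
            cleaned = (regress_out_systemic(smoothed) if smoothed.systemic
                       else smoothed)
            steps = detect_steps(cleaned, config.step_threshold_c)
            extracted = extract_step_responses(cleaned, steps, config.step_window_s)
            # Reconstruct per-plateau attenuation levels from the per-step
            # differences (cumulative sum on top of the pre-step baseline):
            # difference spectra alone carry no cumulative rewarming trend.
            levels = smoothed.attenuation[0][None, :] + np.cumsum(
                extracted.attenuation, axis=0)
            return extracted, SpectralRecording(
                extracted.grid, extracted.times_s, levels,
                extracted.temperature_c, {}, extracted.meta)
        extracted, prediction_input = stage("extract_steps", _steps, sm_path)
        st_path = out / "step_responses.csv"
        extracted.to_csv(st_path)
        artifacts["step_responses"] = st_path.name

    # 4. chromophore inversion (UCLn) on the smoothed recording
    def _chromo():
        table = make_extinction_table(smoothed.grid)
        try:
            chromo_sel = select_wavelengths(smoothed.grid, "band_720_880")
        except Exception:
            chromo_sel = select_wavelengths(
                smoothed.grid, smoothed.grid.wavelengths_nm)
        d_atten = smoothed.attenuation - smoothed.attenuation[0][None, :]
        return ucln_invert(d_atten, table, chromo_sel,
                           PathlengthSpec(**config.pathlength),
                           dialect="raw_change", times_s=smoothed.times_s)
    chromo = stage("chromophores", _chromo, sm_path)
    ch_path = out / "chromophores.csv"
    chromo.to_csv(ch_path)
    artifacts["chromophores"] = ch_path.name

    # 5. wavelength selection + calibration
    selection = stage(
        "wavelength_selection",
        lambda: select_wavelengths(smoothed.grid, p["selection_label"]))

    def _calibrate():
        # Apply the same spectral smoothing to the training water spectra as
        # was applied to the recording (both are linear in wavelength), so
        # training and prediction spectra share one pre-treatment.
        table = make_extinction_table(smoothed.grid)
        sm = smoothed.meta.get("smoothing")
        if sm is not None:
            from scipy.signal import savgol_filter

            table = dataclasses.replace(
                table,
                epsilon_h2o_ref=savgol_filter(table.epsilon_h2o_ref,
                                              sm["window"], sm["poly_order"]),
                kappa_h2o=savgol_filter(table.kappa_h2o,
                                        sm["window"], sm["poly_order"]),
            )
        meta = recording.meta
        gain = (meta["pathlength_cm"] * meta["concentrations"]["h2o_fraction"])
        calset = build_calibration_set(
            table, selection, config.cal_t_min_c, config.cal_t_max_c,
            config.cal_levels, gain=gain)
        k_max = min(config.k_max, max(1, calset.centred_rank()))
        k_best, cv = select_num_components(
            calset, k_max=k_max, folds=min(config.folds, calset.n_levels),
            seed=config.seed)
        k = min(k_best, config.max_components)
        model = fit_plsr(calset, k)
        return dataclasses.replace(model, selection_label=p["selection_label"],
                                   cv_error_by_k=cv), cv
    model, cv_errors = stage("calibrate", _calibrate)
    model_path = out / "model.json"
    model.to_json(model_path)
    artifacts["model"] = model_path.name

    # 6. predict
    prediction = stage(
        "predict",
        lambda: predict_temperature(model, prediction_input, config.anchor))
    pred_path = out / "prediction.csv"
    prediction.to_csv(pred_path)
    artifacts["prediction"] = pred_path.name

    # 7. evaluate
    def _evaluate():
        curve = rroc_curve(prediction.measured_c, prediction.predicted_c,
                           config.rroc_shifts)
        report = prediction_metrics(
            prediction.measured_c, prediction.predicted_c,
            subject_id=f"{config.preset}_seed{config.seed}",
            method=model.method,
            wavelength_label=model.selection_label)
        return report, curve
    report, curve = stage("evaluate", _evaluate, pred_path)
    metrics = {
        "subject_id": report.subject_id, "r2": report.r2, "mae": report.mae,
        "mse": report.mse, "meb": report.meb, "aoc": curve.aoc,
        "n_components": model.n_components,
        "selection_label": p["selection_label"],
        "cv_error_by_k": cv_errors.tolist(),
    }
    metrics_path = out / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True)
        fh.write("\n")
    artifacts["metrics"] = metrics_path.name
    rroc_path = out / "rroc.csv"
    curve.to_frame().to_csv(rroc_path, index=False, float_format="%.10g")
    artifacts["rroc"] = rroc_path.name

    manifest["metrics"] = metrics
    manifest["artifacts"] = {
        name: {"path": fname, "sha256": _sha256(out / fname)}
        for name, fname in sorted(artifacts.items())
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def make_fixtures(out_dir, seeds=(11, 12, 13, 14)) -> list[Path]:
    """Write a small synthetic cohort: 4 cooling + 4 rewarming subjects.

    Cooling durations vary across the cohort (10-56 min, mirroring the
    spread of real cooling runs); rewarming subjects span 7 steps of
    +0.5 degC. Also writes the parametric extinction tables for both grids.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    animal_grid = WavelengthGrid.linspace(*PRESETS["animal"]["grid"])
    animal_table = make_extinction_table(animal_grid)
    durations = (600.0, 1800.0, 2700.0, 3360.0)
    for i, (seed, dur) in enumerate(zip(seeds, durations), start=1):
        protocol = Protocol.continuous_cooling(duration_s=dur)
        rec = simulate_recording(animal_table, protocol, noise_sd=2e-3, seed=seed)
        path = out / f"animal{i:02d}.csv"
        rec.to_csv(path, float_format="%.6g")
        written.append(path)

    human_grid = WavelengthGrid.linspace(*PRESETS["human"]["grid"])
    human_table = make_extinction_table(human_grid)
    for i, seed in enumerate(seeds, start=1):
        protocol = Protocol.stepwise_rewarming(
            duration_s=4500.0, sampling_hz=0.1, step_interval_s=600.0)
        rec = simulate_recording(
            human_table, protocol, noise_sd=2e-3,
            systemic_spec=SystemicSpec(), seed=seed + 100,
            relaxation_tau_s=10.0)
        path = out / f"human{i:02d}.csv"
        rec.to_csv(path, float_format="%.6g")
        written.append(path)

    for name, table in (("animal", animal_table), ("human", human_table)):
        path = out / f"extinction_{name}.csv"
        table.to_csv(path)
        written.append(path)
    return written
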