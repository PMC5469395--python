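"""Synthetic broadband-NIRS recordings with a temperature-encoded water spectrum.

The in-vivo recordings this package targets are broadband near-infrared
attenuation time series acquired during therapeutic hypothermia: a continuous
cooling run (piglet-style, ~37 -> 33.5 degC over tens of minutes at 0.1 Hz,
662-984 nm) and a stepwise rewarming run (infant-style, 33.5 -> 37 degC in
equal steps, 770-906 nm).  Because no such recordings are publicly deposited,
this module generates physically structured stand-ins:

* a parametric extinction model -- three Gaussian water absorption bands
  centred at 740, 840 and 970 nm whose extinction grows linearly with tissue
  temperature (band-sharpening temperature coefficient, positive at the band
  centres), plus smooth synthetic oxy-/deoxy-haemoglobin curves crossing near
  800 nm;
* a forward model: attenuation = pathlength x (sum of extinction x
  concentration) + systemic leakage + i.i.d. Gaussian noise, with the water
  term evaluated at the protocol temperature.

Everything is deterministic under a fixed seed, and every generated object
records its parameters in ``meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import DomainError, FormatError, RangeError

__all__ = [
    "WavelengthGrid",
    "ExtinctionTable",
    "Protocol",
    "ConcentrationSpec",
    "SystemicSpec",
    "SpectralRecording",
    "make_extinction_table",
    "water_extinction",
    "simulate_recording",
    "TEMPERATURE_DOMAIN_C",
    "WATER_BAND_CENTERS_NM",
]

#: Validity domain of the linear water-temperature model (degC). The outer
#: envelope matches the widest range over which NIR water thermometry has
#: been demonstrated.
TEMPERATURE_DOMAIN_C = (28.0, 48.0)

#: NIR water absorption band centres (nm).
WATER_BAND_CENTERS_NM = (740.0, 840.0, 970.0)

# (centre nm, sigma nm, amplitude 1/cm per unit water fraction)
_WATER_BANDS = (
    (740.0, 22.0, 0.030),
    (840.0, 28.0, 0.055),
    (970.0, 40.0, 0.500),
)
# temperature-coefficient amplitude per band (1/cm per degC at band centre,
# before the 0.5 sharpening factor). The 970 nm band is given a near-zero
# coefficient so that single-wavelength calibrations at 970 nm carry almost
# no usable temperature signal (the band where, in tissue, measurement
# uncertainty drowns the temperature response).
_KAPPA_AMPS = (1.0e-3, 1.4e-3, 4.0e-5)
_KAPPA_WIDE_FACTOR = 1.8
_WATER_BASELINE = 0.020  # flat offset keeping extinction positive in the wings


def _gauss(lam: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - centre) / sigma) ** 2)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm, confined to 600-1000 nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        if lam.ndim != 1 or lam.size < 4:
            raise ValueError("wavelength grid needs at least 4 points")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if lam[0] < 600.0 or lam[-1] > 1000.0:
            raise ValueError("wavelengths must lie within 600-1000 nm")

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @classmethod
    def linspace(cls, lo_nm: float, hi_nm: float, n: int) -> "WavelengthGrid":
        return cls(np.linspace(lo_nm, hi_nm, n))

    def nearest_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths_nm - nm)))

    @property
    def spacing_nm(self) -> np.ndarray:
        return np.diff(self.wavelengths_nm)


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength chromophore extinction and water temperature coefficient.

    Haemoglobin extinctions are in 1/(mM cm); water reference extinction and
    its temperature coefficient are in 1/cm per unit water volume fraction
    (per degC for ``kappa_h2o``). The water model is linear around ``t_ref_c``:
    ``eps_H2O(lam, T) = epsilon_h2o_ref(lam) + (T - t_ref_c) * kappa_h2o(lam)``.
    """

    grid: WavelengthGrid
    epsilon_o2hb: np.ndarray
    epsilon_hhb: np.ndarray
    epsilon_h2o_ref: np.ndarray
    kappa_h2o: np.ndarray
    t_ref_c: float = 35.0

    def __post_init__(self):
        n = len(self.grid)
        for name in ("epsilon_o2hb", "epsilon_hhb", "epsilon_h2o_ref", "kappa_h2o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got {arr.shape}")
        if np.any(self.epsilon_h2o_ref < 0):
            raise ValueError("epsilon_h2o_ref must be non-negative")
        lo, hi = TEMPERATURE_DOMAIN_C
        for t_edge in (lo, hi):
            eps = self.epsilon_h2o_ref + (t_edge - self.t_ref_c) * self.kappa_h2o
            if np.any(eps < 0):
                raise ValueError(
                    "water extinction becomes negative within the "
                    f"{lo}-{hi} degC validity domain"
                )

    def to_csv(self, path) -> None:
        """Write the table as CSV with a header comment carrying t_ref_c."""
        df = pd.DataFrame(
            {
                "wavelength_nm": self.grid.wavelengths_nm,
                "epsilon_o2hb": self.epsilon_o2hb,
                "epsilon_hhb": self.epsilon_hhb,
                "epsilon_h2o_ref": self.epsilon_h2o_ref,
                "kappa_h2o": self.kappa_h2o,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# t_ref_c = {self.t_ref_c!r}\n")
            df.to_csv(fh, index=False)


def _parametric_water(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eps = np.full_like(lam, _WATER_BASELINE)
    kappa = np.zeros_like(lam)
    for (centre, sigma, amp), kamp in zip(_WATER_BANDS, _KAPPA_AMPS):
        eps = eps + amp * _gauss(lam, centre, sigma)
        # band sharpening: positive at the centre, slightly negative wings
        kappa = kappa + kamp * (
            _gauss(lam, centre, sigma)
            - 0.5 * _gauss(lam, centre, _KAPPA_WIDE_FACTOR * sigma)
        )
    return eps, kappa


def _parametric_hemoglobin(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Smooth synthetic curves with the oxy/deoxy crossing (isosbestic-like
    # point) near 800 nm: HHb dominated by a broad 740 nm feature, O2Hb
    # rising towards the red.
    o2hb = 0.45 + 0.85 / (1.0 + np.exp(-(lam - 780.0) / 40.0))
    hhb = 0.30 + 1.30 * _gauss(lam, 740.0, 55.0)
    return o2hb, hhb


_EXTINCTION_COLUMNS = (
    "wavelength_nm",
    "epsilon_o2hb",
    "epsilon_hhb",
    "epsilon_h2o_ref",
    "kappa_h2o",
)


def make_extinction_table(grid: WavelengthGrid, source="parametric") -> ExtinctionTable:
    """Build an :class:`ExtinctionTable` on ``grid``.

    ``source='parametric'`` evaluates the built-in band model; any other value
    is treated as a path to a CSV table (columns ``wavelength_nm``,
    ``epsilon_o2hb``, ``epsilon_hhb``, ``epsilon_h2o_ref``, ``kappa_h2o``;
    an optional leading comment line ``# t_ref_c = <value>``) which is
    linearly interpolated onto ``grid`` -- never extrapolated.
    """
    if isinstance(source, str) and source == "parametric":
        lam = grid.wavelengths_nm
        eps_h2o, kappa = _parametric_water(lam)
        o2hb, hhb = _parametric_hemoglobin(lam)
        return ExtinctionTable(grid, o2hb, hhb, eps_h2o, kappa)

    path = Path(source)
    t_ref_c = 35.0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        try:
            t_ref_c = float(first.split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"cannot parse t_ref_c header line: {first!r}") from exc
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _EXTINCTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"extinction table {path} missing columns {missing}")
    lam_file = df["wavelength_nm"].to_numpy(dtype=float)
    order = np.argsort(lam_file)
    lam_file = lam_file[order]
    lam = grid.wavelengths_nm
    if lam[0] < lam_file[0] or lam[-1] > lam_file[-1]:
        raise RangeError(
            f"grid span {lam[0]:g}-{lam[-1]:g} nm exceeds table span "
            f"{lam_file[0]:g}-{lam_file[-1]:g} nm (no extrapolation)"
        )
    cols = {
        name: np.interp(lam, lam_file, df[name].to_numpy(dtype=float)[order])
        for name in _EXTINCTION_COLUMNS[1:]
    }
    return ExtinctionTable(
        grid,
        cols["epsilon_o2hb"],
        cols["epsilon_hhb"],
        cols["epsilon_h2o_ref"],
        cols["kappa_h2o"],
        t_ref_c=t_ref_c,
    )


def water_extinction(table: ExtinctionTable, temperature_c: float) -> np.ndarray:
    """Water extinction spectrum at ``temperature_c`` (linear model)."""
    lo, hi = TEMPERATURE_DOMAIN_C
    if not (lo <= temperature_c <= hi):
        raise DomainError(
            f"temperature {temperature_c} degC outside the supported "
            f"[{lo}, {hi}] degC domain"
        )
    return table.epsilon_h2o_ref + (temperature_c - table.t_ref_c) * table.kappa_h2o


@dataclass(frozen=True)
class Protocol:
    """Temperature protocol: continuous cooling or stepwise rewarming."""

    kind: str  # "continuous_cooling" | "stepwise_rewarming"
    t_start_c: float
    t_end_c: float
    duration_s: float
    sampling_hz: float
    step_interval_s: float | None = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.kind == "continuous_cooling":
            if not self.t_start_c > self.t_end_c:
                raise ValueError("continuous_cooling requires t_start_c > t_end_c")
        elif self.kind == "stepwise_rewarming":
            if not self.t_start_c < self.t_end_c:
                raise ValueError("stepwise_rewarming requires t_start_c < t_end_c")
            if self.step_interval_s is None or self.step_interval_s <= 0:
                raise ValueError("stepwise_rewarming requires step_interval_s > 0")
        else:
            raise ValueError(f"unknown protocol kind {self.kind!r}")

    @classmethod
    def continuous_cooling(cls, t_start_c=37.0, t_end_c=33.5, duration_s=1800.0,
                           sampling_hz=0.1) -> "Protocol":
        return cls("continuous_cooling", t_start_c, t_end_c, duration_s, sampling_hz)

    @classmethod
    def stepwise_rewarming(cls, t_start_c=33.5, t_end_c=37.0, duration_s=4500.0,
                           sampling_hz=0.2, step_interval_s=600.0) -> "Protocol":
        return cls("stepwise_rewarming", t_start_c, t_end_c, duration_s,
                   sampling_hz, step_interval_s)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_hz))

    @property
    def n_steps(self) -> int:
        if self.kind != "stepwise_rewarming":
            return 0
        return int(np.floor(self.duration_s / self.step_interval_s))

    def temperature_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """Times (s) and reference temperature (degC) along the protocol."""
        n = self.n_samples
        times = np.arange(n) / self.sampling_hz
        if self.kind == "continuous_cooling":
            temp = self.t_start_c + (self.t_end_c - self.t_start_c) * times / self.duration_s
        else:
            n_steps = self.n_steps
            height = (self.t_end_c - self.t_start_c) / n_steps
            k = np.minimum(np.floor(times / self.step_interval_s), n_steps)
            temp = self.t_start_c + height * k
        return times, temp

    def step_times(self) -> np.ndarray:
        """Times (s) of the temperature jumps (stepwise protocols only)."""
        if self.kind != "stepwise_rewarming":
            return np.array([])
        return self.step_interval_s * np.arange(1, self.n_steps + 1)


@dataclass(frozen=True)
class ConcentrationSpec:
    """Baseline chromophore concentrations and optional linear drifts.

    Haemoglobins in mM (tissue-typical tens of micromolar), water as a volume
    fraction. Drifts are per second.
    """

    o2hb_mM: float = 0.050
    hhb_mM: float = 0.020
    h2o_fraction: float = 0.85
    o2hb_drift_per_s: float = 0.0
    hhb_drift_per_s: float = 0.0
    h2o_drift_per_s: float = 0.0

    def trace(self, times_s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c_o2 = self.o2hb_mM + self.o2hb_drift_per_s * times_s
        c_hh = self.hhb_mM + self.hhb_drift_per_s * times_s
        c_w = self.h2o_fraction + self.h2o_drift_per_s * times_s
        for name, arr in (("o2hb", c_o2), ("hhb", c_hh), ("h2o", c_w)):
            if np.any(arr < 0):
                raise ValueError(f"{name} concentration becomes negative")
        return c_o2, c_hh, c_w


@dataclass(frozen=True)
class SystemicSpec:
    """Systemic physiology channels and their linear leakage into attenuation.

    Heart rate and mean blood pressure are modelled as slow sinusoids around
    piglet/infant-typical means plus small Gaussian jitter; leakage adds
    ``leakage_od`` x (smooth spectral profile) x (normalised channel) to the
    attenuation, i.e. the confound is exactly linear in the channels.
    """

    heart_rate_mean: float = 160.0
    heart_rate_amp: float = 8.0
    heart_rate_period_s: float = 300.0
    mean_bp_mean: float = 45.0
    mean_bp_amp: float = 5.0
    mean_bp_period_s: float = 900.0
    jitter_sd: float = 0.5
    leakage_od: float = 1.0e-3


@dataclass(frozen=True)
class SpectralRecording:
    """Time-indexed attenuation matrix with reference temperature.

    ``attenuation`` is (n_times, n_wavelengths) in optical density units;
    ``temperature_c`` is the measured (rectal-equivalent) reference
    temperature; ``systemic`` holds optional named per-time channels.
    """

    grid: WavelengthGrid
    times_s: np.ndarray
    attenuation: np.ndarray
    temperature_c: np.ndarray
    systemic: Mapping[str, np.ndarray] = field(default_factory=dict)
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.attenuation, dtype=float)
        temp = np.asarray(self.temperature_c, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "attenuation", a)
        object.__setattr__(self, "temperature_c", temp)
        object.__setattr__(self, "systemic", dict(self.systemic))
        object.__setattr__(self, "meta", dict(self.meta))
        if a.ndim != 2 or a.shape != (t.size, len(self.grid)):
            raise ValueError(
                f"attenuation shape {a.shape} incompatible with "
                f"{t.size} times x {len(self.grid)} wavelengths"
            )
        if temp.shape != (t.size,):
            raise ValueError("temperature_c length must match times_s")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times_s must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("attenuation contains non-finite values")
        for name, ch in self.systemic.items():
            ch = np.asarray(ch, dtype=float)
            self.systemic[name] = ch
            if ch.shape != (t.size,):
                raise ValueError(f"systemic channel {name!r} length mismatch")

    @property
    def n_times(self) -> int:
        return self.times_s.size

    def with_attenuation(self, attenuation: np.ndarray, **meta_updates) -> "SpectralRecording":
        meta = {**self.meta, **meta_updates}
        return replace(self, attenuation=np.asarray(attenuation, dtype=float), meta=meta)

    # -- serialisation ------------------------------------------------------

    def to_csv(self, path, float_format="%.10g") -> None:
        """Write as CSV (time_s, temperature_c, systemic..., one column per nm).

        ``meta`` goes to a JSON sidecar ``<path>.meta.json``.
        """
        path = Path(path)
        data = {"time_s": self.times_s, "temperature_c": self.temperature_c}
        for name, ch in self.systemic.items():
            data[name] = ch
        for j, nm in enumerate(self.grid.wavelengths_nm):
            data[f"{nm:.10g}"] = self.attenuation[:, j]
        pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)
        with open(path.with_name(path.name + ".meta.json"), "w") as fh:
            json.dump(_jsonable(self.meta), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read_csv(cls, path) -> "SpectralRecording":
        path = Path(path)
        df = pd.read_csv(path)
        if "time_s" not in df.columns or "temperature_c" not in df.columns:
            raise FormatError(f"{path}: need time_s and temperature_c columns")
        wl_cols, systemic_cols = [], []
        for c in df.columns:
            if c in ("time_s", "temperature_c"):
                continue
            try:
                float(c)
                wl_cols.append(c)
            except ValueError:
                systemic_cols.append(c)
        if len(wl_cols) < 4:
            raise FormatError(f"{path}: fewer than 4 wavelength columns")
        meta_path = path.with_name(path.name + ".meta.json")
        meta = {}
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(
            grid=WavelengthGrid(np.array([float(c) for c in wl_cols])),
            times_s=df["time_s"].to_numpy(),
            attenuation=df[wl_cols].to_numpy(),
            temperature_c=df["temperature_c"].to_numpy(),
            systemic={c: df[c].to_numpy() for c in systemic_cols},
            meta=meta,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _relaxed(temp: np.ndarray, dt: float, tau_s: float) -> np.ndarray:
    """First-order exponential relaxation of the tissue response to ``temp``.

    The response lags by one sample (y_i tracks x_{i-1}), so the sample at a
    step time still sits at the pre-step level and the approach to the new
    plateau is fully exponential afterwards.
    """
    if tau_s <= 0:
        return temp
    a = 1.0 - np.exp(-dt / tau_s)
    out, _ = lfilter([0.0, a], [1.0, -(1.0 - a)], temp, zi=[float(temp[0])])
    return out


def simulate_recording(
    table: ExtinctionTable,
    protocol: Protocol,
    concentrations: ConcentrationSpec | None = None,
    noise_sd: float = 0.0,
    systemic_spec: SystemicSpec | None = None,
    seed: int = 0,
    pathlength_cm: float = 14.97,
    relaxation_tau_s: float = 60.0,
) -> SpectralRecording:
    """Forward-simulate a broadband NIRS recording along ``protocol``.

    The attenuation at time t and wavelength lam is::

        A(t, lam) = pathlength_cm * ( eps_O2Hb(lam) * c_O2Hb(t)
                                     + eps_HHb(lam)  * c_HHb(t)
                                     + eps_H2O(lam, T_eff(t)) * c_H2O(t) )
                    + systemic leakage + N(0, noise_sd)

    where T_eff is the protocol temperature, passed through a first-order
    relaxation (time constant ``relaxation_tau_s``) for stepwise protocols so
    the tissue signal approaches each new plateau exponentially. The recorded
    reference ``temperature_c`` is the un-relaxed protocol trace. Identical
    seeds give bitwise-identical recordings.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    concentrations = concentrations or ConcentrationSpec()
    rng = np.random.default_rng(seed)
    times, temp = protocol.temperature_trace()
    dt = 1.0 / protocol.sampling_hz
    c_o2, c_hh, c_w = concentrations.trace(times)

    t_eff = temp
    if protocol.kind == "stepwise_rewarming":
        t_eff = _relaxed(temp, dt, relaxation_tau_s)

    eps_h2o_t = table.epsilon_h2o_ref[None, :] + (
        (t_eff - table.t_ref_c)[:, None] * table.kappa_h2o[None, :]
    )
    atten = pathlength_cm * (
        table.epsilon_o2hb[None, :] * c_o2[:, None]
        + table.epsilon_hhb[None, :] * c_hh[:, None]
        + eps_h2o_t * c_w[:, None]
    )

    systemic: dict[str, np.ndarray] = {}
    if systemic_spec is not None:
        s = systemic_spec
        lam = table.grid.wavelengths_nm
        phases = rng.uniform(0, 2 * np.pi, size=4)
        hr = (
            s.heart_rate_mean
            + s.heart_rate_amp * np.sin(2 * np.pi * times / s.heart_rate_period_s + phases[0])
            + s.jitter_sd * rng.standard_normal(times.size)
        )
        bp = (
            s.mean_bp_mean
            + s.mean_bp_amp * np.sin(2 * np.pi * times / s.mean_bp_period_s + phases[1])
            + s.jitter_sd * rng.standard_normal(times.size)
        )
        systemic = {"heart_rate": hr, "mean_bp": bp}
        for ch, mean, amp, phase in (
            (hr, s.heart_rate_mean, s.heart_rate_amp, phases[2]),
            (bp, s.mean_bp_mean, s.mean_bp_amp, phases[3]),
        ):
            profile = s.leakage_od * (0.5 + 0.5 * np.sin(2 * np.pi * (lam - 600.0) / 250.0 + phase))
            scale = amp if amp > 0 else 1.0
            atten = atten + profile[None, :] * ((ch - mean) / scale)[:, None]

    if noise_sd > 0:
        atten = atten + rng.normal(0.0, noise_sd, size=atten.shape)

    meta = {
        "generator": "nirstherm.synthetic.simulate_recording",
        "seed": int(seed),
        "noise_sd": float(noise_sd),
        "pathlength_cm": float(pathlength_cm),
        "relaxation_tau_s": float(relaxation_tau_s),
        "protocol": {
            "kind": protocol.kind,
            "t_start_c": protocol.t_start_c,
            "t_end_c": protocol.t_end_c,
            "duration_s": protocol.duration_s,
            "sampling_hz": protocol.sampling_hz,
            "step_interval_s": protocol.step_interval_s,
        },
        "concentrations": {
            "o2hb_mM": concentrations.o2hb_mM,
            "hhb_mM": concentrations.hhb_mM,
            "h2o_fraction": concentrations.h2o_fraction,
            "o2hb_drift_per_s": concentrations.o2hb_drift_per_s,
            "hhb_drift_per_s": concentrations.hhb_drift_per_s,
            "h2o_drift_per_s": concentrations.h2o_drift_per_s,
        },
        "systemic": systemic_spec is not None,
        "t_ref_c": table.t_ref_c,
    }
    return SpectralRecording(table.grid, times, atten, temp, systemic, meta)
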