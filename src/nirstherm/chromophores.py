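"""Modified Beer-Lambert (UCLn) inversion of attenuation into chromophores.

Attenuation changes divided by the effective optical pathlength are fitted,
per time point, by a least-squares inversion of the extinction-coefficient
matrix of the three tissue chromophores (O2Hb, HHb, H2O). The effective
pathlength is the optode separation times the differential pathlength factor
(DPF, 4.99 on the newborn head at 3 cm separation), optionally corrected per
wavelength. A second-derivative dialect differentiates both the attenuation
and the extinction columns along wavelength before the fit, which suppresses
slowly varying (scattering-like) baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .exceptions import CollinearityError, DegenerateInputError
from .preprocessing import WavelengthSelection
from .synthetic import ExtinctionTable

__all__ = [
    "PathlengthSpec",
    "ChromophoreSeries",
    "second_derivative",
    "ucln_invert",
    "concentration_temperature_r2",
]


@dataclass(frozen=True)
class PathlengthSpec:
    """Effective optical pathlength: separation x DPF x per-wavelength factor."""

    separation_cm: float = 3.0
    dpf: float = 4.99
    dpf_wavelength_correction: object = 1.0  # scalar or per-selected-wavelength array

    def __post_init__(self):
        if self.separation_cm <= 0 or self.dpf <= 0:
            raise ValueError("separation_cm and dpf must be positive")
        corr = np.asarray(self.dpf_wavelength_correction, dtype=float)
        if np.any(corr <= 0):
            raise ValueError("DPF wavelength correction factors must be positive")

    def pathlength_cm(self, n_wavelengths: int) -> np.ndarray:
        corr = np.asarray(self.dpf_wavelength_correction, dtype=float)
        base = self.separation_cm * self.dpf
        if corr.ndim == 0:
            return np.full(n_wavelengths, base * float(corr))
        if corr.shape != (n_wavelengths,):
            raise ValueError(
                f"correction length {corr.shape} != {n_wavelengths} wavelengths"
            )
        return base * corr


@dataclass(frozen=True)
class ChromophoreSeries:
    """Per-time chromophore concentration changes (tHb = O2Hb + HHb)."""

    times_s: np.ndarray
    d_o2hb: np.ndarray
    d_hhb: np.ndarray
    d_h2o: np.ndarray

    def __post_init__(self):
        for name in ("times_s", "d_o2hb", "d_hhb", "d_h2o"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.times_s.shape:
                raise ValueError(f"{name} length mismatch")

    @property
    def d_thb(self) -> np.ndarray:
        return self.d_o2hb + self.d_hhb

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "d_o2hb": self.d_o2hb,
                "d_hhb": self.d_hhb,
                "d_h2o": self.d_h2o,
                "d_thb": self.d_thb,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _uniform_spacing(wavelengths_nm: np.ndarray) -> float:
    d = np.diff(wavelengths_nm)
    if d.size == 0:
        raise ValueError("need at least 2 wavelengths")
    mean = d.mean()
    if np.max(np.abs(d - mean)) > 0.01 * mean:
        raise ValueError(
            "wavelength grid spacing varies by more than 1%; resample onto a "
            "uniform grid before taking spectral derivatives"
        )
    return float(mean)


def second_derivative(spectra: np.ndarray, wavelengths_nm: np.ndarray,
                      window_points: int = 11, poly_order: int = 3) -> np.ndarray:
    """Savitzky-Golay second derivative along wavelength (per nm^2)."""
    if poly_order < 2:
        raise ValueError("second derivative requires poly_order >= 2")
    window = int(window_points)
    if window % 2 == 0:
        window += 1
    if window <= poly_order:
        raise ValueError(f"window ({window}) must exceed poly_order ({poly_order})")
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if window > spectra.shape[1]:
        raise ValueError(
            f"window of {window} points exceeds {spectra.shape[1]} wavelengths"
        )
    delta = _uniform_spacing(np.asarray(wavelengths_nm, dtype=float))
    return savgol_filter(spectra, window, poly_order, deriv=2, delta=delta, axis=1)


_CHROMOPHORES = ("epsilon_o2hb", "epsilon_hhb", "epsilon_h2o_ref")


def _extinction_matrix(extinction: ExtinctionTable,
                       selection: WavelengthSelection) -> np.ndarray:
    cols = [getattr(extinction, name)[selection.indices] for name in _CHROMOPHORES]
    return np.column_stack(cols)


def _name_collinear_columns(E: np.ndarray) -> str:
    names = ("O2Hb", "HHb", "H2O")
    worst, pair = 0.0, (names[0], names[1])
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = E[:, i], E[:, j]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            c = abs(float(a @ b)) / denom if denom > 0 else 1.0
            if c > worst:
                worst, pair = c, (names[i], names[j])
    return f"{pair[0]} and {pair[1]} (|cos| = {worst:.6f})"


def ucln_invert(
    d_attenuation: np.ndarray,
    extinction: ExtinctionTable,
    selection: WavelengthSelection,
    path: PathlengthSpec,
    dialect: str = "raw_change",
    times_s: np.ndarray | None = None,
    window_points: int = 11,
    poly_order: int = 3,
) -> ChromophoreSeries:
    """Invert attenuation changes into chromophore concentration changes.

    ``d_attenuation`` is (n_times, n_grid) on the table's full grid;
    ``selection`` picks the wavelengths entering the fit (>= 3 required).
    Each row, divided by the per-wavelength pathlength, is least-squares
    fitted by the extinction matrix with columns [eps_O2Hb, eps_HHb,
    eps_H2O at t_ref]. With ``dialect='second_derivative'`` both attenuation
    and extinction columns are second-derivatived along the full grid first.
    """
    A = np.atleast_2d(np.asarray(d_attenuation, dtype=float))
    if A.shape[1] != len(extinction.grid):
        raise ValueError(
            f"attenuation has {A.shape[1]} wavelengths, grid has {len(extinction.grid)}"
        )
    if len(selection) < 3:
        raise ValueError(
            f"UCLn needs >= 3 wavelengths for 3 chromophores, got {len(selection)}"
        )
    lam_full = extinction.grid.wavelengths_nm
    if dialect == "second_derivative":
        A_fit = second_derivative(A, lam_full, window_points, poly_order)[:, selection.indices]
        E_full = np.column_stack([getattr(extinction, name) for name in _CHROMOPHORES])
        E = second_derivative(E_full.T, lam_full, window_points, poly_order).T[selection.indices]
    elif dialect == "raw_change":
        A_fit = A[:, selection.indices]
        E = _extinction_matrix(extinction, selection)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if np.linalg.matrix_rank(E) < 3:
        raise CollinearityError(
            "extinction matrix is rank deficient on the selected wavelengths; "
            f"most collinear columns: {_name_collinear_columns(E)}"
        )
    pl = path.pathlength_cm(len(selection))
    Y = (A_fit / pl[None, :]).T  # (n_sel, n_times)
    dc, *_ = np.linalg.lstsq(E, Y, rcond=None)
    if times_s is None:
        times_s = np.arange(A.shape[0], dtype=float)
    return ChromophoreSeries(np.asarray(times_s, dtype=float), dc[0], dc[1], dc[2])


def concentration_temperature_r2(series: ChromophoreSeries,
                                 temperature_c: np.ndarray) -> tuple[float, float]:
    """OLS R^2 of (d_h2o, d_thb) against the measured temperature."""
    temp = np.asarray(temperature_c, dtype=float)
    if temp.size != series.times_s.size or temp.size < 3:
        raise ValueError("temperature must match the series and have >= 3 points")
    if np.ptp(temp) == 0:
        raise DegenerateInputError("temperature is constant")
    out = []
    for y in (series.d_h2o, series.d_thb):
        if np.ptp(y) == 0:
            raise DegenerateInputError("constant concentration series")
        out.append(float(linregress(temp, y).rvalue ** 2))
    return out[0], out[1]
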