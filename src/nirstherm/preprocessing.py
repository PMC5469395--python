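"""Spectral preprocessing: smoothing, quantile binning, confound removal.

Covers the steps applied to the raw attenuation matrices before calibration:
Savitzky-Golay smoothing, decile (10-quantile) binning of attenuation against
temperature or wavelength for display/statistics, least-squares removal of
systemic physiology (heart rate, mean blood pressure), extraction of one
sample per rewarming step, and wavelength selection (740 / 840 / 970 nm and
the 720-880 nm band).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .exceptions import (
    CollinearityError,
    DegenerateInputError,
    RangeError,
    SelectionError,
)
from .synthetic import SpectralRecording, WavelengthGrid

__all__ = [
    "BinnedAttenuation",
    "WavelengthSelection",
    "smooth_spectra",
    "bin_by_temperature",
    "bin_by_wavelength",
    "attenuation_temperature_r2",
    "regress_out_systemic",
    "extract_step_responses",
    "select_wavelengths",
    "detect_steps",
]

N_BINS = 10


@dataclass(frozen=True)
class BinnedAttenuation:
    """One decile bin of attenuation samples.

    In ``temperature_binned`` mode, ``values`` is the per-wavelength mean
    attenuation of the samples in the bin and ``bin_label`` the bin's mean
    temperature (degC). In ``wavelength_binned`` mode, ``values`` is the
    per-time mean difference attenuation over the bin's wavelengths (relative
    to the minimum-temperature sample) and ``bin_label`` the mean wavelength
    (nm).
    """

    mode: str
    bin_index: int  # 1..10
    bin_label: float
    values: np.ndarray
    count: int
    reference_subtracted: bool = False


@dataclass(frozen=True)
class WavelengthSelection:
    """Named subset of grid wavelengths used for calibration/inversion."""

    label: str
    indices: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "wavelengths_nm", lam)
        if idx.size != lam.size or idx.size == 0:
            raise ValueError("selection must be non-empty with matching arrays")

    def __len__(self) -> int:
        return self.indices.size


_SINGLE_LABELS = {"740": 740.0, "840": 840.0, "970": 970.0}
_BAND_LO, _BAND_HI = 720.0, 880.0


def select_wavelengths(grid: WavelengthGrid, label, *,
                       nominal_tolerance_nm: float = 5.0) -> WavelengthSelection:
    """Resolve a selection label on ``grid``.

    Labels: ``"740"``, ``"840"``, ``"970"`` (nearest grid point; refused if
    the nominal wavelength misses the grid span by more than
    ``nominal_tolerance_nm``), ``"band_720_880"`` (all points in [720, 880] nm;
    refused if the grid does not cover the band to within the tolerance), or
    an explicit sequence of wavelengths (label ``"custom"``).
    """
    lam = grid.wavelengths_nm
    key = str(label)
    if key in _SINGLE_LABELS:
        nominal = _SINGLE_LABELS[key]
        i = grid.nearest_index(nominal)
        if abs(lam[i] - nominal) > nominal_tolerance_nm:
            raise SelectionError(
                f"nominal {nominal:g} nm is {abs(lam[i] - nominal):.1f} nm from the "
                f"nearest grid point ({lam[i]:g} nm); grid spans "
                f"{lam[0]:g}-{lam[-1]:g} nm"
            )
        return WavelengthSelection(key, np.array([i]), np.array([lam[i]]))
    if key == "band_720_880":
        if lam[0] > _BAND_LO + nominal_tolerance_nm or lam[-1] < _BAND_HI - nominal_tolerance_nm:
            raise SelectionError(
                f"grid {lam[0]:g}-{lam[-1]:g} nm does not cover the "
                f"{_BAND_LO:g}-{_BAND_HI:g} nm band"
            )
        idx = np.where((lam >= _BAND_LO) & (lam <= _BAND_HI))[0]
        return WavelengthSelection(key, idx, lam[idx])
    if isinstance(label, (list, tuple, np.ndarray)):
        idx = []
        for nominal in label:
            i = grid.nearest_index(float(nominal))
            if abs(lam[i] - float(nominal)) > nominal_tolerance_nm:
                raise SelectionError(
                    f"nominal {float(nominal):g} nm outside grid span "
                    f"{lam[0]:g}-{lam[-1]:g} nm"
                )
            idx.append(i)
        idx = np.array(sorted(set(idx)), dtype=int)
        return WavelengthSelection("custom", idx, lam[idx])
    raise SelectionError(f"unknown wavelength selection label {label!r}")


def smooth_spectra(recording: SpectralRecording, window_points: int = 60,
                   poly_order: int = 3, axis: str = "wavelength") -> SpectralRecording:
    """Savitzky-Golay smooth the attenuation along wavelength or time.

    The window is forced to the next odd integer >= ``window_points``.
    Temperature and systemic channels are untouched.
    """
    if axis not in ("wavelength", "time"):
        raise ValueError("axis must be 'wavelength' or 'time'")
    window = int(window_points)
    if window % 2 == 0:
        window += 1
    if window <= poly_order:
        raise ValueError(
            f"window ({window}) must exceed polynomial order ({poly_order})"
        )
    ax = 1 if axis == "wavelength" else 0
    n_axis = recording.attenuation.shape[ax]
    if window > n_axis:
        raise ValueError(
            f"window of {window} points exceeds the {axis} axis length {n_axis}"
        )
    smoothed = savgol_filter(recording.attenuation, window, poly_order, axis=ax)
    return recording.with_attenuation(
        smoothed, smoothing={"window": window, "poly_order": poly_order, "axis": axis}
    )


def _decile_slices(n: int) -> list[slice]:
    """Split n sorted samples into 10 equal-count bins, remainder to the
    lowest bins."""
    base, rem = divmod(n, N_BINS)
    sizes = [base + 1 if i < rem else base for i in range(N_BINS)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(edges[i]), int(edges[i + 1])) for i in range(N_BINS)]


def bin_by_temperature(recording: SpectralRecording) -> list[BinnedAttenuation]:
    """Bin time samples into temperature deciles; mean spectrum per bin.

    Samples are sorted by measured temperature (ties broken by time order)
    and split into 10 equal-count bins, the remainder going to the
    lowest-temperature bins.
    """
    n = recording.n_times
    if n < N_BINS:
        raise ValueError(f"need at least {N_BINS} samples, got {n}")
    temp = recording.temperature_c
    if np.ptp(temp) == 0:
        raise DegenerateInputError("temperature is constant; cannot bin")
    order = np.argsort(temp, kind="stable")
    bins = []
    for i, sl in enumerate(_decile_slices(n)):
        idx = order[sl]
        bins.append(
            BinnedAttenuation(
                mode="temperature_binned",
                bin_index=i + 1,
                bin_label=float(np.mean(temp[idx])),
                values=recording.attenuation[idx].mean(axis=0),
                count=idx.size,
            )
        )
    return bins


def bin_by_wavelength(recording: SpectralRecording,
                      band: WavelengthSelection) -> list[BinnedAttenuation]:
    """Bin the band's wavelengths into deciles; difference attenuation per bin.

    Attenuation is first referenced to the sample at the minimum measured
    temperature (per wavelength), then averaged over each wavelength decile,
    giving one difference-attenuation time series per bin.
    """
    if len(band) < N_BINS:
        raise ValueError(f"band must select >= {N_BINS} wavelengths, got {len(band)}")
    i_ref = int(np.argmin(recording.temperature_c))
    diff = recording.attenuation - recording.attenuation[i_ref][None, :]
    lam = recording.grid.wavelengths_nm
    bins = []
    for i, sl in enumerate(_decile_slices(len(band))):
        cols = band.indices[sl]
        bins.append(
            BinnedAttenuation(
                mode="wavelength_binned",
                bin_index=i + 1,
                bin_label=float(np.mean(lam[cols])),
                values=diff[:, cols].mean(axis=1),
                count=cols.size,
                reference_subtracted=True,
            )
        )
    return bins


def attenuation_temperature_r2(binned: Sequence[BinnedAttenuation]) -> float:
    """OLS R^2 of the per-bin mean attenuation against bin index 1..10."""
    if len(binned) != N_BINS:
        raise ValueError(f"expected {N_BINS} bins, got {len(binned)}")
    y = np.array([float(np.mean(b.values)) for b in binned])
    if np.ptp(y) == 0:
        raise DegenerateInputError("bin means have zero variance")
    res = linregress(np.arange(1, N_BINS + 1, dtype=float), y)
    return float(res.rvalue**2)


def regress_out_systemic(recording: SpectralRecording) -> SpectralRecording:
    """Remove systemic-physiology confounds per wavelength by OLS.

    Each wavelength's attenuation is replaced by its residual after
    regression on [intercept, systemic channels]; residuals are orthogonal to
    every channel.
    """
    channels = recording.systemic
    if not channels:
        raise ValueError("recording has no systemic channels")
    n = recording.n_times
    names = sorted(channels)
    Z = np.column_stack([channels[name] for name in names])
    if n <= Z.shape[1] + 1:
        raise ValueError("need more time points than systemic channels + 1")
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"systemic design (intercept + {names}) is rank deficient")
    beta, *_ = np.linalg.lstsq(X, recording.attenuation, rcond=None)
    residuals = recording.attenuation - X @ beta
    return recording.with_attenuation(residuals, systemic_regressed=names)


def detect_steps(recording: SpectralRecording, threshold_c: float = 0.2) -> np.ndarray:
    """Times (s) where the reference temperature jumps by more than
    ``threshold_c`` between consecutive samples."""
    jumps = np.where(np.abs(np.diff(recording.temperature_c)) > threshold_c)[0]
    return recording.times_s[jumps + 1]


def extract_step_responses(recording: SpectralRecording,
                           step_times_s: Sequence[float],
                           window_s: float = 60.0) -> SpectralRecording:
    """Collapse a stepwise recording to one sample per temperature step.

    For each step, within the ``window_s`` interval starting at the step, the
    per-wavelength signal difference is the largest absolute excursion from
    the window's first sample (signed). The output temperature is the
    post-step plateau value (end of window); the output has exactly one time
    sample per step.
    """
    steps = np.asarray(step_times_s, dtype=float)
    if steps.size == 0:
        raise ValueError("no step times given")
    if np.any(np.diff(steps) < window_s):
        raise ValueError(f"step windows of {window_s} s overlap")
    t = recording.times_s
    if steps[0] < t[0] or steps[-1] + window_s > t[-1]:
        raise RangeError(
            f"step window [{steps[0]:g}, {steps[-1] + window_s:g}] s outside "
            f"recording span [{t[0]:g}, {t[-1]:g}] s"
        )
    diffs = np.empty((steps.size, len(recording.grid)))
    temps = np.empty(steps.size)
    for k, s in enumerate(steps):
        mask = (t >= s) & (t <= s + window_s)
        window = recording.attenuation[mask]
        exc = window - window[0][None, :]
        peak_rows = np.argmax(np.abs(exc), axis=0)
        diffs[k] = exc[peak_rows, np.arange(exc.shape[1])]
        temps[k] = recording.temperature_c[mask][-1]
    meta = {**recording.meta, "step_extraction": {"window_s": window_s,
                                                  "n_steps": int(steps.size)}}
    return SpectralRecording(recording.grid, steps, diffs, temps, {}, meta)
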