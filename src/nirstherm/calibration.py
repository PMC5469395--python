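"""Water-spectrum temperature calibration (CLS / ILS / PCR / PLSR).

The calibration set is simulated: pure-water extinction spectra evaluated on
the selected wavelengths at temperatures spanning 30-40 degC. A linear
calibration is fitted so that a measured attenuation spectrum multiplied by
the calibration vector (plus intercept) yields a raw temperature; baseline
anchoring then adds a constant so the first predicted sample equals the
reference temperature at recording onset, absorbing the unknown offset
between tissue attenuation and the pure-water training scale.

Methods
-------
CLS   classical least squares: fit the forward model spectrum = s0 + slope*T
      per wavelength, predict by projecting onto the slope spectrum.
ILS   inverse least squares: regress T directly on the (centred) spectra via
      the pseudoinverse.
PCR   principal component regression: regress T on the top-k principal
      component scores of the mean-centred spectra.
PLSR  partial least squares (single-response NIPALS with deflation):
      components maximise score covariance with T.

All four export an equivalent per-wavelength calibration vector + intercept,
so prediction is uniform across methods. The number of components is chosen
by K-fold (default 10-fold, optionally leave-one-out) cross-validation,
taking the smallest k whose CV error is within tolerance of the minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CompatibilityError, DegenerateInputError
from .preprocessing import WavelengthSelection
from .synthetic import ExtinctionTable, SpectralRecording, water_extinction

__all__ = [
    "CalibrationSet",
    "CalibrationModel",
    "TemperaturePrediction",
    "build_calibration_set",
    "fit_cls",
    "fit_ils",
    "fit_pcr",
    "fit_plsr",
    "select_num_components",
    "predict_temperature",
]

MAX_COMPONENTS = 10


@dataclass(frozen=True)
class CalibrationSet:
    """Simulated training spectra (temperature x wavelength)."""

    temperatures_c: np.ndarray
    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    gain: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.temperatures_c, dtype=float)
        X = np.asarray(self.spectra, dtype=float)
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "temperatures_c", t)
        object.__setattr__(self, "spectra", X)
        object.__setattr__(self, "wavelengths_nm", lam)
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if X.shape != (t.size, lam.size):
            raise ValueError(
                f"spectra shape {X.shape} != ({t.size} temperatures, {lam.size} wavelengths)"
            )

    @property
    def n_levels(self) -> int:
        return self.temperatures_c.size

    def centred_rank(self) -> int:
        Xc = self.spectra - self.spectra.mean(axis=0)
        return int(np.linalg.matrix_rank(Xc))


def build_calibration_set(table: ExtinctionTable, selection: WavelengthSelection,
                          t_min_c: float = 30.0, t_max_c: float = 40.0,
                          n_levels: int = 101, gain: float = 1.0) -> CalibrationSet:
    """Evaluate pure-water extinction on ``selection`` over a temperature sweep.

    ``gain`` converts extinction units to the attenuation units of the
    recordings the model will be applied to (for the forward model used by
    the simulator, gain = pathlength_cm x water fraction). Level offsets are
    absorbed by baseline anchoring at prediction time; gain affects the
    predicted temperature *scale*.
    """
    if len(selection) == 0:
        raise ValueError("selection must be non-empty")
    if not t_min_c < t_max_c:
        raise ValueError("t_min_c must be below t_max_c")
    if n_levels < 2:
        raise ValueError("need at least 2 temperature levels")
    temps = np.linspace(t_min_c, t_max_c, n_levels)
    spectra = np.stack([
        gain * water_extinction(table, t)[selection.indices] for t in temps
    ])
    return CalibrationSet(temps, spectra, selection.wavelengths_nm, gain)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear temperature calibration.

    ``calibration_vector``/``intercept`` map a spectrum on
    ``wavelengths_nm`` to a raw temperature; ``scores``/``loadings`` are kept
    for PCR/PLSR diagnostics.
    """

    method: str
    calibration_vector: np.ndarray
    intercept: float
    wavelengths_nm: np.ndarray
    training_range_c: tuple[float, float]
    selection_label: str = "custom"
    n_components: int | None = None
    scores: np.ndarray | None = None
    loadings: np.ndarray | None = None
    cv_error_by_k: np.ndarray | None = None

    def predict_raw(self, spectra: np.ndarray) -> np.ndarray:
        return np.atleast_2d(spectra) @ self.calibration_vector + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "calibration_vector": self.calibration_vector.tolist(),
            "intercept": float(self.intercept),
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "training_range_c": list(self.training_range_c),
            "selection_label": self.selection_label,
            "n_components": self.n_components,
            "cv_error_by_k": (None if self.cv_error_by_k is None
                              else self.cv_error_by_k.tolist()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            method=d["method"],
            calibration_vector=np.array(d["calibration_vector"], dtype=float),
            intercept=float(d["intercept"]),
            wavelengths_nm=np.array(d["wavelengths_nm"], dtype=float),
            training_range_c=tuple(d["training_range_c"]),
            selection_label=d.get("selection_label", "custom"),
            n_components=d.get("n_components"),
            cv_error_by_k=(None if d.get("cv_error_by_k") is None
                           else np.array(d["cv_error_by_k"], dtype=float)),
        )


def _centred(calset: CalibrationSet):
    X = calset.spectra
    y = calset.temperatures_c
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    if np.allclose(Xc, 0):
        raise DegenerateInputError("training spectra are constant")
    return Xc, y - y_mean, x_mean, y_mean


def _check_k(k: int, Xc: np.ndarray) -> None:
    rank = int(np.linalg.matrix_rank(Xc))
    if not 1 <= k <= min(MAX_COMPONENTS, rank):
        raise ValueError(
            f"n_components={k} outside [1, min({MAX_COMPONENTS}, rank={rank})]"
        )


def _model(calset, method, b, intercept, **extra) -> CalibrationModel:
    return CalibrationModel(
        method=method,
        calibration_vector=np.asarray(b, dtype=float).ravel(),
        intercept=float(intercept),
        wavelengths_nm=calset.wavelengths_nm,
        training_range_c=(float(calset.temperatures_c[0]),
                          float(calset.temperatures_c[-1])),
        **extra,
    )


def fit_cls(calset: CalibrationSet) -> CalibrationModel:
    """Classical least squares: forward model per wavelength, then invert."""
    Xc, yc, x_mean, y_mean = _centred(calset)
    # slope(lam) = d spectrum / d T  (exact OLS since yc is the regressor)
    slope = (Xc.T @ yc) / (yc @ yc)
    denom = slope @ slope
    if denom == 0:
        raise DegenerateInputError("spectra carry no temperature dependence")
    b = slope / denom
    intercept = y_mean - x_mean @ b
    return _model(calset, "CLS", b, intercept)


def fit_ils(calset: CalibrationSet, rcond: float = 1e-10) -> CalibrationModel:
    """Inverse least squares with intercept (pseudoinverse for rank deficiency).

    ``rcond`` is the relative singular-value cutoff of the pseudoinverse;
    directions below it carry no usable training variance (numerically flat
    simulated spectra) and would only amplify noise.
    """
    Xc, yc, x_mean, y_mean = _centred(calset)
    b = np.linalg.pinv(Xc, rcond=rcond) @ yc
    intercept = y_mean - x_mean @ b
    return _model(calset, "ILS", b, intercept)


def fit_pcr(calset: CalibrationSet, k: int) -> CalibrationModel:
    """Principal component regression on the top-k PCs of centred spectra."""
    Xc, yc, x_mean, y_mean = _centred(calset)
    _check_k(k, Xc)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    gamma = (U[:, :k].T @ yc) / s[:k]
    b = Vt[:k].T @ gamma
    intercept = y_mean - x_mean @ b
    return _model(calset, "PCR", b, intercept, n_components=k,
                  scores=scores, loadings=Vt[:k].T)


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """Single-response NIPALS with deflation; returns W, P, q, T (scores)."""
    n, p = Xc.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    T = np.zeros((n, k))
    X = Xc.copy()
    y = yc.copy()
    norm0 = np.linalg.norm(Xc.T @ yc)
    n_found = 0
    for a in range(k):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if norm0 == 0 or nw <= 1e-12 * norm0:
            break  # residual covariance exhausted (rank reached)
        w /= nw
        t = X @ w
        tt = t @ t
        p_vec = (X.T @ t) / tt
        q_a = (y @ t) / tt
        X = X - np.outer(t, p_vec)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_vec, q_a, t
        n_found = a + 1
    return W[:, :n_found], P[:, :n_found], q[:n_found], T[:, :n_found]


def fit_plsr(calset: CalibrationSet, k: int) -> CalibrationModel:
    """Partial least squares regression (single-response NIPALS)."""
    Xc, yc, x_mean, y_mean = _centred(calset)
    _check_k(k, Xc)
    W, P, q, T = _nipals(Xc, yc, k)
    b = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - x_mean @ b
    return _model(calset, "PLSR", b, intercept, n_components=W.shape[1],
                  scores=T, loadings=P)


_FITTERS = {"plsr": fit_plsr, "pcr": fit_pcr}


def _fit_clipped(X_train, y_train, k: int, method: str) -> tuple[np.ndarray, float]:
    """Fit on raw arrays, silently capping k at the training rank (CV helper)."""
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    Xc = X_train - x_mean
    yc = y_train - y_mean
    rank = int(np.linalg.matrix_rank(Xc))
    k_eff = max(1, min(k, rank))
    if method == "plsr":
        W, P, q, _ = _nipals(Xc, yc, k_eff)
        if W.shape[1] == 0:
            return np.zeros(X_train.shape[1]), float(y_mean)
        b = W @ np.linalg.solve(P.T @ W, q)
    elif method == "pcr":
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        k_eff = min(k_eff, int(np.sum(s > 1e-12 * s[0]))) if s.size else 0
        if k_eff == 0:
            return np.zeros(X_train.shape[1]), float(y_mean)
        b = Vt[:k_eff].T @ ((U[:, :k_eff].T @ yc) / s[:k_eff])
    else:
        raise ValueError(f"unknown method {method!r}")
    return b, float(y_mean - x_mean @ b)


def select_num_components(calset: CalibrationSet, k_max: int = MAX_COMPONENTS,
                          folds: int = 10, seed: int | None = None,
                          method: str = "plsr", loo: bool = False,
                          tol_rel: float = 1e-8, tol_abs: float = 1e-12,
                          ) -> tuple[int, np.ndarray]:
    """Choose the number of components by K-fold cross-validation.

    Folds are contiguous by default, or a seeded random permutation when
    ``seed`` is given; ``loo=True`` sets folds = number of training rows.
    Returns ``(k_best, cv_error_by_k)`` where ``cv_error_by_k[k-1]`` is the
    mean squared held-out temperature error for k components and ``k_best``
    is the smallest k whose error is within tolerance of the minimum
    (parsimony tie-break).
    """
    if method not in _FITTERS:
        raise ValueError(f"method must be one of {sorted(_FITTERS)}")
    n = calset.n_levels
    if loo:
        folds = n
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds training rows ({n})")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    idx = np.arange(n)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n)
    fold_ids = np.array_split(idx, folds)

    X, y = calset.spectra, calset.temperatures_c
    cv = np.zeros(k_max)
    for k in range(1, k_max + 1):
        sq_err = 0.0
        for test_idx in fold_ids:
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            b, b0 = _fit_clipped(X[train_mask], y[train_mask], k, method)
            pred = X[test_idx] @ b + b0
            sq_err += float(np.sum((pred - y[test_idx]) ** 2))
        cv[k - 1] = sq_err / n
    cv_min = cv.min()
    within = np.where(cv <= cv_min * (1 + tol_rel) + tol_abs)[0]
    return int(within[0] + 1), cv


@dataclass(frozen=True)
class TemperaturePrediction:
    """Paired measured/predicted temperature series with baseline anchor."""

    times_s: np.ndarray
    measured_c: np.ndarray
    predicted_c: np.ndarray
    baseline_anchor_c: float
    model: CalibrationModel | None = None
    subject_id: str | None = None

    def __post_init__(self):
        for name in ("times_s", "measured_c", "predicted_c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.times_s.shape:
                raise ValueError(f"{name} length mismatch")
        if not np.all(np.isfinite(self.predicted_c)):
            raise ValueError("predicted temperatures contain non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times_s, "measured_c": self.measured_c,
             "predicted_c": self.predicted_c}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TemperaturePrediction":
        df = pd.read_csv(path)
        return cls(
            times_s=df["time_s"].to_numpy(),
            measured_c=df["measured_c"].to_numpy(),
            predicted_c=df["predicted_c"].to_numpy(),
            baseline_anchor_c=float(df["measured_c"].iloc[0]),
            subject_id=str(Path(path).stem),
        )


def predict_temperature(model: CalibrationModel, recording: SpectralRecording,
                        anchor="first_measured",
                        pre_transform=None) -> TemperaturePrediction:
    """Apply a calibration to a recording with baseline anchoring.

    The model's wavelengths are matched against the recording grid (within
    0.01 nm). Raw prediction = attenuation . calibration_vector + intercept;
    the anchored prediction subtracts the first raw value and adds the anchor
    (default: the first measured temperature), so predicted[0] == anchor.
    ``pre_transform`` optionally maps the selected attenuation matrix before
    the dot product (e.g. a derivative transform).
    """
    lam_rec = recording.grid.wavelengths_nm
    idx = []
    for nm in model.wavelengths_nm:
        j = int(np.argmin(np.abs(lam_rec - nm)))
        if abs(lam_rec[j] - nm) > 0.01:
            raise CompatibilityError(
                f"model wavelength {nm:g} nm not on the recording grid"
            )
        idx.append(j)
    A = recording.attenuation[:, idx]
    if pre_transform is not None:
        A = pre_transform(A)
    raw = A @ model.calibration_vector + model.intercept
    anchor_c = (float(recording.temperature_c[0]) if anchor == "first_measured"
                else float(anchor))
    predicted = raw - raw[0] + anchor_c
    return TemperaturePrediction(
        times_s=recording.times_s,
        measured_c=recording.temperature_c,
        predicted_c=predicted,
        baseline_anchor_c=anchor_c,
        model=model,
    )
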