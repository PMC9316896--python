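"""Spectral preprocessing and PLS calibration for surface residue.

Calibration models for cleaning verification are not built on the full
650-4000 cm^-1 trace but on narrow windows around the API's strong
bands (e.g. a single 1200.20-1259.84 cm^-1 window, or two windows for a
two-band API).  Within each window a two-point linear baseline is
removed, which makes predictions immune to the additive offset and tilt
produced by coupon-to-coupon surface roughness.  A univariate-response
partial-least-squares model (NIPALS with deflation) then maps the
preprocessed channels to surface density in ug/cm^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .synthetic import Spectrum

__all__ = [
    "SpectralWindowSet",
    "PreprocessSpec",
    "WindowedChannels",
    "CalibrationSet",
    "PlsModel",
    "Prediction",
    "CoverageError",
    "DegenerateDataError",
    "ConvergenceError",
    "DEFAULT_WINDOWS",
    "restrict_to_windows",
    "baseline_correct",
    "preprocess",
    "build_calibration_set",
    "fit_pls",
    "predict",
    "cross_val_rmse",
    "choose_components_cv",
    "model_to_json",
    "model_from_json",
]


class CoverageError(ValueError):
    """Spectrum grid does not cover a requested window."""


class DegenerateDataError(ValueError):
    """Calibration data carry no usable variance."""


class ConvergenceError(RuntimeError):
    """A latent-variable inner iteration failed to converge."""

    def __init__(self, component: int, message: str | None = None):
        self.component = component
        super().__init__(message or f"component {component} did not converge")


@dataclass(frozen=True)
class SpectralWindowSet:
    """Non-overlapping closed wavenumber intervals, in cm^-1."""

    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        wins = tuple((float(a), float(b)) for a, b in self.windows)
        object.__setattr__(self, "windows", wins)
        if not wins:
            raise ValueError("at least one window required")
        for lo, hi in wins:
            if not lo < hi:
                raise ValueError(f"window ({lo}, {hi}) has low >= high")
        ordered = sorted(wins)
        for (_, hi1), (lo2, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi1:
                raise ValueError("windows overlap")


#: Default single-band model window, matching the strong band of the
#: default synthetic API signature.
DEFAULT_WINDOWS = SpectralWindowSet(((1200.20, 1259.84),))


@dataclass(frozen=True)
class PreprocessSpec:
    """What happens to a raw spectrum before regression."""

    windows: SpectralWindowSet = DEFAULT_WINDOWS
    baseline_mode: str = "linear"  # {"none", "linear"} per window
    centering: str = "mean"  # {"none", "mean"}

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("none", "linear"):
            raise ValueError("baseline_mode must be 'none' or 'linear'")
        if self.centering not in ("none", "mean"):
            raise ValueError("centering must be 'none' or 'mean'")


@dataclass(frozen=True)
class WindowedChannels:
    """Channels retained by a window set, keeping per-window segment sizes
    so baseline correction can act window by window."""

    wavenumbers: np.ndarray
    values: np.ndarray
    segments: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavenumbers", np.asarray(self.wavenumbers, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.wavenumbers) != len(self.values):
            raise ValueError("length mismatch")
        if sum(self.segments) != len(self.values):
            raise ValueError("segments do not partition the channels")


def restrict_to_windows(
    spectrum: Spectrum, windows: SpectralWindowSet
) -> WindowedChannels:
    """Keep channels whose wavenumber lies in a window (closed intervals).

    Windows are processed in their given order; channels stay ascending
    within each window.  Raises :class:`CoverageError` when a window
    falls outside the spectrum grid or retains no channel.
    """
    wn = spectrum.wavenumbers
    vals = spectrum.absorbance
    parts_w, parts_v, seg = [], [], []
    for lo, hi in windows.windows:
        if lo < wn[0] or hi > wn[-1]:
            raise CoverageError(
                f"window ({lo}, {hi}) outside spectrum grid [{wn[0]}, {wn[-1]}]"
            )
        mask = (wn >= lo) & (wn <= hi)
        count = int(mask.sum())
        if count == 0:
            raise CoverageError(f"window ({lo}, {hi}) retains no channel")
        parts_w.append(wn[mask])
        parts_v.append(vals[mask])
        seg.append(count)
    return WindowedChannels(
        np.concatenate(parts_w), np.concatenate(parts_v), tuple(seg)
    )


def baseline_correct(channels: WindowedChannels, mode: str = "linear") -> WindowedChannels:
    """Remove a two-point linear baseline per window.

    In ``linear`` mode the straight line through the first and last
    channel of each window is subtracted, so the window's endpoints map
    to zero; constant offsets and linear tilts are removed exactly.
    ``none`` is the identity.
    """
    if mode == "none":
        return channels
    if mode != "linear":
        raise ValueError("mode must be 'none' or 'linear'")
    out = channels.values.copy()
    start = 0
    for count in channels.segments:
        if count < 3:
            raise DegenerateDataError(
                f"linear baseline needs >= 3 channels per window, got {count}"
            )
        sl = slice(start, start + count)
        w = channels.wavenumbers[sl]
        v = out[sl]
        slope = (v[-1] - v[0]) / (w[-1] - w[0])
        out[sl] = v - (v[0] + slope * (w - w[0]))
        start += count
    return WindowedChannels(channels.wavenumbers, out, channels.segments)


def preprocess(spectrum: Spectrum, spec: PreprocessSpec) -> WindowedChannels:
    """Window restriction followed by baseline correction."""
    return baseline_correct(restrict_to_windows(spectrum, spec.windows), spec.baseline_mode)


@dataclass(frozen=True)
class CalibrationSet:
    """Preprocessed predictor matrix with responses in ug/cm^2."""

    X: np.ndarray  # (n_samples, n_channels)
    y: np.ndarray  # (n_samples,)
    spec: PreprocessSpec
    wavenumbers: np.ndarray
    segments: tuple[int, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per response")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 calibration samples")


def build_calibration_set(
    spectra: Sequence[Spectrum],
    responses: Sequence[float] | None = None,
    spec: PreprocessSpec | None = None,
) -> CalibrationSet:
    """Assemble a calibration set from labelled spectra.

    When ``responses`` is omitted, the spectra's ``true_density`` labels
    are used (the simulator attaches them).
    """
    spec = spec or PreprocessSpec()
    if responses is None:
        responses = [s.true_density for s in spectra]
        if any(r is None for r in responses):
            raise ValueError("spectra lack true_density labels; pass responses")
    if len(spectra) != len(responses):
        raise ValueError("spectra and responses must have equal length")
    rows = [preprocess(s, spec) for s in spectra]
    X = np.vstack([r.values for r in rows])
    return CalibrationSet(
        X=X,
        y=np.asarray(responses, dtype=float),
        spec=spec,
        wavenumbers=rows[0].wavenumbers,
        segments=rows[0].segments,
    )


@dataclass(frozen=True)
class PlsModel:
    """Fitted univariate PLS calibration.

    ``coef`` is the regression vector on centered channels:
    prediction = (x - x_mean) @ coef + y_mean.  ``calibration_floor``
    (ug/cm^2) is set from an LOQ study; predictions below it are
    flagged.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (n_channels, n_components)
    loadings: np.ndarray  # (n_channels, n_components)
    y_loadings: np.ndarray  # (n_components,)
    coef: np.ndarray  # (n_channels,)
    y_range: tuple[float, float]
    spec: PreprocessSpec
    wavenumbers: np.ndarray = field(repr=False)
    segments: tuple[int, ...] = ()
    calibration_floor: float | None = None


NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


def fit_pls(cal: CalibrationSet, n_components: int) -> PlsModel:
    """Fit a PLS1 model by the NIPALS latent-variable recursion.

    Predictors and response are mean-centered; each component extracts a
    weight vector, score, and loadings, then deflates both blocks.  With
    ``n_components`` equal to the predictor rank this reproduces the
    least-squares solution.
    """
    X = cal.X.copy()
    y = cal.y.copy()
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    if np.ptp(y) == 0:
        raise DegenerateDataError("responses are all equal")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if not np.any(Xc):
        raise DegenerateDataError("predictor block has zero variance")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    # covariance below this is numerically exhausted rank, not signal
    cov_tol = 1e-10 * max(np.linalg.norm(Xc) * np.linalg.norm(yc), 1e-300)
    for a in range(n_components):
        # Inner iteration; for a single response it converges in one pass.
        u = yc
        w = Xc.T @ u
        norm = np.linalg.norm(w)
        if norm <= cov_tol:
            raise DegenerateDataError(f"no covariance left at component {a + 1}")
        w = w / norm
        for it in range(NIPALS_MAX_ITER):
            t = Xc @ w
            tt = t @ t
            if tt == 0:
                raise DegenerateDataError(f"zero score at component {a + 1}")
            q = (yc @ t) / tt
            u = yc * q
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise DegenerateDataError(f"no covariance left at component {a + 1}")
            w_new = w_new / norm
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        else:  # pragma: no cover - unreachable for univariate response
            raise ConvergenceError(a + 1)
        t = Xc @ w
        tt = t @ t
        p_a = (Xc.T @ t) / tt
        q_a = (yc @ t) / tt
        Xc = Xc - np.outer(t, p_a)
        yc = yc - t * q_a
        W[:, a], P[:, a], Q[a] = w, p_a, q_a

    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PlsModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=Q,
        coef=coef,
        y_range=(float(cal.y.min()), float(cal.y.max())),
        spec=cal.spec,
        wavenumbers=cal.wavenumbers,
        segments=cal.segments,
    )


@dataclass(frozen=True)
class Prediction:
    """A predicted surface density with its quality flags."""

    value: float  # ug/cm^2
    below_floor: bool
    extrapolated: bool

    @property
    def flagged(self) -> bool:
        return self.below_floor or self.extrapolated


def predict(model: PlsModel, spectrum: Spectrum) -> Prediction:
    """Apply the recorded preprocessing and regression vector.

    The value is always returned; ``below_floor`` marks results under
    the model's calibration floor and ``extrapolated`` marks results
    outside the training response range.
    """
    channels = preprocess(spectrum, model.spec)
    if len(channels.values) != len(model.coef):
        raise CoverageError("spectrum grid does not match the model's channels")
    value = float((channels.values - model.x_mean) @ model.coef + model.y_mean)
    lo, hi = model.y_range
    below = model.calibration_floor is not None and value < model.calibration_floor
    return Prediction(value=value, below_floor=below, extrapolated=not lo <= value <= hi)


def predict_many(model: PlsModel, spectra: Sequence[Spectrum]) -> list[Prediction]:
    return [predict(model, s) for s in spectra]


# ---------------------------------------------------------------------------
# Component selection
# ---------------------------------------------------------------------------


def _level_block_folds(y: np.ndarray, folds: int) -> list[np.ndarray]:
    """Contiguous blocks of response levels; replicates of a level never
    straddle folds, so replicate structure cannot leak."""
    levels = np.unique(y)
    if folds > len(levels):
        raise ValueError("more folds than distinct response levels")
    blocks = np.array_split(levels, folds)
    return [np.flatnonzero(np.isin(y, b)) for b in blocks]


def cross_val_rmse(
    cal: CalibrationSet, n_components: int, folds: int = 3
) -> float:
    """Level-blocked cross-validated RMSE of prediction (ug/cm^2)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    errors: list[np.ndarray] = []
    for test_idx in _level_block_folds(cal.y, folds):
        train_idx = np.setdiff1d(np.arange(len(cal.y)), test_idx)
        sub = CalibrationSet(
            X=cal.X[train_idx],
            y=cal.y[train_idx],
            spec=cal.spec,
            wavenumbers=cal.wavenumbers,
            segments=cal.segments,
        )
        k = min(n_components, min(len(train_idx) - 1, cal.X.shape[1]))
        model = fit_pls(sub, k)
        pred = (cal.X[test_idx] - model.x_mean) @ model.coef + model.y_mean
        errors.append(pred - cal.y[test_idx])
    err = np.concatenate(errors)
    return float(np.sqrt(np.mean(err**2)))


def choose_components_cv(
    cal: CalibrationSet,
    max_components: int,
    folds: int = 3,
    seed: int | None = 0,
) -> int:
    """Smallest component count whose CV RMSE is within 5% of the minimum.

    The parsimony rule guards against fitting noise with extra latent
    variables.  Fold assignment is deterministic (contiguous level
    blocks), so the result does not depend on ``seed``; the argument is
    accepted for interface stability.
    """
    n, p = cal.X.shape
    max_rank = min(n - 1 - (n // folds), p)
    max_components = min(max_components, max_rank)
    if max_components < 1:
        raise ValueError("no admissible component count")
    rmse_list: list[float] = []
    for k in range(1, max_components + 1):
        try:
            rmse_list.append(cross_val_rmse(cal, k, folds))
        except DegenerateDataError:
            break  # effective rank exhausted; larger k cannot be fitted
    if not rmse_list:
        raise DegenerateDataError("no component count could be cross-validated")
    best = min(rmse_list)
    for k, r in enumerate(rmse_list, start=1):
        if r <= 1.05 * best:
            return k
    return int(np.argmin(rmse_list)) + 1  # pragma: no cover


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_json(model: PlsModel) -> str:
    """Serialize a model to a self-describing JSON document.

    Floats survive the round trip exactly (shortest-repr encoding).
    """
    doc = {
        "format": "rcvkit-pls-model",
        "version": 1,
        "n_components": model.n_components,
        "windows": [list(w) for w in model.spec.windows.windows],
        "baseline_mode": model.spec.baseline_mode,
        "centering": model.spec.centering,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "loadings": model.loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "y_range": list(model.y_range),
        "wavenumbers": model.wavenumbers.tolist(),
        "segments": list(model.segments),
        "calibration_floor": model.calibration_floor,
    }
    return json.dumps(doc, indent=1)


def model_from_json(text: str) -> PlsModel:
    doc = json.loads(text)
    if doc.get("format") != "rcvkit-pls-model":
        raise ValueError("not a PLS model document")
    spec = PreprocessSpec(
        windows=SpectralWindowSet(tuple(tuple(w) for w in doc["windows"])),
        baseline_mode=doc["baseline_mode"],
        centering=doc["centering"],
    )
    return PlsModel(
        n_components=doc["n_components"],
        x_mean=np.array(doc["x_mean"]),
        y_mean=doc["y_mean"],
        weights=np.array(doc["weights"]),
        loadings=np.array(doc["loadings"]),
        y_loadings=np.array(doc["y_loadings"]),
        coef=np.array(doc["coef"]),
        y_range=tuple(doc["y_range"]),
        spec=spec,
        wavenumbers=np.array(doc["wavenumbers"]),
        segments=tuple(doc["segments"]),
        calibration_floor=doc["calibration_floor"],
    )


def set_calibration_floor(model: PlsModel, floor: float | None) -> PlsModel:
    """Return a copy of the model with the calibration floor replaced."""
    return replace(model, calibration_floor=floor)
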