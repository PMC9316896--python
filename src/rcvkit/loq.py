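"""LOD/LOQ from pseudo-blank replicates and the calibration-floor rule.

For a PLS calibration on preprocessed FTIR spectra the usual
signal-to-noise and calibration-slope LOQ recipes are unreliable (no
defined peak after baseline removal, and the model range rarely covers
a true blank).  Instead, a pseudo blank — a coupon printed at a low
density — is measured repeatedly at a fixed point, the replicate
predictions are collected, and

    LOD = 3.3 * SD,    LOQ = 10 * SD

with SD the sample standard deviation of the predicted densities.
Because the replicates are model predictions, the LOQ reflects the
whole measurement chain (instrument noise through regression).  The
resulting LOQ becomes the calibration floor: a model whose training
range dips below it is invalid, and predictions under it are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemometrics import PlsModel, set_calibration_floor

__all__ = [
    "ReplicateSet",
    "LoqResult",
    "InvalidCalibrationError",
    "LOD_K",
    "LOQ_K",
    "loq_from_replicates",
    "apply_calibration_floor",
]

#: Default multipliers on the replicate SD (the ICH Q2 convention).
LOD_K = 3.3
LOQ_K = 10.0

#: Replicate count below which an LOQ is exploratory, not reportable.
MIN_REPORTABLE_REPLICATES = 10


class InvalidCalibrationError(ValueError):
    """Model's training range extends below the LOQ floor."""


@dataclass(frozen=True)
class ReplicateSet:
    """Fixed-point repeat measurements in prediction space (ug/cm^2).

    ``source_note`` records measurement conditions (detector
    temperature stability, background status).
    """

    values: np.ndarray
    source_note: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).reshape(-1)
        object.__setattr__(self, "values", arr)
        if arr.size < 2:
            raise ValueError("need at least 2 replicate values")
        if not np.isfinite(arr).all():
            raise ValueError("replicate values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator).

        Exactly 0 for a constant list (no spurious rounding residue).
        """
        if np.ptp(self.values) == 0:
            return 0.0
        return float(self.values.std(ddof=1))


@dataclass(frozen=True)
class LoqResult:
    """Replicate SD with the derived detection and quantification limits."""

    sd: float  # ug/cm^2
    lod: float  # ug/cm^2
    loq: float  # ug/cm^2
    lod_k: float
    loq_k: float
    n_replicates: int
    exploratory: bool = False  # fewer than 10 replicates
    degenerate: bool = False  # zero replicate SD


def loq_from_replicates(
    reps: ReplicateSet | Sequence[float],
    lod_k: float = LOD_K,
    loq_k: float = LOQ_K,
    strict: bool = True,
) -> LoqResult:
    """LOD/LOQ as multiples of the replicate standard deviation.

    ``strict`` enforces the minimum of 10 independent measurements; with
    ``strict=False`` smaller sets are allowed but the result is flagged
    exploratory.  Constant replicates give a degenerate (zero) result,
    flagged rather than raised.
    """
    if not isinstance(reps, ReplicateSet):
        reps = ReplicateSet(np.asarray(reps, dtype=float))
    if lod_k <= 0 or loq_k <= 0:
        raise ValueError("multipliers must be positive")
    exploratory = reps.n < MIN_REPORTABLE_REPLICATES
    if strict and exploratory:
        raise ValueError(
            f"reportable LOQ needs >= {MIN_REPORTABLE_REPLICATES} replicates "
            f"(got {reps.n}); pass strict=False for an exploratory estimate"
        )
    sd = reps.sd
    return LoqResult(
        sd=sd,
        lod=lod_k * sd,
        loq=loq_k * sd,
        lod_k=lod_k,
        loq_k=loq_k,
        n_replicates=reps.n,
        exploratory=exploratory,
        degenerate=(sd == 0.0),
    )


def apply_calibration_floor(model: PlsModel, loq: float | LoqResult) -> PlsModel:
    """Stamp the LOQ onto a model as its calibration floor.

    The calibration must not have been developed below the LOQ: if the
    model's training minimum lies under the floor the model is invalid
    and :class:`InvalidCalibrationError` is raised.  A zero floor is a
    no-op.
    """
    floor = loq.loq if isinstance(loq, LoqResult) else float(loq)
    if floor < 0:
        raise ValueError("LOQ floor must be >= 0")
    if floor == 0:
        return model
    if model.y_range[0] < floor:
        raise InvalidCalibrationError(
            f"calibration trained down to {model.y_range[0]:.3g} ug/cm^2, "
            f"below the LOQ floor {floor:.3g} ug/cm^2; the model must not be "
            "developed below the LOQ"
        )
    return set_calibration_floor(model, floor)
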