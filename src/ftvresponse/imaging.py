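"""Functional tumor volume (FTV) from serial breast DCE-MRI.

A DCE exam contributes three co-registered T1-weighted volumes: pre-contrast
(S0), early post-contrast at roughly 2 min 30 s (S1), and late post-contrast
at roughly 7 min 30 s (S2).  Two voxelwise kinetic quantities drive the
segmentation:

* percent enhancement  PE  = (S1 - S0) / S0 * 100
* signal enhancement ratio SER = (S1 - S0) / (S2 - S0)

A voxel counts toward the functional tumor volume when it lies inside a
rectangular volume of interest (VOI), PE exceeds a threshold (70% by
default) and SER exceeds a threshold (0 by default, i.e. persistent or
washout kinetics with late signal above baseline).  FTV is the summed
volume of those voxels in cubic centimeters.  The VOI and thresholds are
fixed on the baseline exam and propagated unchanged to later timepoints of
the same patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Timepoint",
    "DCEExam",
    "VOIBox",
    "EnhancementThresholds",
    "FTVResult",
    "compute_pe_map",
    "compute_ser_map",
    "segment_enhancing_voxels",
    "compute_ftv",
    "percent_change",
]


class Timepoint(str, Enum):
    """Serial MRI timepoints: pretreatment, early-treatment (~3 weeks),
    inter-regimen (~12 weeks)."""

    T0 = "T0"
    T1 = "T1"
    T2 = "T2"


@dataclass(frozen=True)
class EnhancementThresholds:
    """Voxel-inclusion thresholds; both inequalities are strict.

    pe_min is a percentage (default 70), ser_min dimensionless (default 0).
    Site readers may adjust them per patient on the baseline exam; they are
    then applied unchanged to every later exam of that patient.
    """

    pe_min: float = 70.0
    ser_min: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.pe_min) or self.pe_min < 0:
            raise ValueError(f"pe_min must be finite and >= 0, got {self.pe_min}")
        if not math.isfinite(self.ser_min):
            raise ValueError(f"ser_min must be finite, got {self.ser_min}")


@dataclass(frozen=True)
class VOIBox:
    """Axis-aligned volume of interest, 0-based half-open [lo, hi) indices.

    Axis order (x, y, z) matches the voxel-size order of the exam.
    """

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("VOIBox corners must have 3 components")
        for axis, (a, b) in enumerate(zip(self.lo, self.hi)):
            if a < 0 or b <= a:
                raise ValueError(
                    f"VOI axis {axis}: need 0 <= lo < hi, got [{a}, {b})"
                )

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.lo, self.hi))

    def check_inside(self, shape: tuple[int, ...]) -> None:
        for axis, (b, n) in enumerate(zip(self.hi, shape)):
            if b > n:
                raise ValueError(
                    f"VOI exceeds volume on axis {axis}: hi={b} > shape={n}"
                )

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        self.check_inside(shape)
        m = np.zeros(shape, dtype=bool)
        m[self.slices] = True
        return m


@dataclass
class DCEExam:
    """One DCE-MRI exam: three co-registered signal volumes plus geometry."""

    patient_id: str
    timepoint: Timepoint
    s0: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if not (self.s0.shape == self.s1.shape == self.s2.shape):
            raise ValueError(
                "s0/s1/s2 shapes differ: "
                f"{self.s0.shape}, {self.s1.shape}, {self.s2.shape}"
            )
        if self.s0.ndim != 3:
            raise ValueError(f"expected 3-D volumes, got ndim={self.s0.ndim}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        for name, vol in (("s0", self.s0), ("s1", self.s1), ("s2", self.s2)):
            if not np.all(np.isfinite(vol)):
                raise ValueError(f"{name} contains non-finite values")
        self.timepoint = Timepoint(self.timepoint)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s0.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class FTVResult:
    """FTV for one exam; ftv_cc == voxel_count * voxel_volume_mm3 / 1000."""

    patient_id: str
    timepoint: Timepoint
    ftv_cc: float
    voxel_count: int
    thresholds_used: EnhancementThresholds
    voi_used: VOIBox


def compute_pe_map(exam: DCEExam) -> np.ndarray:
    """Percent enhancement (S1 - S0)/S0 * 100, per voxel.

    Voxels with non-positive pre-contrast signal have undefined enhancement
    and are returned as NaN; NaN never satisfies a threshold comparison, so
    such voxels are excluded from any downstream segmentation.
    """
    valid = exam.s0 > 0
    pe = np.full(exam.shape, np.nan)
    np.divide(exam.s1 - exam.s0, exam.s0, out=pe, where=valid)
    pe[valid] *= 100.0
    return pe


def compute_ser_map(exam: DCEExam) -> np.ndarray:
    """Signal enhancement ratio (S1 - S0)/(S2 - S0), per voxel.

    Voxels where the late phase equals baseline (S2 == S0) have an undefined
    ratio and are returned as NaN (excluded from segmentation).  Washout
    below baseline (S2 < S0 with S1 > S0) yields a negative SER, which fails
    the default SER > 0 criterion.
    """
    denom = exam.s2 - exam.s0
    valid = denom != 0
    ser = np.full(exam.shape, np.nan)
    np.divide(exam.s1 - exam.s0, denom, out=ser, where=valid)
    return ser


def segment_enhancing_voxels(
    exam: DCEExam,
    voi: VOIBox,
    thr: EnhancementThresholds | None = None,
) -> np.ndarray:
    """Boolean mask of enhancing voxels: inside the VOI, PE strictly above
    pe_min and SER strictly above ser_min; undefined voxels excluded."""
    thr = thr or EnhancementThresholds()
    voi.check_inside(exam.shape)
    pe = compute_pe_map(exam)
    ser = compute_ser_map(exam)
    mask = np.zeros(exam.shape, dtype=bool)
    sl = voi.slices
    with np.errstate(invalid="ignore"):
        mask[sl] = (pe[sl] > thr.pe_min) & (ser[sl] > thr.ser_min)
    return mask


def compute_ftv(
    exam: DCEExam,
    voi: VOIBox,
    thr: EnhancementThresholds | None = None,
) -> FTVResult:
    """Functional tumor volume of one exam, in cubic centimeters."""
    thr = thr or EnhancementThresholds()
    mask = segment_enhancing_voxels(exam, voi, thr)
    n = int(mask.sum())
    return FTVResult(
        patient_id=exam.patient_id,
        timepoint=exam.timepoint,
        ftv_cc=n * exam.voxel_volume_mm3 / 1000.0,
        voxel_count=n,
        thresholds_used=thr,
        voi_used=voi,
    )


def percent_change(ftv_ref: float, ftv_t: float) -> float:
    """Percent change of FTV relative to a reference exam.

    Returns ``(ftv_t - ftv_ref)/ftv_ref * 100``.  A zero reference volume
    makes the change undefined: the function returns NaN as an explicit
    sentinel (never a silent 0), and downstream modelling drops such
    patients as incomplete.
    """
    if ftv_ref < 0 or ftv_t < 0:
        raise ValueError("FTV values must be non-negative")
    if ftv_ref == 0:
        return math.nan
    return (ftv_t - ftv_ref) / ftv_ref * 100.0
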