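"""File I/O: NIfTI exam loading, per-patient VOI/threshold config, FTV CSV.

Coordinate convention: volumes are indexed (x, y, z) in the same order as
``voxel_size``; VOI corners are 0-based half-open ``[lo, hi)`` on each axis.
Voxel sizes default to the NIfTI header zooms but can be overridden in the
per-patient config.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .imaging import DCEExam, EnhancementThresholds, FTVResult, Timepoint, VOIBox

__all__ = [
    "load_exam",
    "load_patient_config",
    "save_patient_config",
    "ftv_results_to_frame",
    "write_ftv_csv",
]


def load_exam(
    patient_id: str,
    timepoint: Timepoint | str,
    s0_path: str | Path,
    s1_path: str | Path,
    s2_path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
) -> DCEExam:
    """Load one exam from three NIfTI volumes (.nii or .nii.gz).

    ``voxel_size`` overrides the header zooms of the pre-contrast image.
    """
    imgs = [nib.load(str(p)) for p in (s0_path, s1_path, s2_path)]
    vols = [np.asarray(img.dataobj, dtype=float) for img in imgs]
    if voxel_size is None:
        zooms = imgs[0].header.get_zooms()[:3]
        voxel_size = tuple(float(z) for z in zooms)
    return DCEExam(
        patient_id=patient_id,
        timepoint=Timepoint(timepoint),
        s0=vols[0],
        s1=vols[1],
        s2=vols[2],
        voxel_size=voxel_size,
    )


def load_patient_config(path: str | Path) -> tuple[VOIBox, EnhancementThresholds]:
    """Read a per-patient JSON config.

    Schema: ``{"voi": {"lo": [x,y,z], "hi": [x,y,z]}, "pe_min": 70, "ser_min": 0}``;
    the threshold keys are optional and default to 70 / 0.  The same VOI and
    thresholds apply to every exam of the patient.
    """
    cfg = json.loads(Path(path).read_text())
    voi = VOIBox(lo=tuple(cfg["voi"]["lo"]), hi=tuple(cfg["voi"]["hi"]))
    thr = EnhancementThresholds(
        pe_min=float(cfg.get("pe_min", 70.0)),
        ser_min=float(cfg.get("ser_min", 0.0)),
    )
    return voi, thr


def save_patient_config(
    path: str | Path, voi: VOIBox, thr: EnhancementThresholds
) -> None:
    cfg = {
        "voi": {"lo": list(voi.lo), "hi": list(voi.hi)},
        "pe_min": thr.pe_min,
        "ser_min": thr.ser_min,
    }
    Path(path).write_text(json.dumps(cfg, indent=2) + "\n")


def ftv_results_to_frame(results: list[FTVResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "timepoint": [r.timepoint.value for r in results],
            "ftv_cc": [r.ftv_cc for r in results],
            "voxel_count": [r.voxel_count for r in results],
            "pe_min": [r.thresholds_used.pe_min for r in results],
            "ser_min": [r.thresholds_used.ser_min for r in results],
        }
    )


def write_ftv_csv(results: list[FTVResult], path: str | Path) -> None:
    ftv_results_to_frame(results).to_csv(path, index=False)
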