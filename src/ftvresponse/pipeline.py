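"""End-to-end orchestration: images or cohort table → FTV variables →
subtype-specific models → PPV-constrained thresholds → per-patient decisions.

Small strata are expected in subtype-stratified trial cohorts, so a scope
whose model cannot be fit (too few patients or a single outcome class) is
reported as "insufficient data" rather than aborting the run.  Every stage
draws its randomness from the single configured seed, and a run log records
the seed, a config hash, and per-stage record counts for audit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import FittedModel, model_to_json, select_model
from .synthetic import (
    SUBTYPES,
    CohortSpec,
    PatientRecord,
    cohort_to_frame,
    frame_to_records,
    generate_cohort,
)
from .thresholds import (
    Decision,
    ThresholdSelection,
    implication_report,
    ppv_sensitivity_curve,
    recommend,
    select_threshold,
    threshold_report,
)

__all__ = [
    "PipelineConfig",
    "ExclusionAudit",
    "PipelineResult",
    "exclusion_audit",
    "ftv_table_from_manifest",
    "cohort_from_images",
    "run_pipeline",
]

log = logging.getLogger("ftvresponse")

_FTV_COLUMNS = ("ftv_t0_cc", "dftv_t1_pct", "dftv_t2_pct")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``mode`` selects the input source: "synthetic" draws a cohort from
    ``cohort`` (a :class:`CohortSpec`, seeded from ``seed`` unless set
    explicitly), "cohort_csv" reads an FTV/outcome table from
    ``cohort_csv_path``, and "images" measures FTV from the NIfTI exams
    listed in ``manifest_path`` (which also names a clinical CSV carrying
    subtype and outcome).
    """

    mode: str = "synthetic"
    cohort_csv_path: str | None = None
    manifest_path: str | None = None
    out_dir: str = "ftvresponse_out"
    n_patients: int = 5000
    k_folds: int = 5
    ppv_levels: tuple[float, ...] = (50.0, 70.0, 90.0)
    seed: int = 0
    cohort: CohortSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "cohort_csv", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(not 0 < lvl <= 100 for lvl in self.ppv_levels):
            raise ValueError("ppv_levels must lie in (0, 100]")
        if self.mode == "cohort_csv":
            if not self.cohort_csv_path:
                raise ValueError("cohort_csv mode requires cohort_csv_path")
            if not Path(self.cohort_csv_path).exists():
                raise FileNotFoundError(self.cohort_csv_path)
        if self.mode == "images":
            if not self.manifest_path:
                raise ValueError("images mode requires manifest_path")
            if not Path(self.manifest_path).exists():
                raise FileNotFoundError(self.manifest_path)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        if "ppv_levels" in payload:
            payload["ppv_levels"] = tuple(payload["ppv_levels"])
        if "cohort" in payload and payload["cohort"] is not None:
            payload["cohort"] = CohortSpec(**payload["cohort"])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class ExclusionAudit:
    """Cohort-accounting counts mirroring a trial exclusion flowchart.

    Filters apply in a fixed order: records missing the outcome or the
    receptor status are removed first, then records missing any FTV
    measurement; the remainder is the analysis cohort.
    """

    n_input: int
    n_missing_outcome_or_receptor: int
    n_missing_ftv: int
    n_analysis: int
    analysis: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_missing_outcome_or_receptor": self.n_missing_outcome_or_receptor,
            "n_missing_ftv": self.n_missing_ftv,
            "n_analysis": self.n_analysis,
        }


def exclusion_audit(cohort: pd.DataFrame) -> ExclusionAudit:
    """Apply the missing-data filter chain to a raw cohort table.

    Expects the cohort CSV schema (``patient_id, subtype, pcr, ftv_t0_cc,
    dftv_t1_pct, dftv_t2_pct``); missing values are NA/NaN.  The FTV filter
    also catches the undefined-percent-change sentinel (NaN from a zero
    baseline volume).
    """
    df = cohort.copy()
    n_input = len(df)
    has_outcome = df["pcr"].notna() & df["subtype"].notna()
    n_out = int((~has_outcome).sum())
    df = df[has_outcome]
    has_ftv = df[list(_FTV_COLUMNS)].notna().all(axis=1)
    # a non-positive baseline FTV cannot anchor a percent change
    has_ftv &= df["ftv_t0_cc"] > 0
    n_ftv = int((~has_ftv).sum())
    df = df[has_ftv]
    return ExclusionAudit(
        n_input=n_input,
        n_missing_outcome_or_receptor=n_out,
        n_missing_ftv=n_ftv,
        n_analysis=len(df),
        analysis=df.reset_index(drop=True),
    )


def ftv_table_from_manifest(manifest: dict | str | Path) -> pd.DataFrame:
    """Measure FTV for every exam listed in an image manifest.

    Manifest schema (JSON)::

        {"clinical_csv": "...",
         "patients": [
           {"patient_id": "...",
            "voi": {"lo": [x, y, z], "hi": [x, y, z]},
            "pe_min": 70, "ser_min": 0,          # optional overrides
            "voxel_size": [dx, dy, dz],          # optional header override
            "exams": {"T0": {"s0": "...", "s1": "...", "s2": "..."}, ...}}]}

    The VOI and thresholds are keyed to the patient, never to the exam, so
    the baseline segmentation settings propagate unchanged to T1/T2.
    Relative image paths resolve against the manifest's directory.
    Returns the long FTV table (one row per exam).
    """
    from .imaging import EnhancementThresholds, VOIBox, compute_ftv
    from .io import ftv_results_to_frame, load_exam

    base = Path(".")
    if not isinstance(manifest, dict):
        base = Path(manifest).parent
        manifest = json.loads(Path(manifest).read_text())

    results = []
    for pat in manifest["patients"]:
        voi = VOIBox(lo=tuple(pat["voi"]["lo"]), hi=tuple(pat["voi"]["hi"]))
        thr = EnhancementThresholds(
            pe_min=float(pat.get("pe_min", 70.0)),
            ser_min=float(pat.get("ser_min", 0.0)),
        )
        voxel_size = pat.get("voxel_size")
        if voxel_size is not None:
            voxel_size = tuple(voxel_size)
        for tp, phases in pat["exams"].items():
            exam = load_exam(
                pat["patient_id"],
                tp,
                base / phases["s0"],
                base / phases["s1"],
                base / phases["s2"],
                voxel_size=voxel_size,
            )
            results.append(compute_ftv(exam, voi, thr))
    return ftv_results_to_frame(results)


def cohort_from_images(manifest_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a cohort table from an image manifest plus its clinical CSV.

    Returns ``(ftv_long, cohort)`` where ``cohort`` has the standard schema
    (ftv_t0_cc, dftv_t1_pct, dftv_t2_pct joined with subtype and pCR).
    Patients missing an exam, or with zero baseline FTV, get NaN percent
    changes and fall to the exclusion audit downstream.
    """
    from .imaging import percent_change

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    ftv_long = ftv_table_from_manifest(manifest_path)
    clinical = pd.read_csv(manifest_path.parent / manifest["clinical_csv"])

    wide = ftv_long.pivot(index="patient_id", columns="timepoint", values="ftv_cc")
    rows = []
    for pid, row in wide.iterrows():
        t0 = row.get("T0", math.nan)
        rec = {"patient_id": pid, "ftv_t0_cc": t0}
        for tp, col in (("T1", "dftv_t1_pct"), ("T2", "dftv_t2_pct")):
            ft = row.get(tp, math.nan)
            rec[col] = (
                percent_change(t0, ft)
                if math.isfinite(t0) and t0 > 0 and math.isfinite(ft)
                else math.nan
            )
        rows.append(rec)
    cohort = pd.merge(clinical, pd.DataFrame(rows), on="patient_id", how="outer")
    return ftv_long, cohort


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run, plus the paths written."""

    config: PipelineConfig
    audit: ExclusionAudit
    models: dict[str, FittedModel]
    skipped_scopes: dict[str, str]
    selections: dict[str, list[ThresholdSelection]]
    threshold_report: pd.DataFrame
    implications: pd.DataFrame
    decisions: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _scope_records(
    records: list[PatientRecord], scope: str
) -> list[PatientRecord]:
    if scope == "full":
        return records
    return [r for r in records if r.subtype.value == scope]


def _fit_all_scopes(
    records: list[PatientRecord], config: PipelineConfig
) -> tuple[dict[str, FittedModel], dict[str, str]]:
    models: dict[str, FittedModel] = {}
    skipped: dict[str, str] = {}
    for scope in ["full"] + [s.value for s in SUBTYPES]:
        sub = _scope_records(records, scope)
        try:
            models[scope] = select_model(
                sub, k_folds=config.k_folds, seed=config.seed, scope=scope
            )
            log.info("scope %s: n=%d, selected %s", scope, len(sub),
                     models[scope].predictors)
        except ValueError as err:
            skipped[scope] = f"insufficient data: {err}"
            log.warning("scope %s skipped: %s", scope, err)
    return models, skipped


def _decide_patients(
    records: list[PatientRecord],
    models: dict[str, FittedModel],
    selections: dict[str, list[ThresholdSelection]],
    ppv_levels: tuple[float, ...],
) -> pd.DataFrame:
    rows = []
    for r in records:
        scope = r.subtype.value if r.subtype.value in models else "full"
        row: dict = {
            "patient_id": r.patient_id,
            "subtype": r.subtype.value,
            "model_scope": scope if scope in models else "unavailable",
            "probability": math.nan,
        }
        if scope in models:
            prob = float(models[scope].predict_proba([r])[0])
            row["probability"] = prob
            for sel in selections[scope]:
                key = f"decision_ppv{sel.ppv_level:g}"
                row[key] = recommend(prob, sel).value
        else:
            for lvl in ppv_levels:
                row[f"decision_ppv{lvl:g}"] = "insufficient data"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Writes cohort.csv (synthetic mode), models.json, threshold_report.csv,
    implications.csv, decisions.csv and run_log.json.  Deterministic given
    an identical config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    if config.mode == "synthetic":
        spec = config.cohort or CohortSpec(
            n_patients=config.n_patients, seed=config.seed
        )
        records = generate_cohort(spec)
        cohort_df = cohort_to_frame(records)
        paths["cohort"] = out / "cohort.csv"
        cohort_df.to_csv(paths["cohort"], index=False, float_format="%.6f")
    elif config.mode == "images":
        ftv_long, cohort_df = cohort_from_images(config.manifest_path)
        paths["ftv"] = out / "ftv.csv"
        ftv_long.to_csv(paths["ftv"], index=False)
    else:
        cohort_df = pd.read_csv(config.cohort_csv_path)

    audit = exclusion_audit(cohort_df)
    if audit.n_analysis == 0:
        raise ValueError(
            "no analyzable records after exclusions "
            f"(of {audit.n_input}: {audit.n_missing_outcome_or_receptor} "
            f"missing outcome/receptor, {audit.n_missing_ftv} missing FTV)"
        )
    records = frame_to_records(audit.analysis)

    models, skipped = _fit_all_scopes(records, config)
    if not models:
        raise ValueError("no cohort scope had enough data to fit a model")

    selections: dict[str, list[ThresholdSelection]] = {}
    for scope, model in models.items():
        sub = _scope_records(records, scope)
        probs = model.predict_proba(sub)
        labels = np.array([r.pcr for r in sub])
        curve = ppv_sensitivity_curve(probs, labels)
        selections[scope] = [
            select_threshold(curve, lvl) for lvl in config.ppv_levels
        ]

    report = threshold_report(selections)
    for scope, reason in skipped.items():
        for lvl in config.ppv_levels:
            report.loc[len(report)] = {
                "cohort": scope,
                "ppv_level": lvl,
                "threshold": reason,
                "sensitivity": math.nan,
                "ci_lo": math.nan,
                "ci_hi": math.nan,
            }
    implications = implication_report(selections, ppv_level=config.ppv_levels[0])
    decisions = _decide_patients(records, models, selections, config.ppv_levels)

    paths["models"] = out / "models.json"
    paths["models"].write_text(
        json.dumps(
            {scope: json.loads(model_to_json(m)) for scope, m in models.items()},
            indent=2,
        )
        + "\n"
    )
    paths["threshold_report"] = out / "threshold_report.csv"
    report.to_csv(paths["threshold_report"], index=False)
    paths["implications"] = out / "implications.csv"
    implications.to_csv(paths["implications"], index=False)
    paths["decisions"] = out / "decisions.csv"
    decisions.to_csv(paths["decisions"], index=False, float_format="%.6f")

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "exclusions": audit.to_dict(),
        "scopes_fit": sorted(models),
        "scopes_skipped": skipped,
        "n_decisions": len(decisions),
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(run_log, indent=2) + "\n")

    return PipelineResult(
        config=config,
        audit=audit,
        models=models,
        skipped_scopes=skipped,
        selections=selections,
        threshold_report=report,
        implications=implications,
        decisions=decisions,
        paths=paths,
    )
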