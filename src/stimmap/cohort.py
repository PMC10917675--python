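"""Patients, outcomes, and the percent-improvement metric.

Clinical outcome is expressed as the relative change from pre-operative
baseline to follow-up under active stimulation.  All rating scales
handled here (BFMDRS, UPDRS-III, Y-BOCS, YGTSS) are severity scales —
higher is worse — so improvement is a *reduction*:

    improvement % = 100 * (baseline - followup) / baseline

Negative values (worsening) are allowed and never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import EFieldVolume, load_volume

__all__ = ["PatientRecord", "Cohort", "percent_improvement", "load_cohort"]

logger = logging.getLogger(__name__)

#: Tolerance (percentage points) when cross-checking a provided
#: improvement column against the recomputed value.
IMPROVEMENT_CHECK_TOL = 0.5


def percent_improvement(baseline: float, followup: float,
                        higher_is_better: bool = False) -> float:
    """Percent change from baseline, reduction-positive by default.

    Parameters
    ----------
    baseline, followup : float
        Scale scores; ``baseline`` must be positive.
    higher_is_better : bool
        Flip the sign convention for scales where an increase is the
        desired direction.
    """
    if not baseline > 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    change = 100.0 * (baseline - followup) / baseline
    return -change if higher_is_better else change


@dataclass
class PatientRecord:
    """One patient: identifiers, scores, and per-hemisphere E-fields."""

    patient_id: str
    disorder: str
    baseline_score: float
    followup_score: float
    efields: list[EFieldVolume] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.baseline_score > 0:
            raise ValueError(
                f"{self.patient_id}: baseline must be positive, got {self.baseline_score}"
            )
        if not 1 <= len(self.efields) <= 2 and self.efields:
            raise ValueError(f"{self.patient_id}: expected 1 or 2 E-fields")

    @property
    def improvement_pct(self) -> float:
        return percent_improvement(self.baseline_score, self.followup_score)


@dataclass
class Cohort:
    """A disorder-homogeneous list of patients."""

    records: list[PatientRecord]
    disorder: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate patient ids: {sorted(dupes)}")
        off = [r.patient_id for r in self.records if r.disorder != self.disorder]
        if off:
            raise ValueError(f"records with foreign disorder tag: {off}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def improvements(self) -> np.ndarray:
        return np.array([r.improvement_pct for r in self.records])

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def all_efields(self) -> list[EFieldVolume]:
        """All E-fields pooled across patients and hemispheres, in
        patient order (stable regardless of load order)."""
        out: list[EFieldVolume] = []
        for rec in sorted(self.records, key=lambda r: r.patient_id):
            out.extend(sorted(rec.efields, key=lambda e: e.hemisphere))
        return out


def load_cohort(table_path: str | Path, manifest_path: str | Path | None = None,
                disorder: str | None = None) -> Cohort:
    """Read and validate a cohort table (and optional E-field manifest).

    The table needs columns ``patient_id, disorder, baseline, followup``
    and may carry ``improvement_pct``, which is cross-checked against the
    recomputed value (mismatch beyond 0.5 percentage points logs a
    warning).  The manifest maps ``patient_id, hemisphere`` to an
    ``efield_path``; missing files, duplicate ids and non-positive
    baselines are collected and reported together.
    """
    table = pd.read_csv(table_path)
    required = {"patient_id", "disorder", "baseline", "followup"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{table_path}: missing columns {sorted(missing)}")
    table = table.copy()
    table["patient_id"] = table["patient_id"].astype(str)

    problems: list[str] = []
    dupes = table["patient_id"][table["patient_id"].duplicated()].unique()
    if len(dupes):
        problems.append(f"duplicate patient ids: {sorted(dupes)}")
    bad_base = table.loc[~(table["baseline"] > 0), "patient_id"].tolist()
    if bad_base:
        problems.append(f"non-positive baselines for: {bad_base}")

    manifest = None
    if manifest_path is not None:
        manifest = pd.read_csv(manifest_path)
        manifest["patient_id"] = manifest["patient_id"].astype(str)
        for _, row in manifest.iterrows():
            if not Path(row["efield_path"]).exists():
                problems.append(
                    f"missing E-field file for {row['patient_id']}/{row['hemisphere']}: "
                    f"{row['efield_path']}"
                )
    if problems:
        raise ValueError("cohort validation failed: " + "; ".join(problems))

    records = []
    # sorted for order-independence: shuffled rows produce an equal Cohort
    for _, row in table.sort_values("patient_id").iterrows():
        efields = []
        if manifest is not None:
            sub = manifest[manifest["patient_id"] == row["patient_id"]]
            for _, mrow in sub.sort_values("hemisphere").iterrows():
                vol = load_volume(mrow["efield_path"])
                efields.append(
                    EFieldVolume(vol, patient_id=row["patient_id"],
                                 hemisphere=mrow["hemisphere"])
                )
        rec = PatientRecord(
            patient_id=row["patient_id"], disorder=row["disorder"],
            baseline_score=float(row["baseline"]),
            followup_score=float(row["followup"]), efields=efields,
        )
        if "improvement_pct" in table.columns and np.isfinite(row["improvement_pct"]):
            delta = abs(float(row["improvement_pct"]) - rec.improvement_pct)
            if delta > IMPROVEMENT_CHECK_TOL:
                logger.warning(
                    "%s: provided improvement %.2f%% differs from recomputed %.2f%%",
                    rec.patient_id, row["improvement_pct"], rec.improvement_pct,
                )
        records.append(rec)

    tag = disorder or (records[0].disorder if records else "unknown")
    return Cohort(records=records, disorder=tag)
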