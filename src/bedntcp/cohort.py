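"""Patient data model, late-rectal-bleeding endpoint scoring, and cohort I/O.

The endpoint is grade >=2 late rectal bleeding (G2 LRB) within five years: a
patient is an event if case report forms record any medication or medical
intervention for rectal bleeding, or if patient questionnaires report
moderate bleeding at two or more distinct visits or severe bleeding at least
once.  Bleeding reported after a clinical recurrence is excluded, and events
adjudicated as caused by severe hemorrhoids are not scored.

Eligibility mirrors a randomized two-arm trial analysis set: at least 12
months of follow-up without recurrence, at least one toxicity evaluation
after month 12, and available 3D planning (DVH) data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dosimetry import DVH, FractionationScheme, read_dvh_csv, write_dvh_csv

__all__ = [
    "QUESTIONNAIRE_LEVELS",
    "ToxicityVisit",
    "PatientRecord",
    "Cohort",
    "score_g2_lrb",
    "eligibility_filter",
    "epv_check",
    "read_cohort",
    "write_cohort",
]

#: Four-level bleeding scale of the questionnaire item
#: "did you experience blood in your stools in the past week".
QUESTIONNAIRE_LEVELS = ("none", "little", "moderate", "severe")

#: Scheduled follow-up questionnaire months.
SCHEDULED_MONTHS = (6, 12, 24, 36, 48, 60)


@dataclass(frozen=True)
class ToxicityVisit:
    """One follow-up evaluation.

    ``crf_bleeding_intervention`` is True when the case report form records
    any medication/intervention for rectal bleeding; ``questionnaire_bleeding``
    is the ordinal self-report, or None when the questionnaire is missing.
    Either field may be None (not evaluated).
    """

    month: int
    crf_bleeding_intervention: Optional[bool]
    questionnaire_bleeding: Optional[str]

    def __post_init__(self) -> None:
        if self.month <= 0:
            raise ValueError(f"visit month must be > 0, got {self.month}")
        if self.questionnaire_bleeding is not None and (
            self.questionnaire_bleeding not in QUESTIONNAIRE_LEVELS
        ):
            raise ValueError(
                f"questionnaire_bleeding must be one of {QUESTIONNAIRE_LEVELS}, "
                f"got {self.questionnaire_bleeding!r}"
            )

    @property
    def has_evaluation(self) -> bool:
        return self.crf_bleeding_intervention is not None or self.questionnaire_bleeding is not None


@dataclass
class PatientRecord:
    patient_id: str
    arm: str  # "CF" or "HF"
    scheme: FractionationScheme
    dvh: Optional[DVH]
    abd_surg: bool
    visits: list[ToxicityVisit]
    last_followup_month: int
    recurrence_month: Optional[int] = None
    hemorrhoid_attribution: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("CF", "HF"):
            raise ValueError(f"arm must be 'CF' or 'HF', got {self.arm!r}")
        expected_fx = 39 if self.arm == "CF" else 19
        if self.scheme.n_fractions != expected_fx:
            raise ValueError(
                f"arm {self.arm} requires {expected_fx} fractions, "
                f"scheme has {self.scheme.n_fractions}"
            )
        self.visits = sorted(self.visits, key=lambda v: v.month)
        if self.recurrence_month is not None and self.recurrence_month > self.last_followup_month:
            raise ValueError("recurrence_month cannot exceed last_followup_month")

    @property
    def hypotreat(self) -> bool:
        """Indicator of hypofractionated-arm assignment."""
        return self.arm == "HF"


@dataclass
class Cohort:
    patients: list[PatientRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValueError("cohort must be non-empty")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)


def score_g2_lrb(record: PatientRecord, horizon_months: int = 60) -> bool:
    """Score the G2 LRB endpoint for one patient.

    Restricted to visits at or before the horizon and, for patients with a
    clinical recurrence, at or before the recurrence month.  True iff any
    CRF intervention, or moderate questionnaire bleeding at >=2 distinct
    visits, or severe at >=1 visit.  Hemorrhoid-attributed bleeders are
    never scored as events.  Missing questionnaires are non-informative.
    """
    if record.hemorrhoid_attribution:
        return False
    usable = [
        v
        for v in record.visits
        if v.month <= horizon_months
        and (record.recurrence_month is None or v.month <= record.recurrence_month)
    ]
    if any(v.crf_bleeding_intervention for v in usable):
        return True
    if any(v.questionnaire_bleeding == "severe" for v in usable):
        return True
    moderate_months = {v.month for v in usable if v.questionnaire_bleeding == "moderate"}
    return len(moderate_months) >= 2


def eligibility_filter(cohort: Cohort) -> tuple[Cohort, list[tuple[str, str]]]:
    """Apply the trial analysis-set filters; returns (retained cohort, exclusion log).

    Exclusion reasons: ``followup<12m``, ``recurrence<12m``,
    ``no_evaluation_after_12m``, ``missing_dvh``.
    """
    retained: list[PatientRecord] = []
    log: list[tuple[str, str]] = []
    for p in cohort:
        if p.last_followup_month < 12:
            log.append((p.patient_id, "followup<12m"))
        elif p.recurrence_month is not None and p.recurrence_month < 12:
            log.append((p.patient_id, "recurrence<12m"))
        elif not any(v.month > 12 and v.has_evaluation for v in p.visits):
            log.append((p.patient_id, "no_evaluation_after_12m"))
        elif p.dvh is None:
            log.append((p.patient_id, "missing_dvh"))
        else:
            retained.append(p)
    if not retained:
        raise ValueError("eligibility filter excluded every patient")
    return Cohort(retained, provenance=dict(cohort.provenance, eligibility_filtered=True)), log


def epv_check(n_events: int, n_candidate_predictors: int) -> str:
    """Events-per-variable adequacy: 'pass' when EPV >= 10, else 'warn'."""
    if n_events < 0 or n_candidate_predictors < 0:
        raise ValueError("counts must be non-negative")
    if n_candidate_predictors == 0:
        raise ValueError("EPV undefined for zero candidate predictors")
    return "pass" if n_events / n_candidate_predictors >= 10 else "warn"


# ---------------------------------------------------------------------------
# File layout: <dir>/patients.csv, <dir>/visits.csv, <dir>/dvh/<patient_id>.csv,
# <dir>/provenance.json.  All numerics at full repr precision so that
# read(write(c)) round-trips bit-exactly.

_PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "n_fractions",
    "prescribed_dose_gy",
    "abd_surg",
    "recurrence_month",
    "last_followup_month",
    "hemorrhoid_attribution",
]


def write_cohort(cohort: Cohort, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    (directory / "dvh").mkdir(parents=True, exist_ok=True)
    prows, vrows = [], []
    for p in cohort:
        prows.append(
            {
                "patient_id": p.patient_id,
                "arm": p.arm,
                "n_fractions": p.scheme.n_fractions,
                "prescribed_dose_gy": repr(p.scheme.prescribed_dose),
                "abd_surg": int(p.abd_surg),
                "recurrence_month": "" if p.recurrence_month is None else p.recurrence_month,
                "last_followup_month": p.last_followup_month,
                "hemorrhoid_attribution": int(p.hemorrhoid_attribution),
            }
        )
        for v in p.visits:
            vrows.append(
                {
                    "patient_id": p.patient_id,
                    "month": v.month,
                    "crf_intervention": ""
                    if v.crf_bleeding_intervention is None
                    else int(v.crf_bleeding_intervention),
                    "questionnaire_score": v.questionnaire_bleeding or "",
                }
            )
        if p.dvh is not None:
            write_dvh_csv(p.dvh, directory / "dvh" / f"{p.patient_id}.csv")
    pd.DataFrame(prows, columns=_PATIENT_COLUMNS).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(vrows, columns=["patient_id", "month", "crf_intervention", "questionnaire_score"]).to_csv(
        directory / "visits.csv", index=False
    )
    with open(directory / "provenance.json", "w") as fh:
        json.dump(cohort.provenance, fh, indent=1, sort_keys=True)


def _parse_optional_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def read_cohort(
    directory: Union[str, Path],
    patient_table_path: Optional[Union[str, Path]] = None,
    visits_path: Optional[Union[str, Path]] = None,
) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Patients whose DVH file is absent are loaded with ``dvh=None`` and are
    later removed by :func:`eligibility_filter`.  Duplicate patient ids and
    malformed rows raise with the offending row number.
    """
    directory = Path(directory)
    ptable = pd.read_csv(
        patient_table_path or directory / "patients.csv",
        dtype={"patient_id": str},
        float_precision="round_trip",
    )
    vtable = pd.read_csv(visits_path or directory / "visits.csv", dtype={"patient_id": str})
    missing = set(_PATIENT_COLUMNS) - set(ptable.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")

    visits_by_pid: dict[str, list[ToxicityVisit]] = {}
    for i, row in vtable.iterrows():
        try:
            crf = row["crf_intervention"]
            crf = None if (isinstance(crf, float) and np.isnan(crf)) or crf == "" else bool(int(crf))
            q = row["questionnaire_score"]
            q = None if (isinstance(q, float) and np.isnan(q)) or q == "" else str(q)
            visits_by_pid.setdefault(str(row["patient_id"]), []).append(
                ToxicityVisit(int(row["month"]), crf, q)
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed visits row {i + 2}: {exc}") from exc

    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in ptable.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            raise ValueError(f"duplicate patient_id {pid!r} at patients.csv row {i + 2}")
        seen.add(pid)
        try:
            scheme = FractionationScheme(int(row["n_fractions"]), float(row["prescribed_dose_gy"]))
            dvh_path = directory / "dvh" / f"{pid}.csv"
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    arm=str(row["arm"]),
                    scheme=scheme,
                    dvh=read_dvh_csv(dvh_path) if dvh_path.exists() else None,
                    abd_surg=bool(int(row["abd_surg"])),
                    visits=visits_by_pid.get(pid, []),
                    last_followup_month=int(row["last_followup_month"]),
                    recurrence_month=_parse_optional_int(row["recurrence_month"]),
                    hemorrhoid_attribution=bool(int(row["hemorrhoid_attribution"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed patients.csv row {i + 2}: {exc}") from exc

    prov_path = directory / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    return Cohort(patients, provenance=provenance)
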