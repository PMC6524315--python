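"""Patient-level cohort model for the CT-PIRP analyses.

A cohort is a collection of :class:`PatientRecord` objects, one per subject of
a CKD registry wave (derivation or validation).  Each record carries the six
variables the classification tree uses (proteinuria components, baseline eGFR,
serum phosphate, age, diabetes, sex), a serial-creatinine history used to
derive the annual eGFR slope, and a single terminal outcome (RRT inception,
death, loss to follow-up, or administrative censoring).

Clinical derivations live here: proteinuria coding from its three components,
the CKD-EPI 2009 creatinine equation, KDIGO-style CKD staging, and the
ordinary-least-squares annual eGFR slope.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OUTCOMES",
    "PatientRecord",
    "FollowUp",
    "CohortError",
    "derive_proteinuria",
    "ckdepi_egfr",
    "creatinine_from_egfr",
    "ckd_stage",
    "CKD_STAGE_LABELS",
    "egfr_annual_slope",
    "egfr_slope_category",
    "SLOPE_CATEGORY_LABELS",
    "load_cohort",
    "cohort_to_frame",
    "write_cohort",
]

#: Recognised terminal outcome codes.
OUTCOMES = ("rrt", "death", "lost", "admin_censor")

#: Minimum follow-up required for inclusion (years).
MIN_FOLLOWUP_YEARS = 0.5

DAYS_PER_YEAR = 365.25

# Proteinuria coding thresholds (strict ">" comparisons).
DIPSTICK_THRESHOLD_MG_DL = 20.0
PROTEIN24H_THRESHOLD_G = 0.3
MICROALB_THRESHOLD_MG_L = 20.0


class CohortError(ValueError):
    """Raised for invalid cohort files or records."""


@dataclass(frozen=True)
class FollowUp:
    """Observed follow-up for one subject: time since enrolment and outcome.

    ``time`` is in years; ``event`` is one of :data:`OUTCOMES`.  Subjects enter
    the risk sets at 6 months (the registry's minimum follow-up), so ``time``
    is always at least 0.5.
    """

    time: float
    event: str

    def __post_init__(self) -> None:
        if self.event not in OUTCOMES:
            raise CohortError(f"unknown outcome code: {self.event!r}")
        if self.time < MIN_FOLLOWUP_YEARS - 1e-12:
            raise CohortError(
                f"follow-up time {self.time:.3f} y below the 6-month minimum"
            )


@dataclass
class PatientRecord:
    """One subject's covariates, creatinine history and terminal outcome."""

    patient_id: str
    center_id: int
    cohort: str  # "derivation" | "validation"
    sex: str  # "male" | "female"
    age: float  # years at first visit
    diabetes: bool
    egfr_baseline: float  # mL/min/1.73 m^2
    enrol_date: _dt.date
    exit_date: _dt.date
    outcome: str
    dipstick_protein: float | None = None  # mg/dL
    urine_protein_24h: float | None = None  # g/24 h
    microalbuminuria: float | None = None  # mg/L
    proteinuria: bool | None = None  # may be pre-coded
    phosphate: float | None = None  # mg/dL; ~19% missing in the registry
    creatinine_series: list[tuple[_dt.date, float]] = field(default_factory=list)
    node: int | None = None  # filled by the classifier / simulator

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise CohortError(
                f"{self.patient_id}: unknown outcome code {self.outcome!r}"
            )
        if self.sex not in ("male", "female"):
            raise CohortError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if not self.age > 0:
            raise CohortError(f"{self.patient_id}: non-positive age")
        if not self.egfr_baseline > 0:
            raise CohortError(f"{self.patient_id}: non-positive baseline eGFR")
        if self.followup_years() < MIN_FOLLOWUP_YEARS - 1e-12:
            raise CohortError(
                f"{self.patient_id}: follow-up shorter than the 6-month minimum"
            )
        if self.creatinine_series:
            if len(self.creatinine_series) < 4:
                raise CohortError(
                    f"{self.patient_id}: insufficient measurements "
                    "(at least four serum creatinine values required)"
                )
            dates = [d for d, _ in self.creatinine_series]
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise CohortError(
                    f"{self.patient_id}: creatinine dates not strictly increasing"
                )

    def followup_years(self) -> float:
        return (self.exit_date - self.enrol_date).days / DAYS_PER_YEAR

    def followup(self) -> FollowUp:
        return FollowUp(time=self.followup_years(), event=self.outcome)

    def proteinuria_status(self) -> bool:
        """Proteinuria flag, derived from components when not pre-coded."""
        if self.proteinuria is not None:
            return self.proteinuria
        return derive_proteinuria(
            self.dipstick_protein, self.urine_protein_24h, self.microalbuminuria
        )


def derive_proteinuria(
    dipstick: float | None,
    protein24h: float | None,
    microalb: float | None,
) -> bool:
    """Code proteinuria as present from any of its three components.

    Present if dipstick protein > 20 mg/dL, or 24-h urine total protein
    > 0.3 g, or microalbuminuria > 20 mg/L.  Missing components are
    non-informative; with all three missing the status is undeterminable.
    """
    if dipstick is None and protein24h is None and microalb is None:
        raise CohortError("proteinuria undeterminable: all components missing")
    return (
        (dipstick is not None and dipstick > DIPSTICK_THRESHOLD_MG_DL)
        or (protein24h is not None and protein24h > PROTEIN24H_THRESHOLD_G)
        or (microalb is not None and microalb > MICROALB_THRESHOLD_MG_L)
    )


def ckdepi_egfr(creatinine: float, age: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine eGFR (mL/min/1.73 m^2), without race term.

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209
               * 0.993^age * 1.018[if female]
    with k = 0.7 (female) / 0.9 (male) and alpha = -0.329 / -0.411.
    """
    if creatinine <= 0 or age <= 0:
        raise ValueError("creatinine and age must be positive")
    if sex == "female":
        kappa, alpha, sex_coef = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_coef = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    r = creatinine / kappa
    return (
        141.0
        * min(r, 1.0) ** alpha
        * max(r, 1.0) ** -1.209
        * 0.993**age
        * sex_coef
    )


def creatinine_from_egfr(egfr: float, age: float, sex: str) -> float:
    """Invert :func:`ckdepi_egfr`: the serum creatinine giving this eGFR.

    Used by the cohort simulator to synthesise creatinine series from latent
    eGFR trajectories.  The CKD-EPI map is a strictly decreasing, continuous,
    piecewise power function of creatinine, so the inverse is closed-form.
    """
    if egfr <= 0 or age <= 0:
        raise ValueError("egfr and age must be positive")
    if sex == "female":
        kappa, alpha, sex_coef = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_coef = 0.9, -0.411, 1.0
    base = 141.0 * 0.993**age * sex_coef
    ratio = egfr / base
    if ratio >= 1.0:  # creatinine below kappa: the min(...)^alpha branch
        r = ratio ** (1.0 / alpha)
    else:
        r = ratio ** (1.0 / -1.209)
    return r * kappa


#: Ordered CKD stage labels: KDIGO bands with stages 1-2 merged.
CKD_STAGE_LABELS = ("1-2", "3a", "3b", "4", "5")


def ckd_stage(egfr: float) -> str:
    """CKD stage from eGFR: >=60 '1-2', 45-59 '3a', 30-44 '3b', 15-29 '4', <15 '5'.

    Five ordered categories; boundaries partition (0, inf) with lower bounds
    inclusive.
    """
    if egfr <= 0:
        raise ValueError("eGFR must be positive")
    if egfr >= 60:
        return "1-2"
    if egfr >= 45:
        return "3a"
    if egfr >= 30:
        return "3b"
    if egfr >= 15:
        return "4"
    return "5"


def egfr_annual_slope(record: PatientRecord) -> float:
    """OLS slope of per-visit eGFR against time, in mL/min/1.73 m^2 per year.

    Each creatinine measurement is converted to eGFR with the patient's age
    advanced by the elapsed time since the first visit; the slope is the
    ordinary least-squares coefficient of eGFR on time in years.
    """
    if len(record.creatinine_series) < 4:
        raise CohortError(
            f"{record.patient_id}: insufficient measurements for a slope"
        )
    t0 = record.creatinine_series[0][0]
    t = np.array(
        [(d - t0).days / DAYS_PER_YEAR for d, _ in record.creatinine_series]
    )
    if np.ptp(t) <= 0:
        raise CohortError(f"{record.patient_id}: degenerate time axis")
    y = np.array(
        [
            ckdepi_egfr(cr, record.age + dt_years, record.sex)
            for (_, cr), dt_years in zip(record.creatinine_series, t)
        ]
    )
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


#: Ordered annual eGFR-slope bands (mL/min per year), 5 categories -> 4 df.
SLOPE_CATEGORY_LABELS = ("<=-5", "(-5,-3]", "(-3,-1]", "(-1,+1]", ">+1")


def egfr_slope_category(slope: float) -> str:
    """Band an annual eGFR slope into the five progression-rate categories."""
    if slope <= -5:
        return "<=-5"
    if slope <= -3:
        return "(-5,-3]"
    if slope <= -1:
        return "(-3,-1]"
    if slope <= 1:
        return "(-1,+1]"
    return ">+1"


# ---------------------------------------------------------------------------
# cohort file I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = {
    "patient_id": "patient_id",
    "center_id": "center_id",
    "cohort": "cohort",
    "sex": "sex",
    "age": "age",
    "diabetes": "diabetes",
    "egfr_baseline": "egfr_baseline",
    "enrol_date": "enrol_date",
    "exit_date": "exit_date",
    "outcome": "outcome",
}

_OPTIONAL_COLUMNS = (
    "dipstick_protein",
    "urine_protein_24h",
    "microalbuminuria",
    "proteinuria",
    "phosphate",
    "node",
)


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    v = _opt_float(value)
    return None if v is None else bool(v)


def load_cohort(
    path,
    schema: dict[str, str] | None = None,
    creatinine_path=None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    One row per patient.  The creatinine series may be supplied either as wide
    ``cr_date_k`` / ``cr_val_k`` column pairs or as a companion long CSV
    (columns ``patient_id, date, creatinine``) via ``creatinine_path``.
    ``schema`` maps canonical field names to the file's column names.

    Returns ``(records, rejects)`` where ``rejects`` is a DataFrame with one
    diagnostic row per rejected input row; invalid rows are never silently
    dropped.
    """
    schema = schema or {}
    df = pd.read_csv(path)
    colmap = {k: schema.get(k, v) for k, v in _BASE_COLUMNS.items()}
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise CohortError(f"missing required columns: {missing}")

    long_series: dict[str, list[tuple[_dt.date, float]]] = {}
    if creatinine_path is not None:
        cr = pd.read_csv(creatinine_path)
        for pid, grp in cr.groupby("patient_id"):
            long_series[str(pid)] = [
                (_parse_date(d), float(v))
                for d, v in zip(grp["date"], grp["creatinine"])
            ]
    wide_idx = sorted(
        int(c.rsplit("_", 1)[1]) for c in df.columns if c.startswith("cr_date_")
    )

    records: list[PatientRecord] = []
    rejects: list[dict] = []
    for i, row in df.iterrows():
        pid = str(row[colmap["patient_id"]])
        try:
            if pid in long_series:
                series = sorted(long_series[pid])
            else:
                series = [
                    (_parse_date(row[f"cr_date_{k}"]), float(row[f"cr_val_{k}"]))
                    for k in wide_idx
                    if _opt_float(row.get(f"cr_val_{k}")) is not None
                ]
            rec = PatientRecord(
                patient_id=pid,
                center_id=int(row[colmap["center_id"]]),
                cohort=str(row[colmap["cohort"]]),
                sex=str(row[colmap["sex"]]),
                age=float(row[colmap["age"]]),
                diabetes=bool(int(row[colmap["diabetes"]])),
                egfr_baseline=float(row[colmap["egfr_baseline"]]),
                enrol_date=_parse_date(row[colmap["enrol_date"]]),
                exit_date=_parse_date(row[colmap["exit_date"]]),
                outcome=str(row[colmap["outcome"]]),
                dipstick_protein=_opt_float(row.get("dipstick_protein")),
                urine_protein_24h=_opt_float(row.get("urine_protein_24h")),
                microalbuminuria=_opt_float(row.get("microalbuminuria")),
                proteinuria=_opt_bool(row.get("proteinuria")),
                phosphate=_opt_float(row.get("phosphate")),
                creatinine_series=series,
                node=(lambda n: None if n is None else int(n))(
                    _opt_float(row.get("node"))
                ),
            )
        except (CohortError, ValueError, KeyError) as exc:
            rejects.append({"row": i, "patient_id": pid, "reason": str(exc)})
            continue
        records.append(rec)
    return records, pd.DataFrame(rejects, columns=["row", "patient_id", "reason"])


def cohort_to_frame(
    records: Iterable[PatientRecord], derived: bool = False
) -> pd.DataFrame:
    """Flatten records to a wide DataFrame (creatinine as cr_date_k/cr_val_k).

    With ``derived=True``, append proteinuria status, annual eGFR slope and
    CKD stage columns.
    """
    records = list(records)
    n_cr = max((len(r.creatinine_series) for r in records), default=0)
    rows = []
    for r in records:
        row: dict = {
            "patient_id": r.patient_id,
            "center_id": r.center_id,
            "cohort": r.cohort,
            "sex": r.sex,
            "age": r.age,
            "diabetes": int(r.diabetes),
            "egfr_baseline": r.egfr_baseline,
            "enrol_date": r.enrol_date.isoformat(),
            "exit_date": r.exit_date.isoformat(),
            "outcome": r.outcome,
            "dipstick_protein": r.dipstick_protein,
            "urine_protein_24h": r.urine_protein_24h,
            "microalbuminuria": r.microalbuminuria,
            "proteinuria": None if r.proteinuria is None else int(r.proteinuria),
            "phosphate": r.phosphate,
            "node": r.node,
        }
        for k, (d, v) in enumerate(r.creatinine_series, start=1):
            row[f"cr_date_{k}"] = d.isoformat()
            row[f"cr_val_{k}"] = v
        if derived:
            row["proteinuria_derived"] = int(r.proteinuria_status())
            row["egfr_slope"] = egfr_annual_slope(r) if r.creatinine_series else None
            row["ckd_stage"] = ckd_stage(r.egfr_baseline)
        rows.append(row)
    cols = list(_BASE_COLUMNS) + list(_OPTIONAL_COLUMNS)
    cols += [f"cr_{w}_{k}" for k in range(1, n_cr + 1) for w in ("date", "val")]
    if derived:
        cols += ["proteinuria_derived", "egfr_slope", "ckd_stage"]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(records: Sequence[PatientRecord], path, derived: bool = True) -> None:
    cohort_to_frame(records, derived=derived).to_csv(path, index=False)
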