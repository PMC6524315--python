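"""Fixed CT-PIRP classification tree: assign patients to the seven risk nodes.

The tree was derived once by classification-tree analysis on the original
registry wave and is applied here as a frozen algorithm.  Splits, in order:

* proteinuria present?
    * yes: eGFR > 33.652  -> node 1
           eGFR <= 33.652 and phosphate <= 4.3 -> node 2
           eGFR <= 33.652 and phosphate  > 4.3 -> node 3
    * no:  age <= split and non-diabetic -> node 4
           age <= split and diabetic     -> node 5
           age  > split and female       -> node 6
           age  > split and male         -> node 7

All internal comparisons send "<=" left.  The eGFR and phosphate thresholds
are the published ones; the age threshold is configurable (default 67 y,
consistent with the node age distributions) because its exact value is not
printed in text form.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .cohort import CohortError, PatientRecord

__all__ = ["TreeConfig", "NodeAssignment", "UnassignableError", "assign_node", "assign_cohort"]

NODES = (1, 2, 3, 4, 5, 6, 7)


class UnassignableError(CohortError):
    """Patient cannot be placed in a node (missing required variable)."""


@dataclass(frozen=True)
class TreeConfig:
    """Numeric thresholds of the fixed tree."""

    egfr_split: float = 33.652  # mL/min/1.73 m^2
    phosphate_split: float = 4.3  # mg/dL
    age_split: float = 67.0  # years

    def __post_init__(self) -> None:
        if min(self.egfr_split, self.phosphate_split, self.age_split) <= 0:
            raise ValueError("tree thresholds must be positive")


@dataclass(frozen=True)
class NodeAssignment:
    """Node label plus the predicate path that produced it."""

    node: int
    path: tuple[tuple[str, str, float | str], ...]

    def path_string(self) -> str:
        return " & ".join(f"{v} {c} {t}" for v, c, t in self.path)


def assign_node(patient: PatientRecord, config: TreeConfig = TreeConfig()) -> NodeAssignment:
    """Walk the fixed tree for one patient.

    Raises :class:`UnassignableError` when proteinuria is undeterminable or
    when the proteinuric low-eGFR branch needs a missing phosphate.
    """
    try:
        prot = patient.proteinuria_status()
    except CohortError as exc:
        raise UnassignableError(f"{patient.patient_id}: {exc}") from exc
    path: list[tuple[str, str, float | str]] = []
    if prot:
        path.append(("proteinuria", "==", "present"))
        if patient.egfr_baseline > config.egfr_split:
            path.append(("egfr", ">", config.egfr_split))
            return NodeAssignment(1, tuple(path))
        path.append(("egfr", "<=", config.egfr_split))
        if patient.phosphate is None:
            raise UnassignableError(
                f"{patient.patient_id}: unassignable: phosphate missing"
            )
        if patient.phosphate <= config.phosphate_split:
            path.append(("phosphate", "<=", config.phosphate_split))
            return NodeAssignment(2, tuple(path))
        path.append(("phosphate", ">", config.phosphate_split))
        return NodeAssignment(3, tuple(path))
    path.append(("proteinuria", "==", "absent"))
    if patient.age <= config.age_split:
        path.append(("age", "<=", config.age_split))
        if not patient.diabetes:
            path.append(("diabetes", "==", "no"))
            return NodeAssignment(4, tuple(path))
        path.append(("diabetes", "==", "yes"))
        return NodeAssignment(5, tuple(path))
    path.append(("age", ">", config.age_split))
    if patient.sex == "female":
        path.append(("sex", "==", "female"))
        return NodeAssignment(6, tuple(path))
    path.append(("sex", "==", "male"))
    return NodeAssignment(7, tuple(path))


@dataclass
class AssignmentReport:
    """Cohort-level assignment outcome: labels, counts, and exclusions."""

    assignments: dict[str, NodeAssignment]
    unassignable: dict[str, str]  # patient_id -> reason

    @property
    def counts(self) -> dict[int, int]:
        c = Counter(a.node for a in self.assignments.values())
        return {n: c.get(n, 0) for n in NODES}

    @property
    def proportions(self) -> dict[int, float]:
        total = len(self.assignments)
        return {n: k / total for n, k in self.counts.items()} if total else {}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": pid, "node": a.node, "path": a.path_string()}
            for pid, a in self.assignments.items()
        ]
        rows += [
            {"patient_id": pid, "node": None, "path": reason}
            for pid, reason in self.unassignable.items()
        ]
        return pd.DataFrame(rows, columns=["patient_id", "node", "path"])


def assign_cohort(
    cohort: Iterable[PatientRecord],
    config: TreeConfig = TreeConfig(),
    annotate: bool = True,
) -> AssignmentReport:
    """Assign every patient in a cohort; unassignable patients are reported,
    never dropped.  With ``annotate`` (default) each record's ``node`` field is
    filled in place.  Output is independent of the input ordering."""
    cohort = list(cohort)
    if not cohort:
        raise CohortError("empty cohort")
    assignments: dict[str, NodeAssignment] = {}
    unassignable: dict[str, str] = {}
    for rec in sorted(cohort, key=lambda r: r.patient_id):
        try:
            a = assign_node(rec, config)
        except UnassignableError as exc:
            unassignable[rec.patient_id] = str(exc)
            continue
        assignments[rec.patient_id] = a
    if annotate:
        for rec in cohort:
            rec.node = (
                assignments[rec.patient_id].node
                if rec.patient_id in assignments
                else None
            )
    return AssignmentReport(assignments=assignments, unassignable=unassignable)
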