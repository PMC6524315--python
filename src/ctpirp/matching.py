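"""1:1 matching of validation to derivation patients.

Cohorts are matched exactly on node membership and on follow-up duration
rounded to whole months, so the matched subsets have identical node
distributions and closely comparable observation windows by construction.
Pairing within a (node, month) cell is greedy in sorted patient-id order,
which makes the result deterministic and independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import PatientRecord

__all__ = ["MatchResult", "followup_months", "match_cohorts"]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


def followup_months(record: PatientRecord) -> int:
    """Follow-up duration rounded to whole months (half-month rounds up)."""
    days = (record.exit_date - record.enrol_date).days
    return int(days / DAYS_PER_MONTH + 0.5)


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (derivation_id, validation_id)
    unmatched_derivation: list[str]
    unmatched_validation: list[str]
    match_variables: tuple[str, ...] = ("node", "followup_months")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["derivation_id", "validation_id"])


def _cells(records: Sequence[PatientRecord]) -> dict[tuple[int, int], list[str]]:
    cells: dict[tuple[int, int], list[str]] = {}
    for r in records:
        if r.node is None:
            continue
        cells.setdefault((r.node, followup_months(r)), []).append(r.patient_id)
    return {k: sorted(v) for k, v in cells.items()}


def match_cohorts(
    derivation: Sequence[PatientRecord],
    validation: Sequence[PatientRecord],
    caliper_months: int = 0,
) -> MatchResult:
    """Pair patients sharing a node and (rounded) follow-up month.

    Within each (node, month) cell, pairs are formed up to the smaller cell
    count.  With ``caliper_months > 0``, leftovers may then be paired to the
    nearest month within +/- the caliper (same node), closest offset first.
    Patients without a node assignment are left unmatched.
    """
    d_cells = _cells(derivation)
    v_cells = _cells(validation)
    pairs: list[tuple[str, str]] = []
    for key in sorted(set(d_cells) & set(v_cells)):
        d, v = d_cells[key], v_cells[key]
        k = min(len(d), len(v))
        pairs.extend(zip(d[:k], v[:k]))
        d_cells[key], v_cells[key] = d[k:], v[k:]
    if caliper_months > 0:
        for offset in range(1, caliper_months + 1):
            for key in sorted(d_cells):
                node, month = key
                if not d_cells.get(key):
                    continue
                for cand in ((node, month - offset), (node, month + offset)):
                    d = d_cells[key]
                    v = v_cells.get(cand, [])
                    k = min(len(d), len(v))
                    if k:
                        pairs.extend(zip(d[:k], v[:k]))
                        d_cells[key], v_cells[cand] = d[k:], v[k:]
    matched_d = {a for a, _ in pairs}
    matched_v = {b for _, b in pairs}
    unmatched_d = sorted(
        r.patient_id for r in derivation if r.patient_id not in matched_d
    )
    unmatched_v = sorted(
        r.patient_id for r in validation if r.patient_id not in matched_v
    )
    return MatchResult(
        pairs=sorted(pairs),
        unmatched_derivation=unmatched_d,
        unmatched_validation=unmatched_v,
    )
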