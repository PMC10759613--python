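"""Trauma-based subgroup assignment.

GWI subjects are split by comorbid-PTSD probability using whichever evidence
their recruitment site provides: the Davidson Trauma Scale total (0-136,
self-report; exercise-site cohort) with an inclusive cut at 70, or a
structured-clinical-interview PTSD diagnosis flag (rest-only cohort).
Controls are labeled HC regardless of trauma evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import DTS_MAX, EXERCISE_SITE, REST_ONLY_SITE, CohortTable

__all__ = [
    "DTS_CUT",
    "GroupAssignment",
    "assign_by_dts",
    "assign_by_dx",
    "assign_groups",
]

DTS_CUT = 70


@dataclass(frozen=True)
class GroupAssignment:
    subject_id: str
    label: str  # HC | GWI_L | GWI_H
    evidence: str  # dts_cut | clinical_dx
    dts_total: int | None = None


def assign_by_dts(is_gwi: bool, dts_total: int) -> str:
    """DTS rule: GWI with total >= 70 -> GWI_H, below -> GWI_L; controls -> HC."""
    if not 0 <= dts_total <= DTS_MAX:
        raise ValueError(
            f"DTS total {dts_total} outside the scale range [0, {DTS_MAX}]"
        )
    if not is_gwi:
        return "HC"
    return "GWI_H" if dts_total >= DTS_CUT else "GWI_L"


def assign_by_dx(is_gwi: bool, ptsd_dx: bool) -> str:
    """Clinical-interview rule: GWI with a PTSD diagnosis -> GWI_H."""
    if not is_gwi:
        return "HC"
    return "GWI_H" if ptsd_dx else "GWI_L"


def assign_groups(cohort: CohortTable) -> list[GroupAssignment]:
    """Apply the site-appropriate rule to every subject in the cohort.

    Each subject must carry exactly one evidence source: a DTS total for
    exercise-site subjects or a PTSD diagnosis flag for rest-only subjects.
    """
    out: list[GroupAssignment] = []
    for row in cohort.subjects.itertuples(index=False):
        is_gwi = row.group in ("GWI_L", "GWI_H")
        has_dts = pd.notna(row.dts_total)
        has_dx = pd.notna(row.ptsd_dx)
        if has_dts == has_dx:
            raise ValueError(
                f"subject {row.subject_id}: expected exactly one evidence "
                f"source, got dts={row.dts_total!r} ptsd_dx={row.ptsd_dx!r}"
            )
        if has_dts:
            if row.site != EXERCISE_SITE:
                raise ValueError(
                    f"subject {row.subject_id}: DTS evidence at site {row.site}"
                )
            label = assign_by_dts(is_gwi, int(row.dts_total))
            out.append(
                GroupAssignment(row.subject_id, label, "dts_cut", int(row.dts_total))
            )
        else:
            if row.site != REST_ONLY_SITE:
                raise ValueError(
                    f"subject {row.subject_id}: diagnosis evidence at site "
                    f"{row.site}"
                )
            label = assign_by_dx(is_gwi, bool(row.ptsd_dx))
            out.append(GroupAssignment(row.subject_id, label, "clinical_dx"))
    return out


def assignments_frame(assignments: list[GroupAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in assignments],
            "label": [a.label for a in assignments],
            "evidence": [a.evidence for a in assignments],
            "dts_total": [a.dts_total for a in assignments],
        }
    )
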