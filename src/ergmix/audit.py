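"""Misspecification audit: FP/FN/TP/TN bookkeeping for mixing terms.

Each selective-mixing parameter is compared between a full model and the
base (partial) model: FP = significant only in the partial model, FN =
significant only in the full model, TP/TN = significant/non-significant
in both.  Tallies are broken down by cortical grouping of the mixing
cell and by subject group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ergm import FitResult
from .graph_core import NodeAttributeTable
from .model import ComparisonSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PatientSession",
    "ErrorRecord",
    "ErrorTally",
    "infer_gose",
    "assign_group",
    "classify_pe",
    "cortical_grouping",
    "audit_comparison",
    "tally_errors",
]

OUTCOMES = ("FP", "FN", "TP", "TN")
GROUPINGS = ("within_cortical", "within_subcortical", "cortico_subcortical")


def infer_gose(gcs_v: int, gcs_m: int) -> int:
    """Inferred extended outcome score from the verbal and motor subscales.

    2 (vegetative-state-consistent) when V <= 3 and M <= 4, else 3.
    """
    if not 1 <= gcs_v <= 5:
        raise ValueError(f"GCS verbal subscale {gcs_v} outside 1..5")
    if not 1 <= gcs_m <= 6:
        raise ValueError(f"GCS motor subscale {gcs_m} outside 1..6")
    return 2 if (gcs_v <= 3 and gcs_m <= 4) else 3


def assign_group(session: str, inferred_gose: int) -> str:
    """Map a session label and inferred outcome score to a subject group.

    Patient sessions ('acute'/'chronic'): unconscious when the inferred
    score is 2, otherwise conscious_acute / conscious_chronic.  Rest
    sessions ('rest1'/'rest2') pass through unchanged.
    """
    if session in ("rest1", "rest2"):
        return session
    if session not in ("acute", "chronic"):
        raise ValueError(f"unknown session {session!r}")
    if inferred_gose == 2:
        return "unconscious"
    return f"conscious_{session}"


@dataclass(frozen=True)
class PatientSession:
    subject_id: str
    session: str  # acute/chronic or rest1/rest2
    gcs_v: int | None = None
    gcs_m: int | None = None

    @property
    def inferred_gose(self) -> int | None:
        if self.gcs_v is None or self.gcs_m is None:
            return None
        return infer_gose(self.gcs_v, self.gcs_m)

    @property
    def group(self) -> str:
        if self.session in ("rest1", "rest2"):
            return self.session
        gose = self.inferred_gose
        if gose is None:
            raise ValueError(
                f"{self.subject_id}/{self.session}: GCS subscales required"
            )
        return assign_group(self.session, gose)


def classify_pe(full: FitResult, partial: FitResult, term: str) -> str:
    """FP/FN/TP/TN from the two significance booleans for one term."""
    for fit, which in ((full, "full"), (partial, "partial")):
        if term not in fit.term_names:
            raise KeyError(f"term {term!r} missing from the {which} fit")
        if not fit.converged:
            raise ValueError(f"{which} fit did not converge")
    sig_full = bool(full.significant[full.term(term)])
    sig_partial = bool(partial.significant[partial.term(term)])
    if sig_partial and not sig_full:
        return "FP"
    if sig_full and not sig_partial:
        return "FN"
    return "TP" if sig_full else "TN"


def cortical_grouping(term: str, attrs: NodeAttributeTable) -> str:
    """Cortical grouping of one mixing term ``mix.<a>.<b>``."""
    if not term.startswith("mix."):
        raise ValueError(f"{term!r} is not a mixing term")
    _, a, b = term.split(".", 2)
    ga = attrs.cortical_group_of(a)
    gb = attrs.cortical_group_of(b)
    if ga == "cortical" and gb == "cortical":
        return "within_cortical"
    if ga == "subcortical" and gb == "subcortical":
        return "within_subcortical"
    return "cortico_subcortical"


@dataclass(frozen=True)
class ErrorRecord:
    subject_id: str
    session: str
    comparison: str
    term: str
    cortical_grouping: str
    outcome: str  # FP/FN/TP/TN


def audit_comparison(
    full: FitResult,
    partial: FitResult,
    comparison: ComparisonSpec | str,
    attrs: NodeAttributeTable,
    subject_id: str,
    session: str,
) -> list[ErrorRecord]:
    """Classify every mixing term shared by the two fits."""
    name = comparison if isinstance(comparison, str) else comparison.name
    records = []
    for term in partial.term_names:
        if not term.startswith("mix."):
            continue
        records.append(
            ErrorRecord(
                subject_id=subject_id,
                session=session,
                comparison=name,
                term=term,
                cortical_grouping=cortical_grouping(term, attrs),
                outcome=classify_pe(full, partial, term),
            )
        )
    return records


@dataclass
class ErrorTally:
    """Counts by (group, cortical grouping, outcome category).

    The ``none`` category pools TP and TN.
    """

    table: pd.DataFrame  # columns: group, cortical_grouping, category, count

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    def count(self, group: str, grouping: str, category: str) -> int:
        t = self.table
        m = (
            (t["group"] == group)
            & (t["cortical_grouping"] == grouping)
            & (t["category"] == category)
        )
        return int(t.loc[m, "count"].sum())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def records_frame(records: Iterable[ErrorRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def tally_errors(
    records: Sequence[ErrorRecord], sessions: Sequence[PatientSession]
) -> ErrorTally:
    """Accumulate FP/FN/none counts per group and cortical grouping."""
    group_of = {(s.subject_id, s.session): s.group for s in sessions}
    rows: dict[tuple[str, str, str], int] = {}
    groups = sorted(set(group_of.values()))
    for g in groups:
        for cg in GROUPINGS:
            for cat in ("FP", "FN", "none"):
                rows[(g, cg, cat)] = 0
    for r in records:
        key = (r.subject_id, r.session)
        if key not in group_of:
            raise KeyError(f"no session/group entry for {key}")
        cat = r.outcome if r.outcome in ("FP", "FN") else "none"
        rows[(group_of[key], r.cortical_grouping, cat)] += 1
    table = pd.DataFrame(
        [
            {"group": g, "cortical_grouping": cg, "category": cat, "count": c}
            for (g, cg, cat), c in rows.items()
        ]
    )
    return ErrorTally(table=table)
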