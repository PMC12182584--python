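"""Darwin Core occurrence export.

Fourteen fields of the standard carry explicit Darwin Core equivalences;
this module flattens a dataset into a GBIF-style occurrence table (term
names as bare column headers).  Each output row represents the HOST
organism occurrence — the standard attaches ``scientificName`` to the
host identification — with parasite evidence carried in
``occurrenceStatus`` (positive -> "present", negative -> "absent",
inconclusive or untested -> blank) and ``associatedOccurrences`` (the
detection target).  The parasite-centric convention also exists in the
wild; see docs/methods.md.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .io import Dataset
from .registry import core_registry

__all__ = ["to_darwin_core", "compose_event_date", "DWC_TERMS"]

#: The 14 mapped Darwin Core terms, in export order.
DWC_TERMS = (
    "decimalLatitude", "decimalLongitude", "coordinateUncertaintyInMeters",
    "day", "month", "year", "scientificName", "sex", "lifeStage",
    "organismQuantity", "organismQuantityType", "associatedOccurrences",
    "occurrenceStatus", "otherCatalogNumbers",
)

_OUTCOME_TO_STATUS = {"positive": "present", "negative": "absent"}


def compose_event_date(day: Optional[int], month: Optional[int],
                       year: Optional[int]):
    """ISO 8601 event date from possibly partial day/month/year.

    Returns ``(text, findings)``: "YYYY-MM-DD" when all parts are present,
    "YYYY-MM" without a day, "YYYY" with only a year, and ``None`` without
    a year.  A day without a month cannot be placed and is dropped with a
    finding.
    """
    findings = []
    if year is None:
        return None, findings
    if month is None:
        if day is not None:
            findings.append("day given without month; day dropped from "
                            "eventDate")
        return f"{year:04d}", findings
    if day is None:
        return f"{year:04d}-{month:02d}", findings
    return f"{year:04d}-{month:02d}-{day:02d}", findings


def to_darwin_core(dataset: Dataset, registry=None):
    """Flatten a dataset into a Darwin Core occurrence table.

    Returns ``(table, findings)`` where ``table`` is a DataFrame with one
    row per record: ``occurrenceID`` (sample id + "|" + detection target,
    best-effort unique), ``eventDate``, the 14 mapped terms, and every
    unmapped standard field as a verbatim extension column prefixed
    ``wdds:``.
    """
    if registry is None:
        registry = core_registry()
    mapped = {spec.slug: spec.dwc_equivalent for spec in registry
              if spec.dwc_equivalent}
    unmapped = [spec for spec in registry if not spec.dwc_equivalent]
    rows, findings = [], []
    for rec in dataset.records:
        row: dict = {}
        target = rec.detection_target or ""
        sid = rec.sample_id or ""
        row["occurrenceID"] = f"{sid}|{target}"
        event_date, notes = compose_event_date(
            rec.collection_day, rec.collection_month, rec.collection_year)
        for note in notes:
            findings.append(f"row {rec.source_row}: {note}")
        row["eventDate"] = event_date
        for slug, term in mapped.items():
            row[term] = getattr(rec, slug)
        outcome = rec.detection_outcome
        if isinstance(outcome, str):
            outcome = outcome.casefold()
        row["occurrenceStatus"] = _OUTCOME_TO_STATUS.get(outcome)
        for spec in unmapped:
            row[f"wdds:{spec.slug}"] = getattr(rec, spec.slug)
        rows.append(row)
    columns = (["occurrenceID", "eventDate"] + list(DWC_TERMS) +
               [f"wdds:{spec.slug}" for spec in unmapped])
    table = pd.DataFrame(rows, columns=columns)
    return table, findings


def darwin_core_csv(dataset: Dataset, registry=None) -> str:
    """Darwin Core occurrence table serialized as CSV text."""
    table, _ = to_darwin_core(dataset, registry)
    return table.to_csv(index=False, lineterminator="\n")
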