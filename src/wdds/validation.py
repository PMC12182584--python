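"""Rule-based validation of records and datasets.

Every rule has a stable code in :data:`wdds.report.RULES`.  Records of
untested samples (blank detection outcome) are legal; for those rows the
detection target and method are also exempt from the required-field rule,
since a sample with no attached test has no test to describe.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

from .io import Dataset, DiseaseRecord
from .registry import DETECTION_OUTCOMES, core_registry, metadata_registry
from .report import ValidationIssue, ValidationReport

__all__ = ["validate_record", "validate_dataset", "check_fit_for_purpose",
           "ElementCompleteness"]

_PY_KINDS = {
    "text": (str,),
    "number": (int, float),
    "integer": (int,),
    "boolean": (bool,),
}

# Detection fields exempt from REQ_FIELD on untested-sample rows.
_TEST_FIELDS = ("detection_target", "detection_method", "detection_outcome")


def _kind_ok(value, kind: str) -> bool:
    if kind in ("number", "integer") and isinstance(value, bool):
        return False
    if kind == "integer" and isinstance(value, float):
        # align with JSON semantics, where 23.0 is a valid integer
        return value.is_integer()
    return isinstance(value, _PY_KINDS[kind])


def validate_record(record: DiseaseRecord, registry=None) -> list:
    """Apply all record-level rules; returns a list of issues (never
    raises — findings are data, not exceptions)."""
    if registry is None:
        registry = core_registry()
    issues: list = []
    row = record.source_row

    def add(rule, severity, field_, msg):
        issues.append(ValidationIssue(rule_id=rule, severity=severity,
                                      record=row, field=field_, message=msg))

    untested = record.detection_outcome is None
    typed_ok = {}
    for spec in registry:
        value = getattr(record, spec.slug, None)
        if value is None:
            typed_ok[spec.slug] = False
            if spec.required and spec.cell_required_when is None and \
                    not (untested and spec.slug in _TEST_FIELDS):
                add("REQ_FIELD", "error", spec.slug,
                    f"required field {spec.name!r} is blank")
            continue
        if not _kind_ok(value, spec.value_kind):
            typed_ok[spec.slug] = False
            add("FIELD_TYPE", "error", spec.slug,
                f"{spec.name!r} holds {value!r}, expected "
                f"{spec.value_kind}")
            continue
        typed_ok[spec.slug] = True
        if spec.vocabulary is not None and \
                str(value).casefold() not in spec.vocabulary:
            add("VOCAB", "error", spec.slug,
                f"{spec.name!r} value {value!r} not in "
                f"{set(spec.vocabulary)}")

    # units / measurement-axis pairings
    for spec in registry:
        if spec.depends_on and typed_ok.get(spec.depends_on) and \
                getattr(record, spec.slug, None) is None:
            add("UNITS_PAIR", "error", spec.slug,
                f"{spec.name!r} must be provided because "
                f"{spec.depends_on!r} is provided")

    # coordinates
    lat, lon = record.latitude, record.longitude
    if typed_ok.get("latitude") and not -90 <= lat <= 90:
        add("COORD_RANGE", "error", "latitude",
            f"latitude {lat!r} outside [-90, 90]")
    if typed_ok.get("longitude") and not -180 <= lon <= 180:
        add("COORD_RANGE", "error", "longitude",
            f"longitude {lon!r} outside [-180, 180]")
    if typed_ok.get("spatial_uncertainty") and record.spatial_uncertainty < 0:
        add("COORD_RANGE", "error", "spatial_uncertainty",
            f"spatial uncertainty {record.spatial_uncertainty!r} is "
            f"negative")
    if typed_ok.get("latitude") and typed_ok.get("longitude") and \
            lat == 0 and lon == 0:
        add("PLACEHOLDER", "warning", "latitude",
            "coordinates are exactly (0, 0) — likely a placeholder")

    # calendar date; partial dates are legal
    day, month, year = (record.collection_day, record.collection_month,
                        record.collection_year)
    if typed_ok.get("collection_month") and not 1 <= month <= 12:
        add("DATE_VALID", "error", "collection_month",
            f"month {month!r} outside [1, 12]")
    elif typed_ok.get("collection_day") and not 1 <= day <= 31:
        add("DATE_VALID", "error", "collection_day",
            f"day {day!r} outside [1, 31]")
    elif all(typed_ok.get(s) for s in
             ("collection_day", "collection_month", "collection_year")):
        if int(day) > calendar.monthrange(int(year), int(month))[1]:
            add("DATE_VALID", "error", "collection_day",
                f"{year}-{month:02d}-{day:02d} is not a real date")

    # outcome/identity consistency
    outcome = record.detection_outcome
    if isinstance(outcome, str):
        outcome = outcome.casefold()
    if outcome == "positive" and record.parasite_identification is None:
        add("POS_NO_ID", "warning", "parasite_identification",
            "positive outcome without a parasite identification")
    if outcome == "negative" and record.parasite_identification is not None:
        add("NEG_WITH_ID", "error", "parasite_identification",
            f"negative outcome with parasite identification "
            f"{record.parasite_identification!r}; the cell must be blank")
    return issues


def _row_key(record: DiseaseRecord) -> tuple:
    return (tuple(record.typed_slots().items()),
            tuple(sorted(record.extras.items())))


def validate_dataset(dataset: Dataset, registry=None,
                     parse_findings=None) -> ValidationReport:
    """Validate every record plus cross-record, pooled-link, nesting and
    metadata rules; returns a :class:`ValidationReport`."""
    if registry is None:
        registry = core_registry()
    issues: list = list(parse_findings or [])
    for record in dataset.records:
        issues.extend(validate_record(record, registry))

    # cross-record consistency on stable host attributes
    by_animal: dict = {}
    for record in dataset.records:
        for aid in record.animal_ids():
            by_animal.setdefault(aid, []).append(record)
    for aid, group in by_animal.items():
        if len(group) < 2:
            continue
        for slug, label in (("host_identification", "host identification"),
                            ("organism_sex", "sex")):
            values = {getattr(r, slug) for r in group
                      if getattr(r, slug) is not None}
            if len(values) > 1:
                issues.append(ValidationIssue(
                    rule_id="XREC_CONFLICT", severity="warning",
                    record=group[-1].source_row, field=slug,
                    message=f"records of animal {aid!r} disagree on "
                            f"{label}: {sorted(map(str, values))}"))

    # byte-identical duplicate rows
    seen: dict = {}
    for record in dataset.records:
        key = _row_key(record)
        if key in seen:
            issues.append(ValidationIssue(
                rule_id="DUP_ROW", severity="warning",
                record=record.source_row,
                message=f"row duplicates row {seen[key]}"))
        else:
            seen[key] = record.source_row

    # pooled-sample side table integrity
    if dataset.pooled_links:
        sample_ids = {r.sample_id for r in dataset.records
                      if r.sample_id is not None}
        for sample_id, animal_id in dataset.pooled_links:
            if sample_id not in sample_ids:
                issues.append(ValidationIssue(
                    rule_id="POOL_LINK", severity="error", field="sample_id",
                    message=f"pooled link ({sample_id!r}, {animal_id!r}) "
                            f"references a sample absent from the dataset"))

    # nesting acyclicity (parasite-of-parasite chains)
    from .relationships import find_nesting_cycles
    for cycle in find_nesting_cycles(dataset):
        issues.append(ValidationIssue(
            rule_id="NEST_CYCLE", severity="error", field="parasite_id",
            message=f"nested detections form a cycle: "
                    f"{' -> '.join(cycle + cycle[:1])}"))

    if dataset.metadata is not None:
        from .pids import validate_metadata
        issues.extend(validate_metadata(dataset.metadata,
                                        metadata_registry()))
    return ValidationReport(issues=issues)


@dataclass
class ElementCompleteness:
    """Advisory completeness of one fit-for-purpose element."""

    element: str
    present: bool
    completeness: float  # fraction of records with the element populated

    def __str__(self):
        state = "present" if self.present else "ABSENT"
        return f"{self.element}: {state} ({self.completeness:.0%} of records)"


def check_fit_for_purpose(dataset: Dataset) -> list:
    """Advisory check that the dataset carries the elements every record
    of a wildlife disease dataset should include: host identification,
    diagnostic method, test outcome, a parasite-identification column,
    and the date and location of sampling."""
    n = len(dataset.records)

    def frac(predicate) -> float:
        if n == 0:
            return 0.0
        return sum(1 for r in dataset.records if predicate(r)) / n

    elements = [
        ("host identification", frac(lambda r: r.host_identification
                                     is not None)),
        ("diagnostic method", frac(lambda r: r.detection_method is not None)),
        ("test outcome", frac(lambda r: r.detection_outcome is not None)),
        ("parasite identification",
         frac(lambda r: r.parasite_identification is not None or
              r.detection_outcome is not None)),
        ("sampling date", frac(lambda r: r.collection_year is not None)),
        ("sampling location", frac(lambda r: r.latitude is not None and
                                   r.longitude is not None)),
    ]
    return [ElementCompleteness(name, completeness > 0, completeness)
            for name, completeness in elements]
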