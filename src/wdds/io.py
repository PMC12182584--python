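"""Reading and writing standard-conformant flat files.

The on-disk contract is deliberately plain: CSV, UTF-8 (BOM tolerated),
comma delimiter, period decimal separator, RFC 4180 quoting.  A blank cell
is a first-class "no value" state — placeholder tokens such as ``NA`` are
converted to blank at parse time and reported as findings, and are never
written back out.  Unrecognized columns are preserved verbatim so that
datasets extended beyond the minimum standard survive a round trip.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .registry import FieldSpec, core_registry, metadata_registry, slugify
from .report import ValidationIssue

__all__ = [
    "DiseaseRecord", "Dataset", "ProvenanceEntry", "ProjectMetadata",
    "read_csv", "write_csv", "read_metadata", "read_pooled_links",
    "record_to_object", "ParseError", "PLACEHOLDER_TOKENS",
]

#: Tokens treated (case-insensitively) as illegal placeholders for "no value".
PLACEHOLDER_TOKENS = frozenset(
    {"na", "n/a", "nan", "null", "none", "-", "."})

_CORE_SLUGS = tuple(s.slug for s in core_registry())


class ParseError(ValueError):
    """Hard, unrecoverable defect in an input file (encoding, ragged rows,
    duplicate headers)."""


@dataclass
class DiseaseRecord:
    """One row of a dataset: the outcome of a single diagnostic test, with
    its sampling context, host data, and parasite data.

    Blank cells are ``None``.  Numeric slots hold floats, integer slots
    ints, ``live_capture`` a tri-state bool/None.  Columns outside the
    standard are kept verbatim in :attr:`extras`.
    """

    # sampling
    sample_id: Optional[str] = None
    animal_id: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    spatial_uncertainty: Optional[float] = None
    collection_day: Optional[int] = None
    collection_month: Optional[int] = None
    collection_year: Optional[int] = None
    sample_collection_method: Optional[str] = None
    sample_collection_body_part: Optional[str] = None
    sample_material: Optional[str] = None
    # host
    host_identification: Optional[str] = None
    organism_sex: Optional[str] = None
    live_capture: Optional[bool] = None
    host_life_stage: Optional[str] = None
    age: Optional[float] = None
    age_units: Optional[str] = None
    mass: Optional[float] = None
    mass_units: Optional[str] = None
    length: Optional[float] = None
    length_measurement: Optional[str] = None
    length_units: Optional[str] = None
    organism_quantity: Optional[float] = None
    organism_quantity_units: Optional[str] = None
    # parasite
    detection_target: Optional[str] = None
    detection_method: Optional[str] = None
    forward_primer_sequence: Optional[str] = None
    reverse_primer_sequence: Optional[str] = None
    gene_target: Optional[str] = None
    primer_citation: Optional[str] = None
    probe_target: Optional[str] = None
    probe_type: Optional[str] = None
    probe_citation: Optional[str] = None
    detection_outcome: Optional[str] = None
    detection_measurement: Optional[float] = None
    detection_measurement_units: Optional[str] = None
    parasite_identification: Optional[str] = None
    parasite_id: Optional[str] = None
    parasite_life_stage: Optional[str] = None
    genbank_accession: Optional[str] = None
    # bookkeeping
    extras: dict = field(default_factory=dict)
    source_row: Optional[int] = None

    def get(self, slug: str):
        return getattr(self, slug)

    def typed_slots(self) -> dict:
        """Mapping slug -> value over the 40 standard slots."""
        return {slug: getattr(self, slug) for slug in _CORE_SLUGS}

    def animal_ids(self) -> list:
        """Animal identifiers on this row; a pooled row may carry several
        separated by ';'."""
        if self.animal_id is None:
            return []
        return [tok.strip() for tok in str(self.animal_id).split(";")
                if tok.strip()]


@dataclass
class ProvenanceEntry:
    """One documented transformation applied to a dataset."""

    method: str
    parameters: dict
    timestamp: str

    @classmethod
    def now(cls, method: str, parameters: dict) -> "ProvenanceEntry":
        return cls(method, dict(parameters),
                   datetime.now(timezone.utc).isoformat(timespec="seconds"))


@dataclass
class ProjectMetadata:
    """Project-level metadata document (DataCite-derived properties).

    ``values`` maps registry property names to their raw JSON values;
    unknown properties are preserved in ``extras``.
    """

    values: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def get(self, name: str):
        return self.values.get(name)

    def creators(self) -> list:
        """Creators as dicts with name/orcid/affiliation/ror keys."""
        raw = self.values.get("Creators")
        out = []
        for entry in _aslist(raw):
            if isinstance(entry, dict):
                out.append({"name": entry.get("name"),
                            "orcid": entry.get("orcid"),
                            "affiliation": entry.get("affiliation"),
                            "ror": entry.get("ror")})
            else:
                out.append({"name": str(entry), "orcid": None,
                            "affiliation": None, "ror": None})
        return out

    def funders(self) -> list:
        raw = self.values.get("Funder name")
        out = []
        for entry in _aslist(raw):
            if isinstance(entry, dict):
                out.append({"name": entry.get("name"),
                            "funder_id": entry.get("funder_id"),
                            "award": entry.get("award")})
            else:
                out.append({"name": str(entry), "funder_id": None,
                            "award": None})
        return out


def _aslist(value) -> list:
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


@dataclass
class Dataset:
    """Ordered records plus optional project metadata, pooled-sample links,
    and an append-only provenance log."""

    records: list = field(default_factory=list)
    metadata: Optional[ProjectMetadata] = None
    pooled_links: Optional[list] = None  # list of (sample_id, animal_id)
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# parsing

def _decode(source: Union[str, bytes, Path, _io.IOBase]) -> str:
    """Return text from a path, byte string, text string, or file object;
    a hard error names the byte offset of any undecodable byte."""
    if isinstance(source, Path):
        data = source.read_bytes()
    elif isinstance(source, bytes):
        data = source
    elif isinstance(source, str):
        try:
            is_path = "\n" not in source and Path(source).is_file()
        except (OSError, ValueError):
            is_path = False
        if is_path:
            data = Path(source).read_bytes()
        else:
            return source
    elif hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return data
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot read from {type(source)!r}")
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise ParseError(
            f"input is not valid UTF-8: byte 0x{data[exc.start]:02x} at "
            f"offset {exc.start}") from exc
    return text.lstrip("﻿")


def _clean_cell(raw: str):
    """Strip whitespace; return (value_or_None, was_placeholder)."""
    s = raw.strip()
    if s == "":
        return None, False
    if s.lower() in PLACEHOLDER_TOKENS:
        return None, True
    return s, False


_MINUS_NORMALIZE = str.maketrans({"−": "-"})


def _parse_typed(s: str, spec: FieldSpec):
    """Parse a cleaned, non-blank cell into the field's value kind.
    Raises ValueError when the cell cannot be interpreted."""
    if spec.value_kind == "text":
        return s
    if spec.value_kind == "boolean":
        low = s.lower()
        if low == "true":
            return True
        if low == "false":
            return False
        raise ValueError(f"expected TRUE or FALSE, got {s!r}")
    s = s.translate(_MINUS_NORMALIZE)
    if spec.value_kind == "integer":
        return int(s, 10)
    return float(s)


def read_csv(source, registry=None, pooled_links=None):
    """Parse a standard-formatted CSV into a :class:`Dataset`.

    Parameters
    ----------
    source
        Path, text, bytes, or file object holding the CSV.
    registry
        Field registry to match headers against (default: the core
        registry).  Headers match case-insensitively via their slug, so
        both printed names ("Sample ID") and slugs (``sample_id``) work.
    pooled_links
        Optional pooled-sample side table, as a list of
        ``(sample_id, animal_id)`` pairs or a source accepted by
        :func:`read_pooled_links`.

    Returns
    -------
    (Dataset, list of ValidationIssue)
        All rows are returned even when findings exist.  Hard errors
        (undecodable bytes, duplicate headers, ragged rows) raise
        :class:`ParseError` instead.
    """
    if registry is None:
        registry = core_registry()
    text = _decode(source)
    reader = csv.reader(_io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("input is empty: no header row") from None

    by_slug = {spec.slug: spec for spec in registry}
    columns = []  # (raw_name, spec_or_None)
    seen_raw, seen_slug = set(), set()
    for raw in header:
        name = raw.strip().lstrip("﻿")
        key = slugify(name)
        if name in seen_raw or (key in seen_slug and key in by_slug):
            raise ParseError(f"duplicate header name: {name!r}")
        seen_raw.add(name)
        seen_slug.add(key)
        columns.append((name, by_slug.get(key)))

    findings: list = []
    present_slugs = {spec.slug for _, spec in columns if spec is not None}
    for spec in registry:
        if spec.required and spec.slug not in present_slugs:
            findings.append(ValidationIssue(
                rule_id="REQ_FIELD", severity="error", record=None,
                field=spec.slug,
                message=f"required column {spec.name!r} is missing"))

    records = []
    for i, row in enumerate(reader, start=2):
        if not row:
            continue  # trailing blank line
        if len(row) != len(columns):
            raise ParseError(
                f"row {i} has {len(row)} cells, header has {len(columns)}")
        rec = DiseaseRecord(source_row=i)
        for (name, spec), raw in zip(columns, row):
            value, was_placeholder = _clean_cell(raw)
            if was_placeholder:
                findings.append(ValidationIssue(
                    rule_id="PLACEHOLDER", severity="warning", record=i,
                    field=spec.slug if spec else name,
                    message=f"placeholder value {raw.strip()!r} treated as "
                            f"blank in {name!r}"))
            if spec is None:
                rec.extras[name] = "" if value is None else raw.strip()
                continue
            if value is None:
                continue
            try:
                setattr(rec, spec.slug, _parse_typed(value, spec))
            except ValueError:
                findings.append(ValidationIssue(
                    rule_id="FIELD_TYPE", severity="error", record=i,
                    field=spec.slug,
                    message=f"cannot parse {value!r} as "
                            f"{spec.value_kind} for {spec.name!r}"))
        records.append(rec)

    if pooled_links is not None and not isinstance(pooled_links, list):
        pooled_links = read_pooled_links(pooled_links)
    return Dataset(records=records, pooled_links=pooled_links), findings


def read_pooled_links(source) -> list:
    """Read the two-column ``sample_id,animal_id`` side table that links a
    pooled sample to its member animals."""
    text = _decode(source)
    reader = csv.reader(_io.StringIO(text))
    header = next(reader, None)
    if header is None:
        return []
    pairs = []
    rows = [header] if slugify(header[0]) != "sample_id" else []
    rows.extend(reader)
    for row in rows:
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise ParseError(f"pooled-links row needs 2 cells: {row!r}")
        pairs.append((row[0].strip(), row[1].strip()))
    return pairs


# ---------------------------------------------------------------------------
# writing

def _format_cell(value) -> str:
    if value is None:
        return ""
    if value is True:
        return "TRUE"
    if value is False:
        return "FALSE"
    if isinstance(value, float):
        if value.is_integer():
            return str(int(value))
        return repr(value)
    return str(value)


def write_csv(dataset: Dataset, registry=None) -> str:
    """Serialize a dataset to standard CSV text.

    Core columns appear in registry order under their printed names, then
    extra columns in first-seen order.  Blanks become empty cells — never
    a placeholder token.
    """
    if registry is None:
        registry = core_registry()
    extra_names: list = []
    for rec in dataset.records:
        for name in rec.extras:
            if name not in extra_names:
                extra_names.append(name)
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([spec.name for spec in registry] + extra_names)
    for rec in dataset.records:
        row = [_format_cell(getattr(rec, spec.slug)) for spec in registry]
        row += [rec.extras.get(name, "") for name in extra_names]
        writer.writerow(row)
    return buf.getvalue()


def write_pooled_links(pairs) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["sample_id", "animal_id"])
    writer.writerows(pairs or [])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# record <-> JSON object

def record_to_object(record: DiseaseRecord, registry=None) -> dict:
    """Serialize a record for JSON Schema validation: slug -> value with
    blanks as null; the detection outcome is canonicalized to lowercase."""
    if registry is None:
        registry = core_registry()
    obj = {}
    for spec in registry:
        value = getattr(record, spec.slug, None)
        if spec.slug == "detection_outcome" and isinstance(value, str):
            value = value.lower()
        obj[spec.slug] = value
    obj.update(record.extras)
    return obj


def read_metadata(source, registry=None) -> ProjectMetadata:
    """Parse a project-metadata JSON document.

    Properties are matched by name (case-insensitively via slug); unknown
    properties are preserved in ``extras``.  Malformed JSON raises
    :class:`ParseError` with the position.
    """
    if registry is None:
        registry = metadata_registry()
    text = _decode(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"malformed metadata JSON at line {exc.lineno} column "
            f"{exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise ParseError("metadata document must be a JSON object")
    by_slug = {spec.slug: spec.name for spec in registry}
    meta = ProjectMetadata()
    for key, value in doc.items():
        canonical = by_slug.get(slugify(str(key)))
        if canonical is not None:
            meta.values[canonical] = value
        else:
            meta.extras[key] = value
    return meta


def dataset_records_to_json(dataset: Dataset, registry=None) -> str:
    """Serialize records as a JSON array of objects (blank cells omitted)."""
    if registry is None:
        registry = core_registry()
    out = []
    for rec in dataset.records:
        obj = {spec.name: getattr(rec, spec.slug)
               for spec in registry if getattr(rec, spec.slug) is not None}
        obj.update({k: v for k, v in rec.extras.items() if v != ""})
        out.append(obj)
    return json.dumps(out, indent=2, ensure_ascii=False) + "\n"


def dataset_from_json(source, registry=None):
    """Read records from a JSON array of objects (inverse of
    :func:`dataset_records_to_json`)."""
    if registry is None:
        registry = core_registry()
    text = _decode(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON: {exc.msg} at line {exc.lineno}") \
            from exc
    if not isinstance(doc, list):
        raise ParseError("records document must be a JSON array")
    by_slug = {spec.slug: spec for spec in registry}
    records, findings = [], []
    for i, obj in enumerate(doc, start=1):
        rec = DiseaseRecord(source_row=i)
        for key, value in obj.items():
            spec = by_slug.get(slugify(str(key)))
            if spec is None:
                rec.extras[str(key)] = value
            elif value is not None:
                setattr(rec, spec.slug, value)
        records.append(rec)
    return Dataset(records=records), findings
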