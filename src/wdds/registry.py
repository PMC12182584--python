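"""Machine-readable registry of the wildlife disease data standard.

The standard describes disaggregated wildlife disease surveillance data:
one row per diagnostic-test outcome, with 40 core fields split across three
categories (sampling context, host organism, parasite/test) of which 9 are
required, plus 24 project-level metadata properties (7 required) derived
from the DataCite metadata kernel.

This module is the single source of truth for field names, types,
requiredness, controlled vocabularies, Darwin Core equivalences and
units-pair dependencies.  Everything else in the package (parsing,
validation, template/schema emission, the Darwin Core crosswalk) is driven
by this registry.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = [
    "FieldSpec",
    "MetadataPropertySpec",
    "core_registry",
    "metadata_registry",
    "emit_json_schema",
    "emit_template",
    "emit_data_dictionary",
    "slugify",
    "DETECTION_OUTCOMES",
]

#: Closed vocabulary for a single diagnostic-test result.
DETECTION_OUTCOMES = ("positive", "negative", "inconclusive")

_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(name: str) -> str:
    """Lower-snake-case a printed field label ("Sample collection method"
    -> ``sample_collection_method``)."""
    return _SLUG_RE.sub("_", name.strip().lower()).strip("_")


@dataclass(frozen=True)
class FieldSpec:
    """One core field of the data standard.

    Parameters
    ----------
    name : str
        Canonical printed label, e.g. ``"Sample ID"``.
    category : str
        One of ``{"sampling", "host", "parasite"}``.
    value_kind : str
        One of ``{"text", "number", "integer", "boolean"}`` (JSON Schema
        primitive kinds).
    required : bool
        Whether the column must exist and, unless conditionally exempt,
        each cell must be non-blank.
    cell_required_when : str, optional
        Named predicate restricting the cell-level requirement; currently
        only ``"outcome_positive"`` (parasite identification is expected
        only for positive results, and its absence there is advisory).
    depends_on : str, optional
        Slug of a companion value field that makes this field mandatory
        whenever the companion is non-blank (units / measurement-axis
        pairings).
    dwc_equivalent : str, optional
        Darwin Core term this field maps onto.
    vocabulary : tuple of str, optional
        Closed value set, if any.
    description : str
        Data-dictionary prose.
    """

    name: str
    category: str
    value_kind: str
    required: bool = False
    cell_required_when: Optional[str] = None
    depends_on: Optional[str] = None
    dwc_equivalent: Optional[str] = None
    vocabulary: Optional[tuple] = None
    description: str = ""
    slug: str = field(default="", compare=True)

    def __post_init__(self):
        if not self.slug:
            object.__setattr__(self, "slug", slugify(self.name))


@dataclass(frozen=True)
class MetadataPropertySpec:
    """One project-level metadata property (DataCite-derived)."""

    name: str
    required: bool = False
    value_kind: str = "text"
    pid_kind: Optional[str] = None  # doi | orcid | ror | funder_id
    description: str = ""
    slug: str = field(default="")

    def __post_init__(self):
        if not self.slug:
            object.__setattr__(self, "slug", slugify(self.name))


_F = FieldSpec

_CORE_FIELDS: tuple = (
    # --- sampling (11) ---
    _F("Sample ID", "sampling", "text", required=True,
       description="Researcher-generated unique identifier for the sample, "
                   "usually mixing characters and integers so identifiers "
                   "stay unique when datasets are merged."),
    _F("Animal ID", "sampling", "text",
       description="Researcher-generated identifier for the individual animal "
                   "the sample came from. May be blank when animals are not "
                   "individually identified (e.g. pooled testing); a pooled "
                   "sample may list several identifiers separated by ';'."),
    _F("Latitude", "sampling", "number", required=True,
       dwc_equivalent="decimalLatitude",
       description="Latitude of the collection site in decimal degrees."),
    _F("Longitude", "sampling", "number", required=True,
       dwc_equivalent="decimalLongitude",
       description="Longitude of the collection site in decimal degrees."),
    _F("Spatial uncertainty", "sampling", "number",
       dwc_equivalent="coordinateUncertaintyInMeters",
       description="Coordinate uncertainty in meters, from GPS error, "
                   "digitization, or deliberate alteration such as rounding "
                   "or jittering."),
    _F("Collection day", "sampling", "integer", dwc_equivalent="day",
       description="Day of the month the specimen was collected."),
    _F("Collection month", "sampling", "integer", dwc_equivalent="month",
       description="Numeric month the specimen was collected."),
    _F("Collection year", "sampling", "integer", dwc_equivalent="year",
       description="Year the specimen was collected."),
    _F("Sample collection method", "sampling", "text", required=True,
       description="Technique used to acquire the sample (e.g. 'swab', "
                   "'wing punch', 'necropsy', 'visual inspection')."),
    _F("Sample collection body part", "sampling", "text",
       description="Part of the animal body the sample was collected from "
                   "(e.g. 'rectum', 'wing')."),
    _F("Sample material", "sampling", "text",
       description="Organic tissue or fluid collected (e.g. 'liver', "
                   "'blood', 'whole organism')."),
    # --- host (13) ---
    _F("Host identification", "host", "text", required=True,
       dwc_equivalent="scientificName",
       description="Linnaean classification of the sampled animal at the "
                   "lowest level possible, ideally a species binomial."),
    _F("Organism sex", "host", "text", dwc_equivalent="sex",
       description="Sex of the sampled animal."),
    _F("Live capture", "host", "boolean",
       description="Whether the animal was alive at the time of capture "
                   "(TRUE/FALSE); lethal sampling is recorded as TRUE."),
    _F("Host life stage", "host", "text", dwc_equivalent="lifeStage",
       description="Life stage of the sampled animal, as appropriate for "
                   "the organism (e.g. 'juvenile', 'adult')."),
    _F("Age", "host", "number",
       description="Numeric age of the animal at sample collection, if "
                   "known (e.g. in monitored populations)."),
    _F("Age units", "host", "text", depends_on="age",
       description="Units age is measured in (usually years). Must "
                   "accompany any age value."),
    _F("Mass", "host", "number",
       description="Mass of the animal at sample collection."),
    _F("Mass units", "host", "text", depends_on="mass",
       description="Units mass is recorded in (e.g. 'kg'). Must accompany "
                   "any mass value."),
    _F("Length", "host", "number",
       description="Numeric length of the animal at sample collection."),
    _F("Length measurement", "host", "text", depends_on="length",
       description="Axis of measurement (e.g. 'snout-vent length', 'wing "
                   "length'). Must accompany any length value."),
    _F("Length units", "host", "text", depends_on="length",
       description="Units length is recorded in (e.g. 'meters'). Must "
                   "accompany any length value."),
    _F("Organism quantity", "host", "number",
       dwc_equivalent="organismQuantity",
       description="Quantity of organisms, e.g. the number of individuals "
                   "contributing to a pooled sample."),
    _F("Organism quantity units", "host", "text",
       depends_on="organism_quantity",
       dwc_equivalent="organismQuantityType",
       description="Units organism quantity is recorded in (e.g. "
                   "'individuals', 'kg'). Must accompany any quantity."),
    # --- parasite (16) ---
    _F("Detection target", "parasite", "text", required=True,
       dwc_equivalent="associatedOccurrences",
       description="Taxonomic identity of the parasite being screened for, "
                   "often coarser than the parasite eventually identified "
                   "(e.g. a whole family for a PCR screen)."),
    _F("Detection method", "parasite", "text", required=True,
       description="Type of test performed to detect the parasite or "
                   "parasite-specific antibody (e.g. 'PCR', 'ELISA')."),
    _F("Forward primer sequence", "parasite", "text",
       description="Sequence of the forward primer used for detection, "
                   "where applicable (e.g. PCR)."),
    _F("Reverse primer sequence", "parasite", "text",
       description="Sequence of the reverse primer used for detection, "
                   "where applicable (e.g. PCR)."),
    _F("Gene target", "parasite", "text",
       description="Parasite gene targeted by the primers (e.g. 'RdRp')."),
    _F("Primer citation", "parasite", "text",
       description="Citation for the primers, ideally a DOI or other "
                   "persistent work identifier."),
    _F("Probe target", "parasite", "text",
       description="Antibody or antigen targeted for detection, where "
                   "applicable (e.g. ELISA)."),
    _F("Probe type", "parasite", "text",
       description="Antibody or antigen used for detection, where "
                   "applicable (e.g. ELISA)."),
    _F("Probe citation", "parasite", "text",
       description="Citation for the probes, ideally a DOI or other "
                   "persistent work identifier."),
    _F("Detection outcome", "parasite", "text", required=True,
       dwc_equivalent="occurrenceStatus",
       vocabulary=DETECTION_OUTCOMES,
       description="The test result: 'positive', 'negative', or "
                   "'inconclusive'. These strings are preferred over "
                   "numeric codes to avoid ambiguity. May be blank for "
                   "records of untested samples."),
    _F("Detection measurement", "parasite", "number",
       description="Any numeric measurement of detection more detailed "
                   "than positive/negative (e.g. viral titer, parasite "
                   "count, sequence reads)."),
    _F("Detection measurement units", "parasite", "text",
       description="Units for the quantitative detection measurement "
                   "(e.g. 'Ct', 'TCID50/mL', 'parasite count')."),
    _F("Parasite identification", "parasite", "text", required=True,
       cell_required_when="outcome_positive",
       description="Identity of a parasite detected by the test, if any, "
                   "at the lowest possible taxonomic level. Always blank "
                   "for negative test results; may be more specific than "
                   "the detection target."),
    _F("Parasite ID", "parasite", "text",
       description="Researcher-generated unique identifier for an "
                   "individual parasite; in nested designs this identifier "
                   "reappears as an Animal ID in another row (e.g. a flea "
                   "taken off a rat and itself tested)."),
    _F("Parasite life stage", "parasite", "text",
       description="Life stage of the detected parasite, as appropriate "
                   "for the organism."),
    _F("GenBank accession", "parasite", "text",
       dwc_equivalent="otherCatalogNumbers",
       description="GenBank accession for any parasite genetic sequence; "
                   "identifiers for other platforms belong in additional "
                   "fields."),
)

# 24 project-metadata properties, 7 required.  The composition follows the
# DataCite mandatory kernel plus generalist-repository recommendations; it
# is provisional (see docs/methods.md).
_M = MetadataPropertySpec
_METADATA_PROPERTIES: tuple = (
    _M("Title", required=True,
       description="Name of the dataset."),
    _M("Description", required=True,
       description="Written description of the data, intended use, and "
                   "known limitations (e.g. explanations of missing values "
                   "or any coordinate obfuscation applied)."),
    _M("Creators", required=True,
       description="People or organizations that produced the dataset."),
    _M("Creator ORCID", pid_kind="orcid",
       description="ORCID iD(s) of the creators."),
    _M("Creator affiliation",
       description="Institutional affiliation(s) of the creators."),
    _M("Affiliation ROR", pid_kind="ror",
       description="Research Organization Registry identifier(s) for the "
                   "creator affiliations."),
    _M("Publication year", required=True, value_kind="integer",
       description="Year the dataset was (or will be) made public."),
    _M("Publisher",
       description="Repository or platform holding the dataset."),
    _M("Resource type", required=True,
       description="General type of the resource (normally 'Dataset')."),
    _M("Identifier", required=True, pid_kind="doi",
       description="Persistent identifier of the dataset, normally a DOI."),
    _M("License", required=True,
       description="License under which the dataset is distributed."),
    _M("Subjects",
       description="Keywords or classification codes describing the "
                   "dataset."),
    _M("Language",
       description="Primary language of the dataset."),
    _M("Version",
       description="Version of the dataset."),
    _M("Funder name",
       description="Name(s) of the funding body."),
    _M("Funder identifier", pid_kind="funder_id",
       description="Persistent identifier of the funder (Crossref Funder "
                   "DOI or ROR)."),
    _M("Award number",
       description="Grant or award number(s)."),
    _M("Related identifier",
       description="Persistent identifier of a related work (e.g. the "
                   "paper describing the dataset)."),
    _M("Related identifier type",
       description="Type of the related identifier (e.g. 'DOI')."),
    _M("Relation type",
       description="Relationship of the dataset to the related work "
                   "(e.g. 'IsSupplementTo')."),
    _M("Contributors",
       description="People or organizations that contributed to the "
                   "dataset other than the creators."),
    _M("Contributor type",
       description="Role of each contributor (e.g. 'DataCurator')."),
    _M("Coverage dates",
       description="Temporal coverage of the sampling."),
    _M("Geographic coverage description",
       description="Prose description of the spatial coverage, useful when "
                   "coordinates are generalized for safety."),
)


def core_registry() -> tuple:
    """Return the 40 core field specs in standard (table) order."""
    return _CORE_FIELDS


def metadata_registry() -> tuple:
    """Return the 24 project-metadata property specs."""
    return _METADATA_PROPERTIES


def _field_schema(spec: FieldSpec) -> dict:
    kind = {"text": "string", "number": "number",
            "integer": "integer", "boolean": "boolean"}[spec.value_kind]
    # Unconditionally required cells must be non-null; everything else
    # (optional fields, and required fields with a conditional exemption)
    # admits null, i.e. a blank cell.
    unconditional = spec.required and spec.cell_required_when is None \
        and spec.slug not in ("detection_target", "detection_method",
                              "detection_outcome")
    if unconditional:
        sch: dict = {"type": kind}
    else:
        sch = {"type": [kind, "null"]}
    if spec.vocabulary is not None:
        enum = list(spec.vocabulary)
        if not unconditional:
            enum.append(None)
        sch["enum"] = enum
    sch["description"] = spec.description
    return sch


def emit_json_schema(registry=None) -> dict:
    """Emit a JSON Schema (draft 2020-12) for one record object.

    A record serializes as ``{slug: value}`` with blank cells as ``null``
    (see :func:`wdds.io.record_to_object`).  The ``required`` list carries
    all 9 required fields — presence of the key corresponds to presence of
    the column — while cell-level blankness rules are encoded in the
    per-property types and the untested-sample conditional: when the
    detection outcome is blank the record documents an untested sample and
    the detection target/method may be blank too.
    """
    if registry is None:
        registry = core_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    properties = {spec.slug: _field_schema(spec) for spec in registry}
    required = [spec.slug for spec in registry if spec.required]
    schema: dict = {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "Wildlife disease surveillance record",
        "type": "object",
        "properties": properties,
        "required": required,
        "additionalProperties": True,
    }
    slugs = {s.slug for s in registry}
    if {"detection_outcome", "detection_target", "detection_method"} <= slugs:
        # Tested record => target and method must be populated.
        schema["allOf"] = [{
            "if": {"properties": {"detection_outcome": {"type": "string"}},
                   "required": ["detection_outcome"]},
            "then": {"properties": {
                "detection_target": {"type": "string"},
                "detection_method": {"type": "string"},
            }},
        }]
    # Deliberately no range constraints: the schema expresses exactly the
    # required/vocabulary/type layer of the standard, so its accept/reject
    # decision coincides with the native validator restricted to those
    # rules; ranges, date plausibility and cross-field rules live in
    # wdds.validation.
    return schema


def emit_json_schema_text(registry=None) -> str:
    """Byte-stable serialized form of :func:`emit_json_schema`."""
    return json.dumps(emit_json_schema(registry), indent=2,
                      ensure_ascii=False, sort_keys=False) + "\n"


def emit_template(registry=None) -> str:
    """CSV template: one header row with the printed field names, no body."""
    if registry is None:
        registry = core_registry()
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([spec.name for spec in registry])
    return buf.getvalue()


def emit_data_dictionary(registry=None) -> pd.DataFrame:
    """Data dictionary: one row per field with name, type, requiredness,
    description, controlled vocabulary and Darwin Core term."""
    if registry is None:
        registry = core_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    rows = []
    for spec in registry:
        rows.append({
            "name": spec.name,
            "type": spec.value_kind,
            "required": spec.required,
            "description": spec.description,
            "vocabulary": "; ".join(spec.vocabulary) if spec.vocabulary else "",
            "darwin_core_term": spec.dwc_equivalent or "",
        })
    return pd.DataFrame(rows)
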