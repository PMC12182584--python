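"""Persistent-identifier (PID) syntax validation and project-metadata
checks.

Strong semantic links between a dataset, its creators, their institutions
and its funders are made with DOIs (works), ORCID iDs (people), ROR ids
(organizations) and Crossref Funder ids.  Validation here is purely
syntactic (ORCID includes its ISO 7064 mod 11-2 check digit); nothing is
resolved over the network.
"""

from __future__ import annotations

import re

from .report import ValidationIssue

__all__ = ["validate_doi", "validate_orcid", "validate_ror",
           "validate_funder_id", "orcid_check_digit", "validate_metadata"]

_DOI_RE = re.compile(r"^10\.\d{4,9}/\S+$")
# Crockford base32: digits + lowercase letters minus i, l, o, u.
_ROR_RE = re.compile(r"^0[0-9abcdefghjkmnpqrstvwxyz]{6}\d{2}$")
_ORCID_RE = re.compile(r"^\d{4}-\d{4}-\d{4}-\d{3}[\dX]$")


def _strip_scheme(s: str, *prefixes: str) -> str:
    s = s.strip()
    low = s.lower()
    for prefix in prefixes:
        if low.startswith(prefix):
            return s[len(prefix):]
    return s


def validate_doi(s: str) -> bool:
    """True iff ``s`` is a DOI: prefix ``10.``, a 4-9 digit registrant
    code, ``/``, and a non-empty suffix.  ``doi:`` and resolver-URL
    wrappers are stripped first."""
    if not isinstance(s, str):
        return False
    s = _strip_scheme(s, "https://doi.org/", "http://doi.org/",
                      "https://dx.doi.org/", "http://dx.doi.org/", "doi:")
    return bool(_DOI_RE.match(s.strip()))


def orcid_check_digit(base_digits: str) -> str:
    """ISO 7064 mod 11-2 check character over the 15 base digits of an
    ORCID iD ('X' encodes the value 10)."""
    total = 0
    for ch in base_digits:
        total = (total + int(ch)) * 2
    result = (12 - total % 11) % 11
    return "X" if result == 10 else str(result)


def validate_orcid(s: str) -> bool:
    """True iff ``s`` is a well-formed ORCID iD (4 hyphen-separated groups
    of 4, last character possibly X) whose check digit verifies."""
    if not isinstance(s, str):
        return False
    s = _strip_scheme(s, "https://orcid.org/", "http://orcid.org/")
    s = s.strip()
    if not _ORCID_RE.match(s):
        return False
    digits = s.replace("-", "")
    return orcid_check_digit(digits[:15]) == digits[15]


def validate_ror(s: str) -> bool:
    """True iff ``s`` is a well-formed ROR id: a leading ``0``, six
    Crockford base32 characters, and two digits.  The ``https://ror.org/``
    wrapper is stripped first.  (The trailing digits are a mod 97-10
    checksum in the registry; only syntax is checked here.)"""
    if not isinstance(s, str):
        return False
    s = _strip_scheme(s, "https://ror.org/", "http://ror.org/", "ror.org/")
    return bool(_ROR_RE.match(s.strip()))


def validate_funder_id(s: str) -> bool:
    """Funder identifiers are accepted as Crossref Funder DOIs
    (``10.13039/...``) or ROR ids."""
    if not isinstance(s, str):
        return False
    if validate_ror(s):
        return True
    stripped = _strip_scheme(s, "https://doi.org/", "http://doi.org/",
                             "doi:")
    return validate_doi(s) and stripped.strip().startswith("10.13039/")


_PID_CHECKS = {"doi": validate_doi, "orcid": validate_orcid,
               "ror": validate_ror, "funder_id": validate_funder_id}


def _blank(value) -> bool:
    return value is None or (isinstance(value, str) and not value.strip()) \
        or (isinstance(value, (list, tuple)) and len(value) == 0)


def validate_metadata(metadata, registry=None) -> list:
    """Check a project-metadata document against the metadata registry:
    missing required properties and malformed PIDs become issues mergeable
    into a dataset's validation report."""
    from .registry import metadata_registry
    if registry is None:
        registry = metadata_registry()
    issues: list = []

    def add(rule, field_, msg):
        issues.append(ValidationIssue(rule_id=rule, severity="error",
                                      record=None, field=field_,
                                      message=msg))

    for spec in registry:
        value = metadata.values.get(spec.name)
        if spec.required and _blank(value):
            add("REQ_FIELD", spec.slug,
                f"required metadata property {spec.name!r} is missing or "
                f"blank")
            continue
        if spec.pid_kind and not _blank(value):
            check = _PID_CHECKS[spec.pid_kind]
            values = value if isinstance(value, (list, tuple)) else [value]
            for v in values:
                if not check(str(v)):
                    add("PID_SYNTAX", spec.slug,
                        f"{spec.name!r} value {v!r} is not a valid "
                        f"{spec.pid_kind.upper().replace('_', ' ')}")

    for creator in metadata.creators():
        if creator.get("orcid") and not validate_orcid(creator["orcid"]):
            add("PID_SYNTAX", "creators",
                f"creator {creator.get('name')!r} has invalid ORCID "
                f"{creator['orcid']!r}")
        if creator.get("ror") and not validate_ror(creator["ror"]):
            add("PID_SYNTAX", "creators",
                f"creator {creator.get('name')!r} has invalid ROR "
                f"{creator['ror']!r}")
    for funder in metadata.funders():
        if funder.get("funder_id") and \
                not validate_funder_id(funder["funder_id"]):
            add("PID_SYNTAX", "funder_name",
                f"funder {funder.get('name')!r} has invalid identifier "
                f"{funder['funder_id']!r}")
    return issues
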