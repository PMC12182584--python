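"""Rule-tagged validation issues and reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["ValidationIssue", "ValidationReport", "RULES", "RULE_IDS"]

#: Closed registry of validation rules: rule_id -> (severity, rationale).
#: Severity policy: violations of an explicit requirement of the standard
#: are errors; departures from best-practice advice are warnings.
RULES = {
    "REQ_FIELD": ("error",
                  "a required field (or metadata property) is missing or "
                  "blank where the standard demands a value"),
    "FIELD_TYPE": ("error",
                   "a cell's value does not match the field's declared "
                   "kind (number, integer, boolean, text)"),
    "VOCAB": ("error",
              "a value falls outside a closed vocabulary, e.g. a detection "
              "outcome other than positive/negative/inconclusive"),
    "UNITS_PAIR": ("error",
                   "a measurement (age, mass, length, organism quantity) "
                   "is present without its units or measurement axis"),
    "COORD_RANGE": ("error",
                    "latitude outside [-90, 90], longitude outside "
                    "[-180, 180], or negative spatial uncertainty"),
    "DATE_VALID": ("error",
                   "collection day/month/year name an impossible calendar "
                   "date (partial dates are allowed)"),
    "PLACEHOLDER": ("warning",
                    "a placeholder was used where a blank cell is expected "
                    "(e.g. 'NA', or (0, 0) coordinates)"),
    "POS_NO_ID": ("warning",
                  "a positive test without a parasite identification"),
    "NEG_WITH_ID": ("error",
                    "a parasite identification on a negative test — the "
                    "identity cell must stay empty for negative results"),
    "XREC_CONFLICT": ("warning",
                      "rows sharing an animal identifier disagree on a "
                      "stable host attribute (identification or sex)"),
    "DUP_ROW": ("warning", "byte-identical duplicate rows"),
    "POOL_LINK": ("error",
                  "a pooled-sample link references a sample absent from "
                  "the dataset"),
    "NEST_CYCLE": ("error",
                   "nested parasite-of-parasite links form a cycle"),
    "PID_SYNTAX": ("error",
                   "a persistent identifier (DOI, ORCID, ROR, funder id) "
                   "is syntactically invalid"),
}

RULE_IDS = tuple(RULES)


@dataclass
class ValidationIssue:
    """One finding: a stable rule code, severity, an address (record row
    and/or field slug) and a human-readable message quoting the offending
    value."""

    rule_id: str
    severity: str  # "error" | "warning"
    record: Optional[int] = None  # 1-based source row, None for dataset-level
    field: Optional[str] = None
    message: str = ""

    def to_dict(self) -> dict:
        return {"rule_id": self.rule_id, "severity": self.severity,
                "record": self.record, "field": self.field,
                "message": self.message}

    def __str__(self) -> str:
        where = []
        if self.record is not None:
            where.append(f"row {self.record}")
        if self.field:
            where.append(self.field)
        loc = " @ ".join(where) if where else "dataset"
        return f"[{self.severity.upper()}] {self.rule_id} ({loc}): " \
               f"{self.message}"


@dataclass
class ValidationReport:
    """Ordered issues with tallies; a dataset is conformant iff it has
    zero error-severity issues."""

    issues: list = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity == "warning")

    @property
    def conformant(self) -> bool:
        return self.n_errors == 0

    def by_rule(self, rule_id: str) -> list:
        return [i for i in self.issues if i.rule_id == rule_id]

    def to_json(self) -> str:
        doc = {"conformant": self.conformant, "n_errors": self.n_errors,
               "n_warnings": self.n_warnings,
               "issues": [i.to_dict() for i in self.issues]}
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"

    def to_text(self) -> str:
        lines = [f"{len(self.issues)} issue(s): {self.n_errors} error(s), "
                 f"{self.n_warnings} warning(s); "
                 f"conformant={self.conformant}"]
        lines += [str(i) for i in self.issues]
        return "\n".join(lines) + "\n"
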