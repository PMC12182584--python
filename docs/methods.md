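# Methods and design notes

## The data model

The unit of observation is a single diagnostic-test outcome ("tidy"
disaggregated data): every row carries its own sampling context (where,
when, how), host information, and test/parasite information. Tests,
samples and animals are many-to-many — an animal can contribute several
samples, a sample can be tested several times, a pooled sample can
aggregate many animals, and a detected parasite (an ectoparasite with its
own identifier) can itself be sampled and tested. The registry fixes 40
core fields (11 sampling / 13 host / 16 parasite; 9 required) and 24
project-metadata properties (7 required).

Two fields are closed: the detection outcome
(`positive`/`negative`/`inconclusive`, matched case-insensitively) and
live capture (boolean). Everything else is open text by design — the
diversity of collection and assay methods defeats any single controlled
vocabulary, and a restrictive standard would simply not be adopted.

**Provisional metadata composition.** The 24-property metadata registry
follows the DataCite kernel (mandatory properties plus
generalist-repository recommendations): Title, Description, Creators,
Publication year, Resource type, Identifier and License are the seven
required properties. The exact published composition of the metadata
table is not available in machine-readable form, so this composition is
provisional and flagged as such here; the counts (24/7) are fixed.

## Requiredness semantics

"Required" is two-level: the column must exist, and cells must be
non-blank — with two principled exemptions.

- *Parasite identification* is a required column whose cells are
  intentionally blank for anything except what was actually detected:
  identity on a negative row is an error (`NEG_WITH_ID`), a positive row
  without identity only a warning (`POS_NO_ID`).
- *Untested samples.* A blank detection outcome marks a record of an
  animal/sample with no attached test (a legal record under the
  standard's flexibility provisions). For such rows the detection target
  and method are also exempt from the required-cell rule — otherwise an
  untested-sample row could never validate. This consistency choice is a
  package decision; the standard itself is silent on it.

Severity policy: rules contradicting an explicit requirement of the
standard are errors; best-practice departures (placeholders, duplicate
rows, (0, 0) coordinates, positive-without-identity, cross-record host
disagreements) are warnings, keeping "required" as minimal as the
standard intends. The (0, 0)-coordinate warning is a heuristic for a
common GIS placeholder ("null island") and is documented as such.

## Blank versus placeholder

Blank is a first-class state (`None` in memory, an empty cell on disk).
The tokens `NA`, `N/A`, `NAN`, `NULL`, `NONE`, `-`, `.`
(case-insensitive) are converted to blank at parse time and reported as
findings; they can never reach a typed slot, and the writer never emits
them. The dialect is CSV, UTF-8 (BOM tolerated), comma delimiter, period
decimal separator; the typographic minus (U+2212), as produced by
typesetting, is normalized to the ASCII hyphen before numeric parsing.
Unknown columns are preserved verbatim (the standard invites extension
fields), and the read/write pair is lossless on typed slots and extras.

## JSON Schema equivalence

The emitted JSON Schema (draft 2020-12) expresses exactly the
required/vocabulary/type layer of the standard: records serialize as
slug-keyed objects with blanks as `null`; the `required` list carries all
nine required fields (key presence ≙ column presence); unconditionally
required cells exclude `null`; the untested-sample exemption is an
`if/then` conditional on the outcome. Range rules, date plausibility and
all cross-field/cross-record rules are deliberately *not* in the schema,
so the schema's accept/reject decision coincides with the native
validator restricted to that layer — verified by fuzzing. One alignment
detail: JSON treats `23.0` as an integer, so the native type check
accepts integral floats in integer slots.

## Relationships

The link graph is typed (`record → sample → animal`, `parasite →
record`, and a `nests` edge whenever a parasite identifier is reused as
an animal identifier). The animal- and parasite-identifier namespaces
are treated as one shared space, because the standard explicitly reuses
parasite IDs as animal IDs for nested detections; an accidental
collision between an unrelated animal and parasite identifier is
undetectable and documented as a caveat. Nesting chains of any depth are
supported (the canonical illustration is one hop: rat → flea →
*Yersinia pestis*); a cycle in the nesting relation is impossible data
and is an error (`NEST_CYCLE`). Pooled samples support both encodings —
`;`-separated lists in the Animal ID cell, and a two-column
`sample_id,animal_id` side table; the side-table format is a package
convention, since the standard mentions "an additional file" without
specifying one. Graph construction is linear in the number of records
(checked empirically at 2×10³ vs 2×10⁴ records, sizes chosen to keep
the suite fast).

## Coordinate obfuscation

- **Truncation** is toward zero (not rounding, not floor), so a
  published value never implies precision beyond the retained decimals;
  the definition of "truncating" is a package choice. Implemented in
  decimal arithmetic on the shortest float representation to avoid
  binary-float edge cases (`trunc(0.29·100) == 28`).
- **Jitter** displaces each point uniformly on a disk of radius *R*
  (`r = R·√u`, θ uniform), converted to degrees with an equirectangular
  local approximation (111,320 m per degree of latitude); longitudes are
  wrapped at the antimeridian and records within 0.1° of a pole are
  skipped with a finding (the longitude conversion degenerates there).
  The approximation error stays below 0.5% of *R* for |φ| ≤ 60°, checked
  against the haversine distance (Earth radius 6,371,000 m).
- **Uncertainty propagation**: truncation raises the spatial-uncertainty
  field to at least the half-cell diagonal
  √((Δ·111320)² + (Δ·111320·cos φ)²), Δ = 0.5·10⁻ᵈ at the truncated
  latitude φ; jitter raises it to at least *R*. Uncertainty never
  decreases.
- **Provenance**: every obfuscation appends exactly one entry (method,
  parameters, timestamp). Jitter requires an explicit seed — no
  wall-clock entropy — so the data owner can reproduce the
  transformation while the published provenance omits the seed by
  default.

Neither operation provides a formal privacy guarantee (no k-anonymity or
differential privacy), and deciding *which* records are sensitive is out
of scope; the package documents residual risk rather than adjudicating
it.

## Synthetic data

The generator's defaults describe a plausible small field study: 100
animals, prevalence 0.1, a Belize-sized bounding box (16–18.5° N,
−89.2 to −87.8° E), sampling years 2018–2023, and 10% of records with
archival-style partial dates (blank day/month). Outcomes are i.i.d.
Bernoulli(prevalence) per test. Five designs cover the standard's
relationship topologies: `simple`, `multisample` (2–3 swabs per animal),
`multitest` (two targets per sample), `nested` (flea-on-rat with the
parasite ID reused as an animal ID; the generated chains are stored in
provenance as ground truth), and `pooled` (default pool size 25, half
the pools linked through the side table, half unidentified with only an
organism quantity). Species names come from a small built-in list of
real wildlife binomials; accession strings are deliberately
non-resolvable (`SYN` prefix) so no plausible archive identifiers are
fabricated. Identifiers follow a prefix+year+serial convention
(`SYN18-001`).

What the generator does *not* emulate: spatial autocorrelation of
infection, transmission dynamics, recapture structure, messy real-world
taxonomy, or encoding errors other than the seeded corruptions. Passing
the generator-closure and mutation tests therefore demonstrates the
validator's rule logic and the I/O contract, not robustness to every
real dataset.

`corrupt(dataset, rule_id, seed)` plants one minimal seeded violation
per rule (e.g. blanking a mass unit, `detected` as an outcome, a
dangling pool link, a parasite-of-parasite cycle) and errors explicitly
when a dataset has no eligible record — the mutation-testing harness
asserts a 100% kill rate with no collateral rule firing.

## PID validation

DOI: `10.` + 4–9-digit registrant + `/` + non-empty suffix, with
`doi:`/resolver-URL wrappers stripped. ORCID: format plus the ISO 7064
mod 11-2 check digit over the 15 base digits (tested against an
independent oracle implementation on 10⁴ random candidates). ROR:
leading `0`, six Crockford base32 characters, two digits — syntax only;
the registry's mod 97-10 checksum on the trailing digits is not
verified, since the practice being supported is *using* PIDs, not
registry-grade verification. Funder identifiers accept Crossref Funder
DOIs (`10.13039/…`) or ROR ids. Nothing is resolved over the network.

## Darwin Core export

Host-centric: each exported row is the host organism occurrence
(`scientificName` ≙ host identification, per the standard's own term
annotations), with parasite evidence in `associatedOccurrences` (the
detection target) and `occurrenceStatus` (`positive → present`,
`negative → absent`, `inconclusive → blank` — blank rather than
`doubtful` to avoid overclaiming). The parasite-centric convention also
exists in the wild; this choice is prominently documented because both
are defensible. `eventDate` composes ISO 8601 partial dates
(`YYYY`, `YYYY-MM`, `YYYY-MM-DD`); a day without a month is dropped
with a finding. Unmapped fields are appended verbatim as
`wdds:`-prefixed extension columns, making the export lossless. No
Darwin Core Archive (`meta.xml`) packaging is attempted.

## Problem sizes and tolerances

The test suite and the acceptance script use: 10⁴ records for jitter
bounds and the radial KS test (α = 0.01 against the closed-form CDF
r²/R²), 10⁴ random candidates for the ORCID oracle, 10³ fuzzed records
for schema equivalence, 50 random configurations for generator closure,
and 5 seeds × 10⁴ records for prevalence recovery (tolerance 0.01).
Truncation uncertainty must match its closed form to 1×10⁻⁶ relative.
These sizes are the package's own choice of statistical resolution;
all stochastic tests run on fixed seeds.

## Known limitations

- Taxonomic names are not checked against any backbone (GBIF/NCBI), and
  GenBank accessions are not format- or existence-checked.
- The metadata composition is provisional (above).
- Identifier-namespace collisions between unrelated animals and
  parasites are undetectable.
- Obfuscation documents, but cannot guarantee, protection against
  re-identification.
- Only UTF-8 (±BOM) CSV is read; no XLSX, TSV, or encoding detection.
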