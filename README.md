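# wdds

A validating toolkit for a **minimum wildlife disease data standard**:
disaggregated surveillance data where **one row is one diagnostic-test
outcome**, with its sampling context, host animal, and parasite/test
information.

Wildlife disease datasets are routinely shared only as summary prevalence
tables — often positives-only — which cannot be disaggregated back to the
individual host, compared across populations, or aggregated across
studies. The standard implemented here fixes the unit of observation at
the single test result and defines:

- **40 core fields** (11 sampling, 13 host, 16 parasite), **9 required**
  (Sample ID, Latitude, Longitude, Sample collection method, Host
  identification, Detection target, Detection method, Detection outcome,
  Parasite identification);
- **24 project-metadata properties** (7 required), derived from the
  DataCite metadata kernel, with persistent identifiers (DOI, ORCID, ROR,
  Crossref Funder ID) validated syntactically;
- a closed vocabulary for the test result — `positive` / `negative` /
  `inconclusive` — with everything else deliberately open text;
- blank cells as the only representation of "no value" (placeholders such
  as `NA` are parse-time findings, never data);
- Darwin Core equivalences for 14 fields, enabling biodiversity-platform
  interoperability.

The package provides, on top of a machine-readable registry of the
standard:

| area | what it does |
|---|---|
| `wdds.registry` | field/metadata registries; JSON Schema (2020-12), CSV template and data-dictionary emission |
| `wdds.io` | standard CSV/JSON reading and writing (UTF-8, period decimal, typographic-minus normalization, extras preserved, lossless round trip) |
| `wdds.validation` | rule-based validator with stable rule codes, record/field addresses and an error/warning severity policy |
| `wdds.pids` | DOI / ORCID (ISO 7064 mod 11-2 check digit) / ROR / funder-id syntax validation, metadata conformance |
| `wdds.relationships` | sample–animal–test link graph, nested detections (a flea off a rat, itself tested), pooled-sample summaries |
| `wdds.crosswalk` | Darwin Core occurrence export (host-centric; `positive → present`, `negative → absent`) |
| `wdds.obfuscation` | documented coordinate truncation and seeded uniform-disk jitter with uncertainty propagation and provenance |
| `wdds.synthetic` | conformant synthetic datasets across five sample/animal/test designs, plus seeded rule corruptions for mutation-testing the validator |
| `wdds.cli` | `wdds validate / template / dictionary / schema / export-dwc / obfuscate / simulate / convert` with a stable exit-code contract (0 ok, 1 warnings under `--strict`, 2 errors, 3 unreadable input) |

## Worked example

The package ships a transcription of a published two-record example
dataset: one vampire bat (*Desmodus rotundus*) sampled in Belize in April
2019, whose oral swab tested positive for a novel alphacoronavirus
(GenBank OM240578) and whose rectal swab tested negative.

```python
from wdds import (table4_fixture, validate_dataset, to_darwin_core,
                  truncate_coordinates)

ds = table4_fixture()
print(validate_dataset(ds).to_text())
# 0 issue(s): 0 error(s), 0 warning(s); conformant=True
```

The dataset is conformant: the negative row's blank parasite
identification is required to stay blank — identity is only reported for
what was actually detected.

```python
table, _ = to_darwin_core(ds)
print(table[["occurrenceID", "eventDate", "scientificName",
             "occurrenceStatus", "otherCatalogNumbers"]].to_string(index=False))
#             occurrenceID  eventDate    scientificName occurrenceStatus otherCatalogNumbers
# OS BZ19-95|Coronaviridae 2019-04-23 Desmodus rotundus          present            OM240578
# RS BZ19-95|Coronaviridae 2019-04-23 Desmodus rotundus           absent                None
```

Each exported row is the *host* occurrence with the test evidence mapped
onto `occurrenceStatus`; the positive/negative pair becomes
present/absent at the same place and date.

```python
obf, _ = truncate_coordinates(ds, 2)
r = obf.records[0]
print(r.latitude, r.longitude, round(r.spatial_uncertainty, 1))
# 17.76 -88.65 768.6
```

Truncating to two decimals coarsens the roost location (17.7643 →
17.76) and, because obfuscation must be documented rather than silent,
raises the spatial-uncertainty field to the half-cell diagonal (≈769 m
at this latitude) and appends a provenance entry.

From the shell:

```sh
wdds template -o template.csv       # 40-column header
wdds validate mydata.csv --strict   # exit code 0/1/2/3
wdds simulate --design pooled --n 500 --prevalence 0.1 --seed 42 -o sim.csv
wdds obfuscate mydata.csv --jitter 1000 --seed 7 -o shared.csv
```

## Layout

```
src/wdds/          library (registry, io, validation, pids,
                   relationships, crosswalk, obfuscation, synthetic, cli)
src/wdds/data/     packaged worked example + illustrative metadata
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, conventions, parameter choices, limitations
```
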