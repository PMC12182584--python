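"""Synthetic surveillance-data generation and seeded corruption.

The generator emits standard-conformant datasets across the five common
relationship designs between tests, samples and animals:

``simple``
    one animal, one sample, one test;
``multisample``
    several samples per animal (e.g. oral and rectal swabs);
``multitest``
    one sample screened for several targets;
``nested``
    ectoparasites detected on hosts are themselves tested, the parasite
    identifier reappearing as an animal identifier;
``pooled``
    many animals pooled into one tested sample, half the pools linked to
    per-animal identifiers through a side table, half unidentified.

Test outcomes are i.i.d. Bernoulli draws at the configured prevalence.
:func:`corrupt` plants a single, minimal, seeded violation of a chosen
validation rule into a conformant dataset — the mutation-testing harness
for the validator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io import Dataset, DiseaseRecord, ProjectMetadata, ProvenanceEntry, \
    read_csv, read_metadata
from .pids import orcid_check_digit
from .report import RULE_IDS

__all__ = ["SyntheticConfig", "generate", "corrupt", "table4_fixture",
           "example_metadata", "CorruptionError", "DESIGNS"]

DESIGNS = ("simple", "multisample", "multitest", "nested", "pooled")

_DEFAULT_SPECIES = (
    "Desmodus rotundus", "Artibeus jamaicensis", "Carollia perspicillata",
    "Odocoileus virginianus", "Rattus rattus", "Myotis lucifugus",
)


class CorruptionError(ValueError):
    """The requested rule cannot be violated on this dataset (no eligible
    record)."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic surveillance dataset.

    Defaults describe a plausible small field study: a hundred animals in
    a Belize-sized bounding box sampled over 2018-2023, a 10% test
    prevalence, and one in ten records with incomplete (archival-style)
    dates.
    """

    n_animals: int = 100
    design: str = "simple"
    prevalence: float = 0.1
    samples_per_animal: tuple = (2, 3)  # inclusive range, multisample
    tests_per_sample: int = 2           # multitest
    pool_size: int = 25                 # pooled
    species_pool: tuple = _DEFAULT_SPECIES
    target: str = "Coronaviridae"
    secondary_target: str = "Paramyxoviridae"
    bbox: tuple = (16.0, 18.5, -89.2, -87.8)  # lat min/max, lon min/max
    year_range: tuple = (2018, 2023)
    partial_date_fraction: float = 0.1
    with_metadata: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; "
                             f"expected one of {DESIGNS}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.n_animals < 1 or self.tests_per_sample < 1 or \
                self.pool_size < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.samples_per_animal
        if not 1 <= lo <= hi:
            raise ValueError("samples_per_animal must be a valid range")
        lat0, lat1, lon0, lon1 = self.bbox
        if not (-90 <= lat0 < lat1 <= 90 and -180 <= lon0 < lon1 <= 180):
            raise ValueError("bbox outside valid coordinate ranges")
        if not self.species_pool:
            raise ValueError("species_pool must be non-empty")


def _accession(rng) -> str:
    # Deliberately non-resolvable: 'SYN' prefix, never a plausible real id.
    return "SYN" + "".join(str(rng.integers(0, 10)) for _ in range(6))


def _outcome(rng, prevalence: float) -> str:
    return "positive" if rng.random() < prevalence else "negative"


def _base_record(rng, cfg: SyntheticConfig, animal_serial: int,
                 species: str):
    lat0, lat1, lon0, lon1 = cfg.bbox
    y0, y1 = cfg.year_range
    year = int(rng.integers(y0, y1 + 1))
    rec = DiseaseRecord(
        latitude=round(float(rng.uniform(lat0, lat1)), 4),
        longitude=round(float(rng.uniform(lon0, lon1)), 4),
        collection_year=year,
        sample_collection_method="swab",
        host_identification=species,
        organism_sex=str(rng.choice(("male", "female"))),
        live_capture=True,
        host_life_stage=str(rng.choice(("juvenile", "subadult", "adult"))),
        detection_method="qPCR",
        gene_target="RdRp",
        primer_citation="10.3390/v9120364",
    )
    if rng.random() >= cfg.partial_date_fraction:
        rec.collection_month = int(rng.integers(1, 13))
        rec.collection_day = int(rng.integers(1, 29))
    return rec


def _apply_outcome(rec, rng, cfg: SyntheticConfig, target: str):
    rec.detection_target = target
    rec.detection_outcome = _outcome(rng, cfg.prevalence)
    if rec.detection_outcome == "positive":
        rec.parasite_identification = f"{target[:-1]}us sp." \
            if target.endswith("ae") else f"{target} sp."
        rec.genbank_accession = _accession(rng)


def generate(config: SyntheticConfig) -> Dataset:
    """Generate a conformant synthetic dataset for the configured design.

    Deterministic under ``config.seed``.  The design, the configuration,
    and (for the nested design) the true host-to-ectoparasite chains are
    recorded in the dataset's provenance entry, which serves as ground
    truth for link-recovery checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    yy = config.year_range[0] % 100
    records: list = []
    pooled_links = None
    truth: dict = {}

    def animal_id(i: int) -> str:
        return f"SYN{yy:02d}-{i + 1:03d}"

    if config.design in ("simple", "multisample", "multitest"):
        swab_codes = ("OS", "RS", "BS", "WS")
        for i in range(config.n_animals):
            species = str(rng.choice(config.species_pool))
            aid = animal_id(i)
            if config.design == "multisample":
                lo, hi = config.samples_per_animal
                n_samples = int(rng.integers(lo, hi + 1))
            else:
                n_samples = 1
            base = _base_record(rng, config, i, species)
            base.mass = round(float(rng.uniform(0.01, 0.08)), 3)
            base.mass_units = "kg"
            for s in range(n_samples):
                sid = f"{swab_codes[s % len(swab_codes)]} {aid}"
                n_tests = (config.tests_per_sample
                           if config.design == "multitest" else 1)
                for t in range(n_tests):
                    rec = copy.deepcopy(base)
                    rec.sample_id = sid
                    rec.animal_id = aid
                    rec.sample_collection_body_part = \
                        {"OS": "mouth", "RS": "rectum"}.get(sid[:2])
                    target = (config.secondary_target if t % 2 else
                              config.target)
                    _apply_outcome(rec, rng, config, target)
                    records.append(rec)
    elif config.design == "nested":
        chains = []
        for i in range(config.n_animals):
            aid = animal_id(i)
            host = _base_record(rng, config, i, "Rattus rattus")
            host.sample_id = f"WS {aid}"
            host.animal_id = aid
            host.sample_collection_method = "visual inspection"
            host.sample_material = "whole organism"
            host.detection_method = "dissection"
            host.gene_target = None
            host.primer_citation = None
            host.detection_target = "Siphonaptera"
            host.detection_outcome = _outcome(rng, config.prevalence)
            if host.detection_outcome == "positive":
                ect_id = f"ECT{yy:02d}-{i + 1:03d}"
                host.parasite_identification = "Ctenocephalides felis"
                host.parasite_id = ect_id
                host.parasite_life_stage = "adult"
                child = _base_record(rng, config, i,
                                     "Ctenocephalides felis")
                child.latitude = host.latitude
                child.longitude = host.longitude
                child.sample_id = f"HS {ect_id}"
                child.animal_id = ect_id
                child.sample_collection_method = "homogenization"
                child.sample_material = "whole organism"
                _apply_outcome(child, rng, config, "Yersinia pestis")
                if child.detection_outcome == "positive":
                    child.parasite_identification = "Yersinia pestis"
                records.append(host)
                records.append(child)
                chains.append([aid, ect_id])
            else:
                records.append(host)
        truth["chains"] = chains
    elif config.design == "pooled":
        pooled_links = []
        n_pools = max(1, config.n_animals // config.pool_size)
        serial = 0
        for p in range(n_pools):
            rec = _base_record(rng, config, p, "Culex quinquefasciatus")
            sid = f"POOL SYN{yy:02d}-{p + 1:03d}"
            rec.sample_id = sid
            rec.sample_collection_method = "CDC light trap"
            rec.sample_material = "whole organism"
            rec.organism_quantity = float(config.pool_size)
            rec.organism_quantity_units = "individuals"
            _apply_outcome(rec, rng, config, "Flavivirus")
            if p % 2 == 0:
                # identified pool: members listed in the side table
                for _ in range(config.pool_size):
                    pooled_links.append((sid, animal_id(serial)))
                    serial += 1
            records.append(rec)

    for i, rec in enumerate(records, start=2):
        rec.source_row = i

    metadata = example_metadata() if config.with_metadata else None
    dataset = Dataset(records=records, metadata=metadata,
                      pooled_links=pooled_links)
    params = {"design": config.design, "n_animals": config.n_animals,
              "prevalence": config.prevalence, "seed": config.seed}
    params.update(truth)
    dataset.provenance.append(ProvenanceEntry.now("generate", params))
    return dataset


# ---------------------------------------------------------------------------
# seeded corruption (validator mutation testing)

def _pick(rng, items):
    if not items:
        return None
    return items[int(rng.integers(0, len(items)))]


def corrupt(dataset: Dataset, rule_id: str, seed: int) -> Dataset:
    """Return a copy of a conformant dataset with one minimal, seeded
    edit that violates exactly the targeted validation rule.

    Raises
    ------
    CorruptionError
        When no record in the dataset is eligible for the rule (e.g.
        a cross-record conflict needs an animal with several records).
    ValueError
        When ``rule_id`` is not in the rule registry.
    """
    if rule_id not in RULE_IDS:
        raise ValueError(f"unknown rule_id {rule_id!r}")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(dataset)
    recs = out.records

    if rule_id == "REQ_FIELD":
        rec = _pick(rng, recs)
        if rec is None:
            raise CorruptionError("empty dataset")
        rec.host_identification = None
    elif rule_id == "FIELD_TYPE":
        rec = _pick(rng, recs)
        if rec is None:
            raise CorruptionError("empty dataset")
        rec.latitude = "seventeen point eight"
    elif rule_id == "VOCAB":
        rec = _pick(rng, [r for r in recs
                          if r.detection_outcome is not None])
        if rec is None:
            raise CorruptionError("no tested record to corrupt")
        rec.detection_outcome = "detected"
        rec.parasite_identification = None
        rec.genbank_accession = None
    elif rule_id == "UNITS_PAIR":
        rec = _pick(rng, [r for r in recs if r.mass is not None])
        if rec is None:
            rec = _pick(rng, recs)
            if rec is None:
                raise CorruptionError("empty dataset")
            rec.mass = 0.5
        rec.mass_units = None
    elif rule_id == "COORD_RANGE":
        rec = _pick(rng, recs)
        if rec is None:
            raise CorruptionError("empty dataset")
        rec.latitude = 91.0
    elif rule_id == "DATE_VALID":
        rec = _pick(rng, [r for r in recs
                          if r.collection_year is not None])
        if rec is None:
            raise CorruptionError("no dated record to corrupt")
        rec.collection_day, rec.collection_month = 30, 2
    elif rule_id == "PLACEHOLDER":
        rec = _pick(rng, recs)
        if rec is None:
            raise CorruptionError("empty dataset")
        rec.latitude, rec.longitude = 0.0, 0.0
    elif rule_id == "POS_NO_ID":
        rec = _pick(rng, [r for r in recs
                          if r.detection_outcome == "positive"])
        if rec is None:
            raise CorruptionError("no positive record to corrupt")
        rec.parasite_identification = None
    elif rule_id == "NEG_WITH_ID":
        rec = _pick(rng, [r for r in recs
                          if r.detection_outcome == "negative"])
        if rec is None:
            raise CorruptionError("no negative record to corrupt")
        rec.parasite_identification = "Parasitus suspectus"
    elif rule_id == "XREC_CONFLICT":
        by_animal: dict = {}
        for r in recs:
            if r.animal_id is not None and ";" not in r.animal_id:
                by_animal.setdefault(r.animal_id, []).append(r)
        groups = [g for g in by_animal.values() if len(g) > 1]
        group = _pick(rng, groups)
        if group is None:
            raise CorruptionError("no animal with multiple records")
        rec = group[-1]
        rec.organism_sex = ("female" if rec.organism_sex == "male"
                            else "male")
    elif rule_id == "DUP_ROW":
        rec = _pick(rng, recs)
        if rec is None:
            raise CorruptionError("empty dataset")
        dup = copy.deepcopy(rec)
        dup.source_row = (recs[-1].source_row or len(recs) + 1) + 1
        recs.append(dup)
    elif rule_id == "POOL_LINK":
        if out.pooled_links is None:
            out.pooled_links = []
        out.pooled_links.append(("NO-SUCH-SAMPLE",
                                 f"SYN00-{int(rng.integers(0, 999)):03d}"))
    elif rule_id == "NEST_CYCLE":
        hosts = [r for r in recs if r.parasite_id is not None and
                 r.animal_id is not None]
        animal_ids = {a for r in recs for a in r.animal_ids()}
        hosts = [r for r in hosts if r.parasite_id in animal_ids]
        host = _pick(rng, hosts)
        if host is None:
            raise CorruptionError("no nested detection to corrupt")
        children = [r for r in recs if r.animal_id == host.parasite_id]
        children[-1].parasite_id = host.animal_id
    elif rule_id == "PID_SYNTAX":
        if out.metadata is None:
            raise CorruptionError("dataset has no project metadata")
        out.metadata.values["Identifier"] = "not-a-doi"
    else:  # pragma: no cover
        raise CorruptionError(f"no corruption defined for {rule_id}")
    return out


# ---------------------------------------------------------------------------
# packaged worked example

def table4_fixture() -> Dataset:
    """The packaged worked example: one vampire bat (Desmodus rotundus)
    sampled in Belize in April 2019, an oral swab positive for a novel
    alphacoronavirus and a rectal swab negative — two records, one animal,
    transcribed from the published example table (including its
    typographic minus in the longitude)."""
    source = resources.files("wdds.data").joinpath("worked_example.csv")
    dataset, findings = read_csv(source.read_bytes())
    assert not findings, "packaged fixture must parse cleanly"
    return dataset


def example_metadata() -> ProjectMetadata:
    """Packaged illustrative project-metadata document (synthetic: the
    identifiers use documented example/test PIDs)."""
    source = resources.files("wdds.data").joinpath("example_metadata.json")
    return read_metadata(source.read_bytes())
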