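"""Shared builders for hand-crafted records in the test suite."""

from wdds.io import DiseaseRecord


def make_record(**over) -> DiseaseRecord:
    """A minimal conformant record (negative qPCR test of a rat), with
    keyword overrides for seeding specific violations."""
    base = dict(sample_id="S1", animal_id="A1", latitude=10.0,
                longitude=-60.0, sample_collection_method="swab",
                host_identification="Rattus rattus",
                detection_target="Coronaviridae", detection_method="PCR",
                detection_outcome="negative", source_row=2)
    base.update(over)
    return DiseaseRecord(**base)
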