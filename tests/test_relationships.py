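"""Link topology: sample/animal/test graphs, nested detections, pooled
samples."""

import time

import pytest

from helpers import make_record

from wdds import build_link_graph, nested_chains, pool_summary, \
    validate_dataset
from wdds.relationships import NestingCycleError, graph_to_edge_csv
from wdds.synthetic import SyntheticConfig, generate
from wdds.validation import validate_dataset as _validate
from wdds.io import Dataset


def rat_flea_dataset() -> Dataset:
    """A rat carries a flea; the flea itself tests positive for plague."""
    rat = make_record(sample_id="WS RAT1", animal_id="RAT1",
                      detection_target="Siphonaptera",
                      detection_method="visual inspection",
                      detection_outcome="positive",
                      parasite_identification="Ctenocephalides felis",
                      parasite_id="FLEA1", source_row=2)
    flea = make_record(sample_id="HS FLEA1", animal_id="FLEA1",
                       host_identification="Ctenocephalides felis",
                       detection_target="Yersinia pestis",
                       detection_outcome="positive",
                       parasite_identification="Yersinia pestis",
                       source_row=3)
    return Dataset(records=[rat, flea])


def node_counts(graph):
    counts: dict = {}
    for _, kind in graph.nodes(data="kind"):
        counts[kind] = counts.get(kind, 0) + 1
    return counts


class TestLinkGraph:
    def test_worked_example_topology(self, fixture_dataset):
        g = build_link_graph(fixture_dataset)
        counts = node_counts(g)
        assert counts["sample"] == 2
        assert counts["animal"] == 1
        test_edges = [e for *e_, k in g.edges(data="kind") if k == "tests"
                      for e in [e_]]
        assert len(test_edges) == 2

    def test_rat_flea_nesting_edge(self):
        g = build_link_graph(rat_flea_dataset())
        nest_edges = [(u, v) for u, v, k in g.edges(data="kind")
                      if k == "nests"]
        assert nest_edges == [(("parasite", "FLEA1"), ("animal", "FLEA1"))]

    def test_empty_dataset_empty_graph(self):
        g = build_link_graph(Dataset())
        assert len(g) == 0

    def test_node_counts_invariant_under_reordering(self, simple_dataset):
        forward = build_link_graph(simple_dataset)
        reordered = Dataset(records=list(reversed(simple_dataset.records)),
                            pooled_links=simple_dataset.pooled_links)
        backward = build_link_graph(reordered)
        assert node_counts(forward) == node_counts(backward)
        assert forward.number_of_edges() == backward.number_of_edges()

    def test_edge_csv_export(self):
        text = graph_to_edge_csv(build_link_graph(rat_flea_dataset()))
        assert text.splitlines()[0] == \
            "source_type,source_id,target_type,target_id,kind"
        assert any("nests" in line for line in text.splitlines())

    def test_build_time_scales_roughly_linearly(self):
        small = generate(SyntheticConfig(n_animals=2000, seed=3))
        large = generate(SyntheticConfig(n_animals=20000, seed=3))
        build_link_graph(small)  # warm-up

        def best_of(dataset, repeats=3):
            times = []
            for _ in range(repeats):
                t0 = time.perf_counter()
                build_link_graph(dataset)
                times.append(time.perf_counter() - t0)
            return min(times)

        t_small = best_of(small)
        t_large = best_of(large)
        # 10x the records should cost far less than a quadratic blowup
        # (100x); generous slack absorbs scheduler noise
        assert t_large < 50 * max(t_small, 1e-3)


class TestNestedChains:
    def test_rat_flea_single_chain(self):
        assert nested_chains(rat_flea_dataset()) == [["RAT1", "FLEA1"]]

    def test_two_level_chain(self):
        ds = rat_flea_dataset()
        # the flea record detects a parasite individual that is itself
        # sampled as an "animal" in a third row
        ds.records[1].parasite_id = "MITE1"
        ds.records.append(make_record(
            sample_id="HS MITE1", animal_id="MITE1",
            host_identification="Acari", source_row=4))
        assert nested_chains(ds) == [["RAT1", "FLEA1", "MITE1"]]

    def test_cycle_raises_and_validates_as_error(self):
        ds = rat_flea_dataset()
        ds.records[1].parasite_id = "RAT1"  # flea's parasite is the rat
        with pytest.raises(NestingCycleError):
            nested_chains(ds)
        report = validate_dataset(ds)
        assert report.by_rule("NEST_CYCLE")
        assert not report.conformant

    def test_generator_truth_chains_recovered_exactly(self):
        ds = generate(SyntheticConfig(design="nested", n_animals=40,
                                      prevalence=0.5, seed=23))
        truth = ds.provenance[0].parameters["chains"]
        assert truth  # the draw produced at least one chain
        assert sorted(nested_chains(ds)) == sorted(truth)


class TestPoolSummary:
    def test_unidentified_pool(self):
        rec = make_record(sample_id="P1", animal_id=None,
                          organism_quantity=30.0,
                          organism_quantity_units="individuals")
        row = pool_summary(Dataset(records=[rec])).iloc[0]
        assert row["n_linked_animals"] == 0
        assert bool(row["unidentified"]) and bool(row["pooled"])

    def test_semicolon_list_expansion(self):
        rec = make_record(sample_id="P2", animal_id="M1;M2;M3")
        row = pool_summary(Dataset(records=[rec])).iloc[0]
        assert row["n_linked_animals"] == 3
        assert not row["unidentified"]

    def test_side_table_links_counted(self):
        rec = make_record(sample_id="P3", animal_id=None,
                          organism_quantity=2.0,
                          organism_quantity_units="individuals")
        ds = Dataset(records=[rec], pooled_links=[("P3", "M1"),
                                                  ("P3", "M2")])
        row = pool_summary(ds).iloc[0]
        assert row["n_linked_animals"] == 2
        assert not row["unidentified"]

    def test_worked_example_not_pooled(self, fixture_dataset):
        table = pool_summary(fixture_dataset)
        assert list(table["n_linked_animals"]) == [1, 1]
        assert not table["pooled"].any()

    def test_pooled_design_validates_and_summarizes(self):
        ds = generate(SyntheticConfig(design="pooled", n_animals=100,
                                      pool_size=25, prevalence=0.3,
                                      seed=5))
        assert _validate(ds).conformant
        table = pool_summary(ds)
        assert len(table) == 4
        assert sorted(table["n_linked_animals"]) == [0, 0, 25, 25]
        assert list(table["unidentified"]) == \
            [not n for n in table["n_linked_animals"]]
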