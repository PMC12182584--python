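"""Sample/animal/test link topology.

A surveillance dataset is a small typed graph: samples are collected from
animals (possibly many, for pooled samples), records test samples, and
detected parasites can themselves be sampled and tested ("nested
detections": a flea taken off a rat is itself screened, its parasite
identifier reappearing as an animal identifier in another row).  This
module materializes that graph, recovers nesting chains, and summarizes
pooled samples.
"""

from __future__ import annotations

import csv
import io as _io

import networkx as nx
import pandas as pd

from .io import Dataset

__all__ = ["build_link_graph", "nested_chains", "pool_summary",
           "find_nesting_cycles", "NestingCycleError", "graph_to_edge_csv"]


class NestingCycleError(ValueError):
    """Nesting edges (parasite-of-parasite) form a cycle."""

    def __init__(self, cycles):
        self.cycles = cycles
        super().__init__(f"nested detections form {len(cycles)} cycle(s): "
                         + "; ".join(" -> ".join(c) for c in cycles))


def _pool_side_links(dataset: Dataset) -> dict:
    links: dict = {}
    for sample_id, animal_id in dataset.pooled_links or []:
        links.setdefault(sample_id, []).append(animal_id)
    return links


def build_link_graph(dataset: Dataset) -> nx.DiGraph:
    """Build the typed link graph of a dataset.

    Nodes are ``("sample", id)``, ``("animal", id)``, ``("record", row)``
    and ``("parasite", id)``; edges carry a ``kind`` attribute:
    ``collected_from`` (sample -> animal), ``tests`` (record -> sample),
    ``detected_in`` (parasite -> record) and ``nests`` (parasite ->
    animal node of the same identifier, when a parasite id is reused as
    an animal id).
    """
    g = nx.DiGraph()
    side_links = _pool_side_links(dataset)
    animal_ids = set()
    for rec in dataset.records:
        for aid in rec.animal_ids():
            animal_ids.add(aid)
        if rec.sample_id is not None:
            for aid in side_links.get(rec.sample_id, []):
                animal_ids.add(aid)
    for rec in dataset.records:
        rec_node = ("record", rec.source_row)
        g.add_node(rec_node, kind="record")
        if rec.sample_id is not None:
            sample_node = ("sample", rec.sample_id)
            g.add_node(sample_node, kind="sample")
            g.add_edge(rec_node, sample_node, kind="tests")
            linked = rec.animal_ids() + side_links.get(rec.sample_id, [])
            for aid in dict.fromkeys(linked):
                g.add_node(("animal", aid), kind="animal")
                g.add_edge(sample_node, ("animal", aid),
                           kind="collected_from")
        if rec.parasite_id is not None:
            pid = rec.parasite_id
            g.add_node(("parasite", pid), kind="parasite")
            g.add_edge(("parasite", pid), rec_node, kind="detected_in")
            if pid in animal_ids:
                g.add_node(("animal", pid), kind="animal")
                g.add_edge(("parasite", pid), ("animal", pid), kind="nests")
    return g


def _nesting_digraph(dataset: Dataset) -> nx.DiGraph:
    """Condensed nesting relation on the shared identifier namespace:
    edge A -> P when a record of animal A detected parasite individual P
    and P is itself used as an animal identifier."""
    side_links = _pool_side_links(dataset)
    used_as_animal = set()
    for rec in dataset.records:
        used_as_animal.update(rec.animal_ids())
        if rec.sample_id is not None:
            used_as_animal.update(side_links.get(rec.sample_id, []))
    g = nx.DiGraph()
    g.add_nodes_from(used_as_animal)
    for rec in dataset.records:
        pid = rec.parasite_id
        if pid is None or pid not in used_as_animal:
            continue
        hosts = rec.animal_ids() + \
            (side_links.get(rec.sample_id, []) if rec.sample_id else [])
        for host in dict.fromkeys(hosts):
            if host != pid:
                g.add_edge(host, pid)
    return g


def find_nesting_cycles(dataset: Dataset) -> list:
    """Cycles in the nesting relation, each as an ordered id list."""
    g = _nesting_digraph(dataset)
    return [list(c) for c in nx.simple_cycles(g)]


def nested_chains(dataset: Dataset) -> list:
    """Maximal nesting chains (host -> ectoparasite -> ...), each an
    ordered list of identifiers of length >= 2.

    Raises
    ------
    NestingCycleError
        When the nesting relation contains a cycle.
    """
    g = _nesting_digraph(dataset)
    cycles = [list(c) for c in nx.simple_cycles(g)]
    if cycles:
        raise NestingCycleError(cycles)
    roots = [n for n in g.nodes if g.in_degree(n) == 0 and
             g.out_degree(n) > 0]
    chains = []
    for root in sorted(roots, key=str):
        stack = [[root]]
        while stack:
            path = stack.pop()
            succ = sorted(g.successors(path[-1]), key=str)
            if not succ:
                if len(path) >= 2:
                    chains.append(path)
                continue
            for nxt in succ:
                stack.append(path + [nxt])
    return chains


def pool_summary(dataset: Dataset) -> pd.DataFrame:
    """Per-sample summary of pooled linkage.

    Columns: ``sample_id``, ``n_linked_animals`` (from the ';' list
    encoding plus the side table), ``unidentified`` (blank animal id with
    an organism quantity, e.g. "a pool of 30 mosquitoes"), and ``pooled``
    (more than one linked animal, or unidentified).
    """
    side_links = _pool_side_links(dataset)
    rows = []
    seen = set()
    for rec in dataset.records:
        sid = rec.sample_id
        if sid is None or sid in seen:
            continue
        seen.add(sid)
        linked = list(dict.fromkeys(rec.animal_ids() +
                                    side_links.get(sid, [])))
        unidentified = (not linked) and rec.organism_quantity is not None
        rows.append({"sample_id": sid, "n_linked_animals": len(linked),
                     "unidentified": unidentified,
                     "pooled": unidentified or len(linked) > 1})
    return pd.DataFrame(rows,
                        columns=["sample_id", "n_linked_animals",
                                 "unidentified", "pooled"])


def graph_to_edge_csv(graph: nx.DiGraph) -> str:
    """Edge-list CSV export (source type/id, target type/id, edge kind)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["source_type", "source_id", "target_type",
                     "target_id", "kind"])
    for (stype, sid), (ttype, tid), data in graph.edges(data=True):
        writer.writerow([stype, sid, ttype, tid, data.get("kind", "")])
    return buf.getvalue()
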