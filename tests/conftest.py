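"""Shared fixtures: one synthetic corpus per session plus loaded resources."""

from __future__ import annotations

from collections import defaultdict

import pytest
from hypothesis import settings

from aersdm import build_lexicon, load_meddra, load_rrf
from aersdm.aers_io import DemoRecord
from aersdm.fixtures import FixtureBlueprint, generate_fixture_set
from aersdm.ndfrt_classify import ANCHOR_TTYS, DEFAULT_RELATIONS
from aersdm.rxgraph import RxGraph, is_ndfrt_concept

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """The default synthetic corpus (~200 concepts, 500 cases), written to disk."""
    out = tmp_path_factory.mktemp("fixture-corpus")
    return generate_fixture_set(FixtureBlueprint(seed=0), out)


@pytest.fixture(scope="session")
def graph(fixture_set) -> RxGraph:
    return load_rrf(fixture_set.rxnorm.conso_path, fixture_set.rxnorm.rel_path)


@pytest.fixture(scope="session")
def lexicon(graph):
    return build_lexicon(graph)


@pytest.fixture(scope="session")
def meddra(fixture_set):
    return load_meddra(fixture_set.meddra.path)


@pytest.fixture()
def table1_rows() -> list[DemoRecord]:
    """The four-report duplicate example: two cases, one with a date tie."""
    return [
        DemoRecord(isr=4269368, case_id=4047837, fda_dt=(2004, 1, 13)),
        DemoRecord(isr=4275741, case_id=4047837, fda_dt=(2004, 1, 21)),
        DemoRecord(isr=7637789, case_id=8468457, fda_dt=(2011, 7, 20)),
        DemoRecord(isr=7637797, case_id=8468457, fda_dt=(2011, 7, 20)),
    ]


def bfs_anchor_oracle(graph: RxGraph, query: int, max_depth: int = 3,
                      relations=DEFAULT_RELATIONS):
    """Exhaustive shortest-path anchor search, independent of the traversal code.

    Works directly off the public relation set (not the adjacency indexes)
    and returns (depth, anchors) like the production search.
    """
    if is_ndfrt_concept(graph, query):
        return 0, frozenset({query})
    adj = defaultdict(set)
    for rel in graph.relations:
        if rel.rela in relations:
            adj[rel.from_rxcui].add(rel.to_rxcui)
            adj[rel.to_rxcui].add(rel.from_rxcui)
    seen = {query}
    frontier = {query}
    for depth in range(1, max_depth + 1):
        frontier = {n for node in frontier for n in adj[node]} - seen
        if not frontier:
            break
        anchors = frozenset(
            n for n in frontier
            if is_ndfrt_concept(graph, n) and graph.concepts[n].term_types & ANCHOR_TTYS)
        if anchors:
            return depth, anchors
        seen |= frontier
    return None, frozenset()


def random_typed_graph(rng, n_nodes: int) -> RxGraph:
    """A random concept graph mixing allowed and disallowed relation labels."""
    ttys = ("IN", "PIN", "BN", "SCD", "SBD", "SCDC", "DF", "FN")
    relas = tuple(sorted(DEFAULT_RELATIONS)) + ("dose_form_of", "has_doseformgroup")
    g = RxGraph()
    for i in range(1, n_nodes + 1):
        sab = "NDFRT" if rng.random() < 0.2 else "RXNORM"
        g.add_concept(i, f"Concept {i}", rng.choice(ttys), sab)
    for _ in range(2 * n_nodes):
        a, b = rng.randint(1, n_nodes), rng.randint(1, n_nodes)
        if a != b:
            g.add_relation(a, b, rng.choice(relas))
    return g
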