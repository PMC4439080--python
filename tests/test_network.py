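"""Median-joining network construction, annotation and export."""

import itertools

import networkx as nx
import numpy as np
import pytest

from paleocattle.haplotyping import HaplotypeTable, collapse_haplotypes
from paleocattle.network import (
    EpsilonParam,
    MEDIAN,
    OBSERVED,
    annotate_nodes,
    build_mjn,
    distance_matrix,
    export_network,
    feasible_links,
    hamming,
    network_cost,
)
from paleocattle.seqio import SampleRecord

from conftest import make_alignment


def table_of(*seqs: str) -> HaplotypeTable:
    return HaplotypeTable(
        labels=[f"H{i + 1:02d}" for i in range(len(seqs))],
        sequences=list(seqs),
        counts=[1] * len(seqs),
        members=[[f"s{i}"] for i in range(len(seqs))],
    )


def test_distance_matrix_metric_properties():
    d = distance_matrix(["AAT", "ATA", "TAA"])
    assert (d == d.T).all() and (np.diag(d) == 0).all()
    assert (d[np.triu_indices(3, 1)] == 2).all()
    # triangle inequality
    for i, j, k in itertools.permutations(range(3), 3):
        assert d[i, j] <= d[i, k] + d[k, j]


def test_single_haplotype_network():
    net = build_mjn(table_of("ACGT"))
    assert net.number_of_nodes() == 1 and net.number_of_edges() == 0


def test_three_haplotype_median():
    """{AAB, ABA, BAA}: one consensus median AAA, three unit edges, cost 3 < MST cost 4."""
    net = build_mjn(table_of("AAB", "ABA", "BAA"))
    medians = [n for n, d in net.nodes(data=True) if d["type"] == MEDIAN]
    assert len(medians) == 1
    assert net.nodes[medians[0]]["sequence"] == "AAA"
    assert net.number_of_edges() == 3
    assert all(d["weight"] == 1 for _, _, d in net.edges(data=True))
    assert network_cost(net) == 3


def test_star_data_yields_star_without_medians():
    center = "AAAAAA"
    leaves = ["CAAAAA", "ACAAAA", "AACAAA", "AAACAA"]
    net = build_mjn(table_of(center, *leaves))
    assert all(d["type"] == OBSERVED for _, d in net.nodes(data=True))
    assert net.number_of_edges() == 4
    degrees = dict(net.degree())
    assert max(degrees.values()) == 4  # the center


def test_epsilon_param_contract():
    with pytest.raises(ValueError):
        EpsilonParam(-1)
    with pytest.raises(ValueError):
        build_mjn(table_of("AAA", "AAAA"))


def test_feasible_links_union_of_msts():
    # equilateral triple: all three edges lie in some MST
    d = distance_matrix(["AAT", "ATA", "TAA"])
    assert set(feasible_links(d, 0)) == {(0, 1), (0, 2), (1, 2)}
    # chain: AA - AT - TT; the 2-step edge is in no MST
    d = distance_matrix(["AA", "AT", "TT"])
    assert set(feasible_links(d, 0)) == {(0, 1), (1, 2)}
    # relaxation admits it again
    assert (0, 2) in feasible_links(d, 1)


def _all_msts(nodes: list[str]) -> list[set[frozenset]]:
    """Enumerate all minimum spanning trees by brute force (small n only)."""
    n = len(nodes)
    d = distance_matrix(nodes)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best, trees = None, []
    for combo in itertools.combinations(edges, n - 1):
        g = nx.Graph(combo)
        if g.number_of_nodes() != n or not nx.is_connected(g):
            continue
        w = sum(d[i, j] for i, j in combo)
        if best is None or w < best:
            best, trees = w, [set(map(frozenset, combo))]
        elif w == best:
            trees.append(set(map(frozenset, combo)))
    return trees


def test_network_contains_every_mst_of_final_node_set(rng):
    """At eps=0 the link set is the union of all MSTs over the network's nodes."""
    for _ in range(5):
        seqs = list({"".join(rng.choice(list("ACT"), 5)) for _ in range(6)})
        net = build_mjn(table_of(*seqs))
        ordered = list(net.nodes)
        node_seqs = [net.nodes[n]["sequence"] for n in ordered]
        edge_set = {frozenset((ordered.index(u), ordered.index(v))) for u, v in net.edges}
        for tree in _all_msts(node_seqs):
            assert tree <= edge_set


def test_observed_mst_edges_present_or_bypassed(rng):
    """Every MST edge of the observed haplotypes is either in the network or
    bypassed by a path whose edges are all strictly smaller (the cycle
    property that justifies dropping it once medians are added)."""
    for _ in range(5):
        seqs = sorted({"".join(rng.choice(list("ACGT"), 6)) for _ in range(6)})
        net = build_mjn(table_of(*seqs))
        label = {net.nodes[n]["sequence"]: n for n in net.nodes}
        for tree in _all_msts(seqs)[:3]:
            for edge in tree:
                i, j = sorted(edge)
                u, v = label[seqs[i]], label[seqs[j]]
                w = hamming(seqs[i], seqs[j])
                if net.has_edge(u, v):
                    assert net[u][v]["weight"] == w
                    continue
                smaller = nx.Graph(
                    (a, b) for a, b, d in net.edges(data=True) if d["weight"] < w
                )
                assert smaller.has_node(u) and smaller.has_node(v)
                assert nx.has_path(smaller, u, v)


def test_median_addition_never_increases_cost(rng):
    for _ in range(5):
        seqs = list({"".join(rng.choice(list("ACT"), 5)) for _ in range(6)})
        d = distance_matrix(seqs)
        mst_cost = int(
            nx.minimum_spanning_tree(nx.Graph(
                (i, j, {"weight": int(d[i, j])})
                for i in range(len(seqs)) for j in range(i + 1, len(seqs))
            )).size(weight="weight")
        )
        net = build_mjn(table_of(*seqs))
        final_seqs = [net.nodes[n]["sequence"] for n in net.nodes]
        fd = distance_matrix(final_seqs)
        g = nx.Graph(
            (i, j, {"weight": int(fd[i, j])})
            for i in range(len(final_seqs)) for j in range(i + 1, len(final_seqs))
        )
        assert nx.minimum_spanning_tree(g).size(weight="weight") <= mst_cost


def test_median_nodes_have_degree_at_least_three(rng):
    for _ in range(5):
        seqs = list({"".join(rng.choice(list("ACT"), 6)) for _ in range(7)})
        net = build_mjn(table_of(*seqs))
        for node, data in net.nodes(data=True):
            if data["type"] == MEDIAN:
                assert net.degree(node) >= 3


def test_deterministic_under_input_permutation(rng):
    seqs = ["AAT", "AAT", "ACT", "GGT", "GCT"]
    base = None
    for perm in (seqs, seqs[::-1]):
        aln = make_alignment({f"s{i}": s for i, s in enumerate(perm)})
        net = build_mjn(collapse_haplotypes(aln))
        canon = (
            sorted((n, d["sequence"], d["type"]) for n, d in net.nodes(data=True)),
            sorted((min(u, v), max(u, v), d["weight"]) for u, v, d in net.edges(data=True)),
        )
        if base is None:
            base = canon
        assert canon == base


def test_annotate_and_export_roundtrip(tmp_path):
    aln = make_alignment({"a": "AAT", "b": "AAT", "c": "ACT"})
    table = collapse_haplotypes(aln)
    net = build_mjn(table)
    samples = [
        SampleRecord(id="a", period="Medieval"),
        SampleRecord(id="b", period="Post-Medieval"),
        SampleRecord(id="c", period="Medieval"),
    ]
    annotate_nodes(net, samples)
    sizes = {n: d["size"] for n, d in net.nodes(data=True)}
    assert sizes["H01"] == 2
    comp = dict(net.nodes(data="periods"))["H01"]
    assert comp == "Medieval:1;Post-Medieval:1"

    gml, tsv = tmp_path / "net.graphml", tmp_path / "edges.tsv"
    export_network(net, gml, tsv)
    back = nx.read_graphml(gml)
    assert nx.is_isomorphic(net, back)
    assert {d["type"] for _, d in back.nodes(data=True)} <= {OBSERVED, MEDIAN}
    assert tsv.read_text().startswith("node1\tnode2\tweight")
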