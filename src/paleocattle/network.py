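"""Median-joining haplotype networks (epsilon-relaxed, reduced).

The network is built by the median-joining strategy for multistate sequence
data: starting from the minimum-spanning network (the union of all minimum
spanning trees, relaxed by a tolerance epsilon on the connection cost),
majority-consensus median vectors of linked triplets are proposed and added
when they reduce the spanning cost of the node set; finally median nodes of
degree <= 2 are pruned (the "reduced" network).  epsilon = 0 is the most
conservative setting and the default.

Nodes carry haplotype labels, carrier counts and (after annotation) the
temporal-period composition of their carriers; edges carry the number of
differing positions and the positions themselves.  Networks are exported as
GraphML plus a flat TSV edge list.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .haplotyping import HaplotypeTable, assign_period
from .seqio import SampleRecord

logger = logging.getLogger(__name__)

OBSERVED, MEDIAN = "observed", "median"


@dataclass(frozen=True)
class EpsilonParam:
    """Non-negative relaxation of the minimum-spanning connection cost."""

    epsilon: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def differing_positions(a: str, b: str, columns: Sequence[int] | None = None) -> list[int]:
    cols = list(columns) if columns is not None else list(range(1, len(a) + 1))
    return [c for c, x, y in zip(cols, a, b) if x != y]


def distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric Hamming distance matrix with zero diagonal."""
    n = len(sequences)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming(sequences[i], sequences[j])
    return d


def _minimax_distances(d: np.ndarray) -> np.ndarray:
    """Minimax path distance (minimal over paths of the largest edge weight).

    Computed on any minimum spanning tree: the minimax distance between two
    nodes equals the largest edge on their MST path.
    """
    n = d.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g)
    mm = np.zeros_like(d)
    for i in range(n):
        # DFS over the MST tracking the max edge weight seen
        stack = [(i, -1, 0)]
        seen = {i}
        while stack:
            node, _, best = stack.pop()
            mm[i, node] = best
            for nb in mst.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, node, max(best, mst[node][nb]["weight"])))
    return mm


def feasible_links(d: np.ndarray, epsilon: int = 0) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum-spanning network.

    An edge (u, v) is feasible iff d(u, v) <= minimax(u, v) + epsilon; at
    epsilon = 0 this is exactly the union of all minimum spanning trees.
    """
    mm = _minimax_distances(d)
    n = d.shape[0]
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= mm[i, j] + epsilon
    ]


def _spanning_cost(d: np.ndarray) -> int:
    n = d.shape[0]
    if n < 2:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=int(d[i, j]))
    return int(nx.minimum_spanning_tree(g).size(weight="weight"))


def _median_vector(u: str, v: str, w: str) -> str:
    """Per-column majority consensus; a three-way tie keeps the first sequence's
    symbol (canonical order makes this deterministic)."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b if a != b else a)
        elif a == b or a == c:
            out.append(a)
        else:
            out.append(a)
    return "".join(out)


def build_mjn(
    table: HaplotypeTable, eps: EpsilonParam | int = 0, max_rounds: int = 50
) -> nx.Graph:
    """Median-joining network of a haplotype table.

    Iterates: compute the epsilon-relaxed minimum-spanning network; for every
    triplet with at least two feasible links among its pairs propose the
    majority-consensus median; add the new medians that strictly reduce the
    spanning cost of the node set (most-parsimonious first); repeat to a
    fixpoint; finally prune median nodes of degree <= 2.  Deterministic for
    a canonically ordered table.
    """
    epsilon = eps.epsilon if isinstance(eps, EpsilonParam) else int(eps)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if len(table) == 0:
        raise ValueError("empty haplotype table")
    lengths = {len(s) for s in table.sequences}
    if len(lengths) != 1:
        raise ValueError("haplotype sequences of unequal length")

    seqs: list[str] = list(table.sequences)
    labels: list[str] = list(table.labels)
    kinds: list[str] = [OBSERVED] * len(seqs)
    n_median = 0

    for _ in range(max_rounds):
        d = distance_matrix(seqs)
        links = set(feasible_links(d, epsilon))
        base_cost = _spanning_cost(d)
        # candidate medians from triplets with >=2 feasible links
        candidates: dict[str, int] = {}
        for i, j, k in itertools.combinations(range(len(seqs)), 3):
            pairs = [(i, j), (i, k), (j, k)]
            if sum(p in links for p in pairs) < 2:
                continue
            m = _median_vector(seqs[i], seqs[j], seqs[k])
            if m in seqs or m in candidates:
                continue
            cost = hamming(seqs[i], m) + hamming(seqs[j], m) + hamming(seqs[k], m)
            candidates[m] = cost
        added = False
        for m, _cost in sorted(candidates.items(), key=lambda kv: (kv[1], kv[0])):
            trial = distance_matrix(seqs + [m])
            if _spanning_cost(trial) < base_cost:
                n_median += 1
                seqs.append(m)
                labels.append(f"mv{n_median}")
                kinds.append(MEDIAN)
                added = True
                break  # re-derive links with the new node before adding more
        if not added:
            break

    # prune obsolete medians (degree <= 2 in the final link graph)
    while True:
        d = distance_matrix(seqs)
        links = feasible_links(d, epsilon)
        degree = {i: 0 for i in range(len(seqs))}
        for i, j in links:
            degree[i] += 1
            degree[j] += 1
        drop = [
            i for i in range(len(seqs)) if kinds[i] == MEDIAN and degree[i] <= 2
        ]
        if not drop:
            break
        for i in reversed(drop):
            del seqs[i], labels[i], kinds[i]

    d = distance_matrix(seqs)
    links = feasible_links(d, epsilon)
    g = nx.Graph()
    columns = table.columns or tuple(range(1, len(seqs[0]) + 1))
    for lab, seq, kind in zip(labels, seqs, kinds):
        count = table.counts[table.labels.index(lab)] if kind == OBSERVED else 0
        members = table.members[table.labels.index(lab)] if kind == OBSERVED else []
        g.add_node(lab, type=kind, sequence=seq, count=count, members=",".join(members))
    for i, j in links:
        g.add_edge(
            labels[i],
            labels[j],
            weight=int(d[i, j]),
            positions=",".join(map(str, differing_positions(seqs[i], seqs[j], columns))),
        )
    return g


def annotate_nodes(net: nx.Graph, samples: Sequence[SampleRecord]) -> nx.Graph:
    """Attach carrier counts and temporal-period composition to each node."""
    by_id = {s.id: s for s in samples}
    for node, data in net.nodes(data=True):
        members = [m for m in data.get("members", "").split(",") if m]
        comp: dict[str, int] = {}
        for m in members:
            rec = by_id.get(m)
            if rec is None:
                logger.warning("node %s: unknown sample id %s", node, m)
                period = "unknown"
            else:
                try:
                    period = rec.period or assign_period(rec)
                except ValueError:
                    period = "unknown"
            comp[period] = comp.get(period, 0) + 1
        data["size"] = len(members)
        data["periods"] = ";".join(f"{k}:{v}" for k, v in sorted(comp.items()))
    return net


def network_cost(net: nx.Graph) -> int:
    return int(sum(d["weight"] for _, _, d in net.edges(data=True)))


def export_network(net: nx.Graph, graphml_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Write GraphML plus a flat TSV edge list (node1, node2, weight, positions)."""
    nx.write_graphml(net, str(graphml_path))
    if tsv_path is not None:
        rows = [
            {"node1": u, "node2": v, "weight": d["weight"], "positions": d.get("positions", "")}
            for u, v, d in sorted(net.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["node1", "node2", "weight", "positions"]).to_csv(
            tsv_path, sep="\t", index=False
        )


def plot_network(net: nx.Graph, path: str | Path, seed: int = 0) -> None:
    """Static plot: node size proportional to carrier count, medians as diamonds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(net, seed=seed, weight=None)
    fig, ax = plt.subplots(figsize=(7, 7))
    obs = [n for n, d in net.nodes(data=True) if d.get("type") == OBSERVED]
    med = [n for n, d in net.nodes(data=True) if d.get("type") == MEDIAN]
    sizes = [120 + 80 * net.nodes[n].get("count", 1) for n in obs]
    nx.draw_networkx_edges(net, pos, ax=ax)
    nx.draw_networkx_nodes(net, pos, nodelist=obs, node_size=sizes, node_color="#c0c0c0", ax=ax)
    nx.draw_networkx_nodes(
        net, pos, nodelist=med, node_size=60, node_color="black", node_shape="d", ax=ax
    )
    nx.draw_networkx_labels(net, pos, font_size=7, ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
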