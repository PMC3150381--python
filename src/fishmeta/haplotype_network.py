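"""Median-joining haplotype networks over the pooled haplotype table.

Observed haplotypes ("real" nodes) are connected through a minimum spanning
network; median (consensus) states — hypothetical unsampled intermediates —
are added for fully connected triples until the network stabilizes, then
median vectors that no shortest connection uses are pruned.  Counting
observed versus median nodes summarizes how many mutational intermediates
separate the sampled variants.

Characters are the aligned nucleotide columns, equally weighted.  Columns
carrying any ambiguity (N or gap) in any haplotype are excluded from
network construction; the exclusion is reported on the graph.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import networkx as nx
import numpy as np

from .sequence_diversity import HaplotypeTable

__all__ = [
    "hamming_matrix",
    "median_joining_network",
    "count_nodes",
]

_UNAMBIGUOUS = frozenset("ACGT")


def hamming_distance(a: str, b: str) -> int:
    """Hamming distance counted over positions unambiguous in both states."""
    return sum(
        x != y for x, y in zip(a, b) if x in _UNAMBIGUOUS and y in _UNAMBIGUOUS
    )


def hamming_matrix(ht: HaplotypeTable) -> tuple[np.ndarray, list[str]]:
    """Integer Hamming distances between all haplotypes (unambiguous sites)."""
    states = [h.sequence for h in ht.haplotypes]
    k = len(states)
    d = np.zeros((k, k), dtype=int)
    for i, j in itertools.combinations(range(k), 2):
        d[i, j] = d[j, i] = hamming_distance(states[i], states[j])
    return d, states


def _mask_ambiguous_columns(states: Sequence[str]) -> tuple[list[str], list[int]]:
    """Drop alignment columns with any N/gap; return reduced states + kept columns."""
    if not states:
        return [], []
    length = len(states[0])
    kept = [
        i for i in range(length) if all(s[i] in _UNAMBIGUOUS for s in states)
    ]
    reduced = ["".join(s[i] for i in kept) for s in states]
    return reduced, kept


def _pairwise(states: Sequence[str]) -> dict[tuple[str, str], int]:
    return {
        (a, b): sum(x != y for x, y in zip(a, b))
        for a, b in itertools.combinations(sorted(states), 2)
    }


def _spanning_network(states: list[str], epsilon: int) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network (union of all MSTs at eps=0).

    Edges are grouped by weight in ascending order; an edge of weight w is
    included iff its endpoints are not already connected using only edges
    of weight < w − epsilon.
    """
    g = nx.Graph()
    g.add_nodes_from(states)
    dist = _pairwise(states)
    by_weight: dict[int, list[tuple[str, str]]] = {}
    for pair, w in dist.items():
        by_weight.setdefault(w, []).append(pair)

    kept = nx.Graph()
    kept.add_nodes_from(states)
    for w in sorted(by_weight):
        # connectivity among edges with weight < w - epsilon
        snapshot = nx.Graph()
        snapshot.add_nodes_from(states)
        snapshot.add_edges_from(
            (u, v) for u, v, d in kept.edges(data="mutations") if d < w - epsilon
        )
        comp = {n: c for c, nodes in enumerate(nx.connected_components(snapshot)) for n in nodes}
        for u, v in sorted(by_weight[w]):
            if comp[u] != comp[v]:
                kept.add_edge(u, v, mutations=w)
    return kept


def _median_state(a: str, b: str, c: str) -> str | None:
    """Site-wise majority consensus of a triple; None if any site is a 3-way tie."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


def median_joining_network(ht: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network of the haplotype table.

    Iterates: build the epsilon-relaxed minimum spanning network over the
    current states; for every triple whose three pairs are all linked in
    that network, propose the site-wise majority consensus as a new median
    state.  Repeats until no new median appears, then prunes obsolete
    medians (degree <= 1, or degree-2 medians that lengthen the connection
    between their two neighbours).  Deterministic: states are processed in
    lexicographic order.

    Node attributes: ``kind`` (``observed``/``median``), ``count``,
    ``species``; edge attribute ``mutations`` (Hamming distance on the
    unmasked columns).  Graph attribute ``masked_columns`` lists excluded
    alignment columns.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be a non-negative integer")
    full_states = [h.sequence for h in ht.haplotypes]
    reduced, kept_cols = _mask_ambiguous_columns(full_states)
    masked = (
        [i for i in range(ht.length) if i not in set(kept_cols)] if full_states else []
    )

    # collapse states identical after masking
    info: dict[str, dict] = {}
    for hap, red in zip(ht.haplotypes, reduced):
        entry = info.setdefault(red, {"count": 0, "species": set()})
        entry["count"] += hap.count
        entry["species"] |= hap.species

    observed = sorted(info)
    states: list[str] = list(observed)
    medians: set[str] = set()

    graph = nx.Graph()
    if states:
        while True:
            graph = _spanning_network(states, epsilon)
            new: set[str] = set()
            for a, b, c in itertools.combinations(sorted(states), 3):
                if graph.has_edge(a, b) and graph.has_edge(a, c) and graph.has_edge(b, c):
                    med = _median_state(a, b, c)
                    if med is not None and med not in states and med not in new:
                        new.add(med)
            if not new:
                break
            medians |= new
            states = sorted(set(states) | new)

        # prune obsolete median vectors
        changed = True
        while changed:
            changed = False
            for node in sorted(graph.nodes):
                if node not in medians or node not in graph:
                    continue
                deg = graph.degree(node)
                if deg <= 1:
                    graph.remove_node(node)
                    medians.discard(node)
                    changed = True
                elif deg == 2:
                    u, v = list(graph.neighbors(node))
                    through = graph[u][node]["mutations"] + graph[node][v]["mutations"]
                    direct = sum(x != y for x, y in zip(u, v))
                    if direct < through:
                        graph.remove_node(node)
                        medians.discard(node)
                        if not graph.has_edge(u, v):
                            graph.add_edge(u, v, mutations=direct)
                        changed = True

    out = nx.Graph(masked_columns=masked)
    for node in graph.nodes:
        if node in medians:
            out.add_node(node, kind="median", count=0, species=set())
        else:
            out.add_node(
                node,
                kind="observed",
                count=info[node]["count"],
                species=set(info[node]["species"]),
            )
    for u, v, d in graph.edges(data="mutations"):
        out.add_edge(u, v, mutations=int(d))
    return out


def count_nodes(graph: nx.Graph) -> tuple[int, int]:
    """(observed, median) node counts of a haplotype network."""
    observed = sum(1 for _, k in graph.nodes(data="kind") if k == "observed")
    median = sum(1 for _, k in graph.nodes(data="kind") if k == "median")
    return observed, median
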