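"""Protein distance matrices, neighbor-joining trees and bootstrap supports.

Distances between polypeptide variants are either the p-distance
(proportion of differing sites, pairwise deletion of ambiguous residues)
or the maximum-likelihood pairwise distance under the JTT empirical model,
optionally with discrete-gamma rate heterogeneity at a user-supplied shape.
Trees are built with Saitou–Nei neighbor joining (Studier–Keppler Q
criterion); split support comes from bootstrap resampling of alignment
columns.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as _gamma_dist
from skbio import DistanceMatrix, TreeNode

from . import _jtt
from .sequence_diversity import ProteinTable

__all__ = [
    "protein_distance",
    "neighbor_joining",
    "bootstrap_support",
    "tree_splits",
]

_AA_INDEX = {a: i for i, a in enumerate(_jtt.AA_ORDER)}
_N_GAMMA_CATEGORIES = 4


def _as_alignment(proteins: ProteinTable | Mapping[str, str]) -> tuple[list[str], list[str]]:
    """Labels and equal-length amino-acid strings from a table or mapping."""
    if isinstance(proteins, ProteinTable):
        labels = [f"pv{i + 1}" for i in range(proteins.P)]
        seqs = [p.sequence for p in proteins.proteins]
    else:
        labels = list(proteins.keys())
        seqs = [proteins[l] for l in labels]
    if len(seqs) < 2:
        raise ValueError("need at least 2 protein variants")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("protein sequences have unequal lengths")
    return labels, seqs


def _encode(seq: str) -> np.ndarray:
    """Residues as JTT indices; anything outside the 20-letter alphabet is -1."""
    return np.asarray([_AA_INDEX.get(c, -1) for c in seq], dtype=int)


def discrete_gamma_rates(shape: float, k: int = _N_GAMMA_CATEGORIES) -> np.ndarray:
    """Mean rates of k equal-probability gamma categories (mean rate 1)."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), shape, scale=1.0 / shape)
    upper = _gamma_dist.cdf(edges[1:], shape + 1, scale=1.0 / shape)
    lower = _gamma_dist.cdf(edges[:-1], shape + 1, scale=1.0 / shape)
    return k * (upper - lower)


class _JttPairwiseML:
    """Maximum-likelihood JTT distance for one pair of encoded sequences."""

    def __init__(self, gamma_shape: Optional[float] = None):
        self.eigval, self.left, self.right = _jtt.spectral_decomposition()
        self.rates = (
            discrete_gamma_rates(gamma_shape) if gamma_shape is not None else np.array([1.0])
        )

    def _transition(self, t: float) -> np.ndarray:
        p = np.zeros((20, 20))
        for r in self.rates:
            p += (self.right * np.exp(self.eigval * r * t)) @ self.left
        p /= len(self.rates)
        return np.clip(p, 1e-300, None)

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            raise ValueError("zero comparable sites between a protein pair")
        counts = np.zeros((20, 20))
        np.add.at(counts, (a[ok], b[ok]), 1.0)
        if (a[ok] == b[ok]).all():
            return 0.0
        log_pi = np.log(_jtt.JTT_FREQS)

        def neg_loglik(t: float) -> float:
            p = self._transition(t)
            return -float((counts * (np.log(p) + log_pi[:, np.newaxis])).sum())

        res = minimize_scalar(neg_loglik, bounds=(1e-8, 30.0), method="bounded")
        return float(res.x)


def protein_distance(
    proteins: ProteinTable | Mapping[str, str],
    model: str = "p",
    gamma_shape: Optional[float] = None,
) -> DistanceMatrix:
    """Pairwise distances between polypeptide variants.

    ``model="p"`` gives the proportion of differing sites with pairwise
    deletion of ambiguous residues (X, gaps).  ``model="jtt"`` gives the
    ML distance under the JTT rate matrix, averaging over four discrete
    gamma rate categories when ``gamma_shape`` is supplied.
    """
    labels, seqs = _as_alignment(proteins)
    enc = [_encode(s) for s in seqs]
    k = len(enc)
    d = np.zeros((k, k))
    ml = _JttPairwiseML(gamma_shape) if model == "jtt" else None
    for i, j in itertools.combinations(range(k), 2):
        a, b = enc[i], enc[j]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            raise ValueError(
                f"zero comparable sites between {labels[i]!r} and {labels[j]!r}"
            )
        if model == "p":
            dij = float((a[ok] != b[ok]).mean())
        elif model == "jtt":
            dij = ml.distance(a, b)
        else:
            raise ValueError(f"unknown model {model!r} (expected 'p' or 'jtt')")
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids=labels)


def _min_leaf(node: TreeNode) -> str:
    return min(t.name for t in node.tips()) if not node.is_tip() else node.name


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Ties in Q are broken by the lexicographically smallest label pair
    (labels of internal nodes are the smallest leaf below them).  Negative
    branch-length estimates are clamped to zero with a warning.  The
    returned tree is unrooted (trifurcating root).
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.ids]
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        keys = [_min_leaf(nd) for nd in nodes]
        best = None
        for i, j in itertools.combinations(range(m), 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            tie = tuple(sorted((keys[i], keys[j])))
            cand = (q, tie, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        if vi < 0 or vj < 0:
            clamped = True
            vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = float(vi), float(vj)

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # terminal trifurcation
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if min(la, lb, lc) < 0:
        clamped = True
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[a, b, c])
    if clamped:
        warnings.warn("negative NJ branch length estimate(s) clamped to zero")
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as smaller leaf sets."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            splits.add(side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other)
    return splits


def bootstrap_support(
    proteins: ProteinTable | Mapping[str, str],
    model: str = "p",
    gamma_shape: Optional[float] = None,
    replicates: int = 2000,
    seed: Optional[int] = None,
) -> TreeNode:
    """NJ tree with bootstrap split supports (percent of replicates).

    Alignment columns are resampled with replacement per replicate; the
    support of each internal split of the point-estimate tree is the
    percentage of replicate trees containing it, stored on the internal
    node as ``support`` (and mirrored into ``name`` for newick output).
    Replicates whose resampled alignment leaves a pair with no comparable
    sites are skipped and counted; a warning is issued above 1% skips.
    """
    labels, seqs = _as_alignment(proteins)
    length = len(seqs[0])
    if length < 1:
        raise ValueError("empty alignment")
    tree = neighbor_joining(protein_distance(dict(zip(labels, seqs)), model, gamma_shape))
    if replicates == 0:
        return tree

    rng = np.random.default_rng(seed)
    split_hits: dict[frozenset[str], int] = {s: 0 for s in tree_splits(tree)}
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamping warnings inside replicates
        for _ in range(replicates):
            cols = rng.integers(0, length, size=length)
            resampled = {l: "".join(s[c] for c in cols) for l, s in zip(labels, seqs)}
            try:
                rep_tree = neighbor_joining(protein_distance(resampled, model, gamma_shape))
            except ValueError:
                skipped += 1
                continue
            rep_splits = tree_splits(rep_tree)
            for s in split_hits:
                if s in rep_splits:
                    split_hits[s] += 1
    done = replicates - skipped
    if done == 0:
        raise ValueError("all bootstrap replicates failed")
    if skipped > 0.01 * replicates:
        warnings.warn(f"{skipped}/{replicates} bootstrap replicates skipped")

    leaves = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if (len(side), sorted(side)) <= (len(leaves - side), sorted(leaves - side)) else leaves - side
        if canon in split_hits:
            pct = 100.0 * split_hits[canon] / done
            node.support = pct
            node.name = f"{pct:g}"
    return tree
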