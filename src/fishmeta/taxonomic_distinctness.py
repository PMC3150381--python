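"""Clarke–Warwick-style taxonomic distinctness over a fixed six-rank tree.

Species are placed at depth six below a synthetic root (root → phylum →
class → order → family → genus → species) and every edge carries the same
weight 100/6, so the longest possible path between two species — different
phyla — scores 100.  Two indices are computed on a species set:

* **TTD** (total taxonomic distinctness): the sum over species of the mean
  pairwise path weight omega to all other species in the set.
* **sPhi+** (total taxonomic path length): the summed edge weights of the
  taxonomy subtree spanning the root and the species' lineages — Faith-style
  diversity on Linnean ranks, root edge included.

The equal-step, fixed-normalization convention is deliberate: it makes the
indices comparable across communities instead of being re-standardized per
dataset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import TaxonomyRecord, normalize_species

__all__ = [
    "STEP_WEIGHT",
    "TaxonomyTree",
    "build_taxonomy_tree",
    "path_weight",
    "path_weight_matrix",
    "total_taxonomic_distinctness",
    "total_taxonomic_path_length",
]

#: equal per-rank step weight; six ranks, maximum path normalized to 100
STEP_WEIGHT = 100.0 / 6.0
_N_RANKS = 6


def _check_hierarchy(records: Sequence[TaxonomyRecord]) -> None:
    parent_of: dict[tuple[int, str], str] = {}
    ranks = ("species", "genus", "family", "order", "class_", "phylum")
    for child_idx in range(len(ranks) - 1):
        child_rank, parent_rank = ranks[child_idx], ranks[child_idx + 1]
        for r in records:
            child = getattr(r, child_rank)
            parent = getattr(r, parent_rank)
            key = (child_idx, child)
            if key in parent_of and parent_of[key] != parent:
                raise ValueError(
                    f"inconsistent taxonomy: {child_rank.rstrip('_')} {child!r} under "
                    f"two different {parent_rank.rstrip('_')} values "
                    f"({parent_of[key]!r} vs {parent!r})"
                )
            parent_of[key] = parent


@dataclass(frozen=True)
class TaxonomyTree:
    """Rooted six-rank tree with equal edge weights of 100/6.

    ``lineages`` maps a normalized species key to the (phylum, class, order,
    family, genus, species) tuple; the synthetic root sits above all phyla.
    """

    lineages: dict[str, tuple[str, ...]]
    display_names: dict[str, str]

    @property
    def n_edges(self) -> int:
        """Edges of the full tree: one per distinct taxon path per rank."""
        return sum(
            len({lin[: depth + 1] for lin in self.lineages.values()})
            for depth in range(_N_RANKS)
        )

    def lineage_of(self, species: str) -> tuple[str, ...]:
        key = normalize_species(species)
        if key not in self.lineages:
            raise KeyError(f"species {species!r} not in taxonomy tree")
        return self.lineages[key]


def build_taxonomy_tree(tax: Sequence[TaxonomyRecord]) -> TaxonomyTree:
    """Build the fixed-rank tree, validating hierarchy consistency."""
    _check_hierarchy(tax)
    lineages: dict[str, tuple[str, ...]] = {}
    display: dict[str, str] = {}
    for rec in tax:
        key = normalize_species(rec.species)
        lineages[key] = rec.lineage()
        display[key] = rec.species
    return TaxonomyTree(lineages, display)


def path_weight(tree: TaxonomyTree, sp_i: str, sp_j: str) -> float:
    """Taxonomic path weight omega between two species.

    The number of ranks ascended from a species to the lowest common taxon,
    times 100/6: congeners score 100/6, confamilials 200/6, ... and species
    in different phyla the full 100.  Identical species score 0.
    """
    li, lj = tree.lineage_of(sp_i), tree.lineage_of(sp_j)
    shared = 0
    for a, b in zip(li, lj):
        if a != b:
            break
        shared += 1
    if shared == _N_RANKS:
        return 0.0
    return (_N_RANKS - shared) * STEP_WEIGHT


def path_weight_matrix(
    tree: TaxonomyTree, species: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Symmetric omega matrix for a species list (zero diagonal)."""
    s = len(species)
    omega = np.zeros((s, s))
    for i, j in itertools.combinations(range(s), 2):
        omega[i, j] = omega[j, i] = path_weight(tree, species[i], species[j])
    return omega, list(species)


def total_taxonomic_distinctness(tree: TaxonomyTree, species: Iterable[str]) -> float:
    """TTD = sum over species of the mean pairwise omega to all others."""
    sp = list(dict.fromkeys(normalize_species(s) for s in species))
    if len(sp) < 2:
        raise ValueError(f"TTD needs at least 2 species, got {len(sp)}")
    omega, _ = path_weight_matrix(tree, sp)
    return float((omega.sum(axis=1) / (len(sp) - 1)).sum())


def total_taxonomic_path_length(tree: TaxonomyTree, species: Iterable[str]) -> float:
    """sPhi+ — summed edge weights of the subtree spanning the species set.

    Equals 100/6 times the number of distinct taxa over the six ranks among
    the selected lineages (the root edge above each distinct phylum counts).
    """
    sp = list(dict.fromkeys(normalize_species(s) for s in species))
    if not sp:
        raise ValueError("sPhi+ needs at least 1 species")
    lineages = [tree.lineage_of(s) for s in sp]
    edges = sum(
        len({lin[: depth + 1] for lin in lineages}) for depth in range(_N_RANKS)
    )
    return edges * STEP_WEIGHT
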