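"""End-to-end community profiling: from input files to the diversity profile.

One profile summarizes one regional catch: pooled haplotype and nucleotide
diversity of the barcode sample, the haplotypes-per-polypeptide ratio,
Shannon index of the sample composition, taxonomic distinctness (TTD) and
taxonomic path length (sPhi+) of the dominant-species set, mean trophic
level, and the node counts of the median-joining haplotype network.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import __version__
from .catch_composition import (
    mean_trophic_level,
    select_dominant_species,
    shannon_index,
)
from .haplotype_network import count_nodes, median_joining_network
from .io_formats import (
    normalize_species,
    read_catch_table,
    read_fasta,
    read_taxonomy_table,
    read_trophic_table,
)
from .protein_phylogeny import bootstrap_support, neighbor_joining, protein_distance
from .sequence_diversity import AlignedSequenceSet, diversity_summary
from .taxonomic_distinctness import (
    build_taxonomy_tree,
    total_taxonomic_distinctness,
    total_taxonomic_path_length,
)

__all__ = ["ProfileConfig", "CommunityProfile", "compute_profile"]


@dataclass(frozen=True)
class ProfileConfig:
    """Tunable knobs of a profiling run."""

    threshold: float = 0.65
    include_all: bool = False  # keep sequences of non-dominant species too
    frame: int | str = "auto"
    epsilon: int = 0
    tree_model: str = "p"
    gamma_shape: Optional[float] = None
    bootstrap_replicates: int = 0
    seed: Optional[int] = None
    trophic_weighted: bool = False
    total_catch: Optional[float] = None  # denominator incl. an "Others" aggregate
    inventory_size: Optional[int] = None  # species inventoried in the ecosystem
    region: str = ""

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class CommunityProfile:
    """All indices for one regional catch (the per-community summary column).

    Any field that cannot be computed is ``None`` and the reason is
    recorded in ``unavailable`` under the field's name.
    """

    region: str = ""
    n_sequences: Optional[int] = None
    k_haplotypes: Optional[int] = None
    P_polypeptides: Optional[int] = None
    haplotypes_per_polypeptide: Optional[float] = None
    Hd: Optional[float] = None
    Hd_sd: Optional[float] = None
    pi: Optional[float] = None
    pi_sd: Optional[float] = None
    n_dominant_species: Optional[int] = None
    dominant_cumulative_percent: Optional[float] = None
    inventory_size: Optional[int] = None
    shannon_H: Optional[float] = None
    TTD: Optional[float] = None
    sPhi_plus: Optional[float] = None
    trophic_mean: Optional[float] = None
    trophic_variance: Optional[float] = None
    network_observed_nodes: Optional[int] = None
    network_median_nodes: Optional[int] = None
    unavailable: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CommunityProfile":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def compute_profile(
    fasta,
    catch,
    taxonomy,
    trophic=None,
    config: ProfileConfig = ProfileConfig(),
) -> CommunityProfile:
    """Run the full pipeline on input files and assemble the profile.

    Species keys are joined across files by exact match after whitespace
    normalization and case-folding; join failures are collected and
    reported exhaustively before aborting.  By default only sequences of
    the dominant-species set enter the pooled-diversity block, mirroring a
    sampling design that targets the main commercial species.
    """
    records = read_fasta(fasta)
    catch_records = read_catch_table(catch)
    tax_records = read_taxonomy_table(taxonomy)
    trophic_records = read_trophic_table(trophic) if trophic is not None else None

    catch_keys = {normalize_species(r.species) for r in catch_records}
    tax_keys = {normalize_species(r.species) for r in tax_records}
    problems = []
    for sp in sorted({r.species for r in records}, key=normalize_species):
        key = normalize_species(sp)
        if key not in catch_keys:
            problems.append(f"species {sp!r} (FASTA) missing from catch table")
        if key not in tax_keys:
            problems.append(f"species {sp!r} (FASTA) missing from taxonomy table")
    if problems:
        raise ValueError("species join failed:\n  " + "\n  ".join(problems))

    profile = CommunityProfile(region=config.region, inventory_size=config.inventory_size)
    profile.provenance = {
        "fishmeta_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "fasta": _digest(fasta),
            "catch": _digest(catch),
            "taxonomy": _digest(taxonomy),
            **({"trophic": _digest(trophic)} if trophic is not None else {}),
        },
    }

    dominant = select_dominant_species(
        catch_records, config.threshold, total=config.total_catch
    )
    profile.n_dominant_species = len(dominant.species)
    profile.dominant_cumulative_percent = dominant.cumulative_percent
    dominant_keys = {normalize_species(s) for s in dominant.species}

    if config.include_all:
        kept = list(records)
    else:
        kept = [r for r in records if normalize_species(r.species) in dominant_keys]
    profile.n_sequences = len(kept)

    # pooled sequence diversity + network
    if len(kept) >= 2:
        seqs = AlignedSequenceSet.from_records(kept)
        summary, ht, pt = diversity_summary(seqs, config.frame)
        profile.k_haplotypes = summary.k
        profile.P_polypeptides = summary.P
        profile.haplotypes_per_polypeptide = summary.ratio
        profile.Hd, profile.Hd_sd = summary.Hd, summary.Hd_sd
        profile.pi, profile.pi_sd = summary.pi, summary.pi_sd
        network = median_joining_network(ht, config.epsilon)
        observed, median = count_nodes(network)
        profile.network_observed_nodes = observed
        profile.network_median_nodes = median
        profile._haplotype_table = ht
        profile._protein_table = pt
        profile._network = network
    else:
        reason = f"only {len(kept)} sequence(s) retained; need >= 2"
        for key in ("k_haplotypes", "P_polypeptides", "haplotypes_per_polypeptide",
                    "Hd", "Hd_sd", "pi", "pi_sd",
                    "network_observed_nodes", "network_median_nodes"):
            profile.unavailable[key] = reason

    # Shannon on the observed per-species sequence counts of the sample
    if kept:
        counts: dict[str, int] = {}
        for r in kept:
            counts[r.species] = counts.get(r.species, 0) + 1
        profile.shannon_H = shannon_index(counts).H
    else:
        profile.unavailable["shannon_H"] = "no sequences retained"

    # taxonomy-based indices on the dominant set
    tree = build_taxonomy_tree(tax_records)
    missing_tax = [s for s in dominant.species if normalize_species(s) not in tree.lineages]
    if missing_tax:
        reason = f"dominant species missing from taxonomy: {missing_tax}"
        profile.unavailable["TTD"] = reason
        profile.unavailable["sPhi_plus"] = reason
    else:
        if len(dominant.species) >= 2:
            profile.TTD = total_taxonomic_distinctness(tree, dominant.species)
        else:
            profile.unavailable["TTD"] = "TTD needs at least 2 dominant species"
        profile.sPhi_plus = total_taxonomic_path_length(tree, dominant.species)

    # trophic summary of the dominant set
    if trophic_records is None:
        profile.unavailable["trophic_mean"] = "no trophic table supplied"
        profile.unavailable["trophic_variance"] = "no trophic table supplied"
    else:
        try:
            weights = (
                dict(zip(dominant.species, dominant.tonnages))
                if config.trophic_weighted
                else None
            )
            summary = mean_trophic_level(dominant.species, trophic_records, weights)
            profile.trophic_mean = summary.mean
            profile.trophic_variance = summary.variance
        except KeyError as exc:
            profile.unavailable["trophic_mean"] = str(exc)
            profile.unavailable["trophic_variance"] = str(exc)

    return profile


def protein_tree(profile: CommunityProfile, config: ProfileConfig = ProfileConfig()):
    """NJ tree (with bootstrap supports if configured) of a computed profile.

    Returns ``None``, with a reason string, when fewer than 3 polypeptide
    variants exist — with two or fewer protein variants there is no
    topology to infer.
    """
    pt = getattr(profile, "_protein_table", None)
    if pt is None or pt.P < 3:
        return None, f"need >= 3 polypeptide variants for a tree (have {0 if pt is None else pt.P})"
    if config.bootstrap_replicates > 0:
        tree = bootstrap_support(
            pt,
            model=config.tree_model,
            gamma_shape=config.gamma_shape,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
        )
    else:
        tree = neighbor_joining(
            protein_distance(pt, config.tree_model, config.gamma_shape)
        )
    return tree, None
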