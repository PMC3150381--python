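"""Synthetic multi-species barcode communities with controlled structure.

The generator emulates the sampling design of a barcode survey of a
fishery catch: a handful of dominant species, each contributing a number
of sequences proportional to its catch weight; within each species a small
set of distinct COI haplotypes with a skewed (geometric by default)
frequency profile; intra-specific variation that is mostly synonymous, so
that many DNA haplotypes collapse to few polypeptides; and inter-species
divergence that respects the taxonomy (congeners closer than confamilials,
and so on).

Every quantity the analysis pipeline estimates — haplotype count k,
polypeptide count P, k/P, and (asymptotically) Hd and pi — has a designed,
closed-form counterpart here, which is what makes parameter-recovery
testing possible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .catch_composition import DominantSet, allocate_samples
from .io_formats import (
    CatchRecord,
    SequenceRecord,
    TaxonomyRecord,
    TrophicRecord,
    write_fasta,
)
from .sequence_diversity import VERTEBRATE_MITO_TABLE, translate_coi

__all__ = [
    "SpeciesSpec",
    "CommunitySpec",
    "generate_ancestors",
    "generate_haplotypes",
    "generate_community",
    "generate_dataset",
    "expected_haplotype_distribution",
]

_BASES = "ACGT"
_STOPS_MITO = {"TAA", "TAG", "AGA", "AGG"}


@dataclass(frozen=True)
class SpeciesSpec:
    """Design of one species' contribution to the community sample."""

    species: str
    taxonomy: TaxonomyRecord
    tonnage: float
    n_haplotypes: int = 3
    frequency_profile: str = "geometric"  # or "uniform"
    geometric_ratio: float = 0.5
    n_nonsynonymous: int = 0
    mutation_steps: int = 1
    trophic_level: float = 3.0
    n_samples: Optional[int] = None  # explicit count; overrides allocation

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1:
            raise ValueError("n_haplotypes must be >= 1")
        if not 0 <= self.n_nonsynonymous < self.n_haplotypes:
            raise ValueError("n_nonsynonymous must be in [0, n_haplotypes)")
        if self.frequency_profile not in ("geometric", "uniform"):
            raise ValueError(f"unknown frequency profile {self.frequency_profile!r}")

    def haplotype_frequencies(self) -> np.ndarray:
        k = self.n_haplotypes
        if self.frequency_profile == "uniform":
            p = np.full(k, 1.0 / k)
        else:
            p = self.geometric_ratio ** np.arange(k)
            p = p / p.sum()
        return p


@dataclass(frozen=True)
class CommunitySpec:
    """Design of a whole synthetic community dataset."""

    species: tuple[SpeciesSpec, ...]
    length: int = 300
    divergence: int = 20
    n: int = 40
    seed: Optional[int] = None
    #: constrain inter-species divergence to synonymous changes, so all
    #: ancestors share one polypeptide (the Salmo trutta / S. salar situation)
    divergence_synonymous: bool = False

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ValueError("barcode length must be a codon multiple")
        if self.divergence < 1:
            raise ValueError("divergence must be >= 1")

    @classmethod
    def from_json(cls, path) -> "CommunitySpec":
        raw = json.loads(Path(path).read_text())
        species = tuple(
            SpeciesSpec(
                species=s["species"],
                taxonomy=TaxonomyRecord(**s["taxonomy"]),
                tonnage=s["tonnage"],
                n_haplotypes=s.get("n_haplotypes", 3),
                frequency_profile=s.get("frequency_profile", "geometric"),
                geometric_ratio=s.get("geometric_ratio", 0.5),
                n_nonsynonymous=s.get("n_nonsynonymous", 0),
                mutation_steps=s.get("mutation_steps", 1),
                trophic_level=s.get("trophic_level", 3.0),
                n_samples=s.get("n_samples"),
            )
            for s in raw["species"]
        )
        return cls(
            species=species,
            length=raw.get("length", 300),
            divergence=raw.get("divergence", 20),
            n=raw.get("n", 40),
            seed=raw.get("seed"),
            divergence_synonymous=raw.get("divergence_synonymous", False),
        )


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS_MITO:
            return codon


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_random_codon(rng) for _ in range(length // 3))


def _mutate_codon(codon: str, rng: np.random.Generator, synonymous: Optional[bool] = None) -> Optional[str]:
    """A single-base change of ``codon``; constrain synonymy if requested."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate(table=VERTEBRATE_MITO_TABLE))
    options = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            cand = codon[:pos] + b + codon[pos + 1 :]
            if cand in _STOPS_MITO:
                continue
            cand_aa = str(Seq(cand).translate(table=VERTEBRATE_MITO_TABLE))
            if synonymous is True and cand_aa != aa:
                continue
            if synonymous is False and cand_aa == aa:
                continue
            options.append(cand)
    if not options:
        return None
    return options[rng.integers(len(options))]


class _CodonPool:
    """Hands out unused codon indices so mutations never interfere."""

    def __init__(self, n_codons: int):
        self.free = list(range(n_codons))

    def take(self, rng: np.random.Generator) -> int:
        if not self.free:
            raise ValueError(
                "sequence too short for the requested mutations; increase length"
            )
        return self.free.pop(rng.integers(len(self.free)))


def _rank_steps(divergence: int) -> dict[str, int]:
    """Mutation counts added along each taxonomic branch, by rank.

    Species branches carry half the minimum divergence each (two species
    branches meet at any LCA, so every pair is at least ``divergence``
    apart); every higher rank adds one further mutation per branch, so the
    deeper the lowest common taxon the strictly larger the distance —
    congeners end up closer than confamilials, and so on up the ranks.
    """
    base = max(1, -(-divergence // 2))  # ceil
    return {"species": base, "genus": 1, "family": 1, "order": 1, "class_": 1, "phylum": 1}


def _apply_mutations(
    seq: str,
    n_mut: int,
    pool: _CodonPool,
    rng: np.random.Generator,
    synonymous: Optional[bool] = None,
) -> str:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    applied = 0
    tried: list[int] = []
    while applied < n_mut:
        idx = pool.take(rng)
        mutated = _mutate_codon(codons[idx], rng, synonymous)
        if mutated is None:
            tried.append(idx)
            continue
        codons[idx] = mutated
        applied += 1
    pool.free.extend(tried)
    return "".join(codons)


def generate_ancestors(
    spec: CommunitySpec, rng: Optional[np.random.Generator] = None
) -> dict[str, str]:
    """One stop-free ancestral coding sequence per species.

    Sequences diverge along the taxonomy: a shared root sequence is
    mutated at every taxonomic split, each branch drawing fresh codon
    positions, so pairwise Hamming distances are exact sums of branch
    mutations and closer ranks imply strictly smaller distances.
    """
    rng = rng or np.random.default_rng(spec.seed)
    root = _random_coding_sequence(spec.length, rng)
    pool = _CodonPool(spec.length // 3)
    steps = _rank_steps(spec.divergence)
    synonymous = True if spec.divergence_synonymous else None

    # walk the taxonomy top-down; every distinct taxon gets a mutated copy
    # of its parent's sequence, drawn at fresh codon positions, so pairwise
    # distances are exact sums over the two branch paths below the LCA
    seq_at: dict[tuple[str, ...], str] = {(): root}
    ranks = ("phylum", "class_", "order", "family", "genus", "species")
    for depth, rank in enumerate(ranks):
        groups: dict[tuple[str, ...], str] = {}
        for sp in spec.species:
            lineage = sp.taxonomy.lineage()[: depth + 1]
            if lineage in groups:
                continue
            parent = seq_at[lineage[:-1]]
            groups[lineage] = _apply_mutations(
                parent, steps[rank], pool, rng, synonymous=synonymous
            )
        seq_at.update(groups)

    out = {}
    for sp in spec.species:
        out[sp.species] = seq_at[sp.taxonomy.lineage()]
    # verify the divergence floor and stop-free frame 1
    for a, b in itertools.combinations(spec.species, 2):
        d = sum(x != y for x, y in zip(out[a.species], out[b.species]))
        if d < spec.divergence:
            raise ValueError(
                f"ancestors of {a.species!r} and {b.species!r} differ at {d} sites "
                f"< required divergence {spec.divergence}"
            )
    for name, seq in out.items():
        translate_coi(seq, frame=1)  # raises on internal stops
    return out


def generate_haplotypes(
    ancestor: str,
    k: int,
    synonymous_only: bool = True,
    n_nonsynonymous: int = 0,
    mutation_steps: int = 1,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[str]:
    """k distinct haplotypes derived from one ancestral sequence.

    Haplotype 0 is the ancestor itself.  Every further haplotype draws
    ``mutation_steps`` changes at fresh codon positions (distinctness by
    construction).  With ``synonymous_only`` all changes preserve the
    vertebrate-mitochondrial translation; otherwise the last
    ``n_nonsynonymous`` haplotypes each carry one amino-acid-changing
    substitution, so the design yields exactly ``1 + n_nonsynonymous``
    protein variants.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng or np.random.default_rng(seed)
    pool = _CodonPool(len(ancestor) // 3)
    haps = [ancestor]
    n_nonsyn = 0 if synonymous_only else n_nonsynonymous
    for i in range(1, k):
        hap = _apply_mutations(ancestor, mutation_steps, pool, rng, synonymous=True)
        if i >= k - n_nonsyn:
            hap = _apply_mutations(hap, 1, pool, rng, synonymous=False)
        haps.append(hap)
    return haps


def _realize_haplotypes(
    spec: CommunitySpec, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Draw ancestors and per-species haplotype sets, in spec order."""
    ancestors = generate_ancestors(spec, rng)
    return {
        sp.species: generate_haplotypes(
            ancestors[sp.species],
            sp.n_haplotypes,
            synonymous_only=sp.n_nonsynonymous == 0,
            n_nonsynonymous=sp.n_nonsynonymous,
            mutation_steps=sp.mutation_steps,
            rng=rng,
        )
        for sp in spec.species
    }


def expected_haplotype_distribution(spec: CommunitySpec) -> tuple[list[str], np.ndarray]:
    """Designed sampling distribution over the community's haplotypes.

    Returns the haplotype sequences and the probability that a randomly
    drawn sequence of the dataset equals each of them, combining the
    per-species sample shares with the within-species frequency profiles.
    The same PRNG path as :func:`generate_community` is replayed, so the
    sequences coincide with the dataset's.  Used for closed-form
    expectations of Hd and pi.
    """
    counts = _sample_counts(spec)
    n = sum(counts.values())
    haplotypes = _realize_haplotypes(spec, np.random.default_rng(spec.seed))
    seqs: list[str] = []
    probs: list[float] = []
    for sp in spec.species:
        share = counts[sp.species] / n if n else 0.0
        for h, p in zip(haplotypes[sp.species], sp.haplotype_frequencies()):
            seqs.append(h)
            probs.append(share * p)
    return seqs, np.asarray(probs)


def _sample_counts(spec: CommunitySpec) -> dict[str, int]:
    explicit = [sp.n_samples for sp in spec.species]
    if all(c is not None for c in explicit):
        return {sp.species: int(sp.n_samples) for sp in spec.species}
    if any(c is not None for c in explicit):
        raise ValueError("set n_samples for all species or for none")
    if spec.n == 0:
        return {sp.species: 0 for sp in spec.species}
    dom = DominantSet(
        species=tuple(sp.species for sp in spec.species),
        tonnages=tuple(sp.tonnage for sp in spec.species),
        fractions=tuple(
            sp.tonnage / sum(s.tonnage for s in spec.species) for sp in spec.species
        ),
        cumulative_percent=100.0,
        threshold=1.0,
    )
    return allocate_samples(dom, spec.n).counts


@dataclass
class SyntheticCommunity:
    """In-memory realization of a community spec."""

    records: list[SequenceRecord]
    catch: list[CatchRecord]
    taxonomy: list[TaxonomyRecord]
    trophic: list[TrophicRecord]
    haplotypes: dict[str, list[str]] = field(default_factory=dict)
    sample_counts: dict[str, int] = field(default_factory=dict)


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Draw a full dataset: sequences plus catch/taxonomy/trophic tables.

    One PRNG stream (from ``spec.seed``) drives everything; species are
    processed in spec order, so results are fully reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    haplotypes = _realize_haplotypes(spec, rng)
    counts = _sample_counts(spec)

    records: list[SequenceRecord] = []
    sample_no = 0
    for sp in spec.species:
        haps = haplotypes[sp.species]
        freqs = sp.haplotype_frequencies()
        for _ in range(counts[sp.species]):
            sample_no += 1
            hap = haps[rng.choice(len(haps), p=freqs)]
            records.append(
                SequenceRecord(
                    sample_id=f"S{sample_no:04d}", species=sp.species, sequence=hap
                )
            )

    catch = [CatchRecord(sp.species, sp.tonnage) for sp in spec.species]
    taxonomy = [sp.taxonomy for sp in spec.species]
    trophic = [TrophicRecord(sp.species, sp.trophic_level) for sp in spec.species]
    return SyntheticCommunity(records, catch, taxonomy, trophic, haplotypes, counts)


def generate_dataset(spec: CommunitySpec, out_dir) -> dict[str, Path]:
    """Write the dataset files (FASTA + three TSV tables) and return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    community = generate_community(spec)

    paths = {
        "fasta": out_dir / "sequences.fasta",
        "catch": out_dir / "catch.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "trophic": out_dir / "trophic.tsv",
    }
    write_fasta(community.records, paths["fasta"])
    catch_lines = ["species\ttonnage"] + [
        f"{r.species}\t{r.tonnage}" for r in community.catch
    ]
    paths["catch"].write_text("\n".join(catch_lines) + "\n")
    tax_lines = ["species\tgenus\tfamily\torder\tclass\tphylum"] + [
        f"{t.species}\t{t.genus}\t{t.family}\t{t.order}\t{t.class_}\t{t.phylum}"
        for t in community.taxonomy
    ]
    paths["taxonomy"].write_text("\n".join(tax_lines) + "\n")
    trophic_lines = ["species\ttrophic_level"] + [
        f"{t.species}\t{t.trophic_level}" for t in community.trophic
    ]
    paths["trophic"].write_text("\n".join(trophic_lines) + "\n")
    return paths
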