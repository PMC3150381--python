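"""Pooled ("metagenomic") sequence diversity of a multi-species barcode sample.

All sequences of a regional catch are treated together, without separating
species: unique DNA haplotypes are collapsed by exact identity, haplotypic
diversity Hd and per-site nucleotide diversity pi are estimated with Nei's
sample-corrected formulas, haplotypes are translated under the vertebrate
mitochondrial code, and the haplotypes-per-polypeptide ratio summarizes how
much of the DNA-level variation is synonymous (hidden at the protein level).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import SequenceRecord

__all__ = [
    "AlignedSequenceSet",
    "Haplotype",
    "HaplotypeTable",
    "ProteinVariant",
    "ProteinTable",
    "DiversitySummary",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "translate_coi",
    "detect_frame",
    "collapse_proteins",
    "haplotypes_per_protein",
    "diversity_summary",
]

_UNAMBIGUOUS = frozenset("ACGT")
#: NCBI translation table 2
VERTEBRATE_MITO_TABLE = 2


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length, species-labelled DNA sequences (pre-aligned barcodes)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) != 1:
                raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")
            if self.length == 0:
                raise ValueError("zero-length alignment")

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "AlignedSequenceSet":
        return cls(tuple(records))

    @property
    def length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def n(self) -> int:
        return len(self.records)


@dataclass
class Haplotype:
    sequence: str
    count: int
    species: set[str] = field(default_factory=set)


@dataclass
class HaplotypeTable:
    """Unique DNA haplotypes of the pooled sample with their sample counts."""

    haplotypes: list[Haplotype]
    length: int

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def counts(self) -> np.ndarray:
        return np.asarray([h.count for h in self.haplotypes], dtype=float)


@dataclass
class ProteinVariant:
    sequence: str
    count: int
    species: set[str] = field(default_factory=set)


@dataclass
class ProteinTable:
    proteins: list[ProteinVariant]

    @property
    def P(self) -> int:
        return len(self.proteins)

    @property
    def n(self) -> int:
        return sum(p.count for p in self.proteins)


@dataclass(frozen=True)
class DiversitySummary:
    """The pooled-diversity block of a community profile."""

    k: int
    P: int
    ratio: float
    Hd: float
    Hd_sd: float
    pi: float
    pi_sd: float
    n: int


def _is_ambiguous(seq: str) -> bool:
    return any(c not in _UNAMBIGUOUS for c in seq)


def _compatible(ambig: str, hap: str) -> bool:
    """True if the two states agree at every site where both are unambiguous."""
    return all(
        a == b
        for a, b in zip(ambig, hap)
        if a in _UNAMBIGUOUS and b in _UNAMBIGUOUS
    )


def collapse_haplotypes(seqs: AlignedSequenceSet) -> HaplotypeTable:
    """Collapse the pooled sample into unique haplotypes.

    Unambiguous sequences collapse by exact string identity.  A sequence
    containing ``N`` or ``-`` is merged into an existing haplotype only if
    it is compatible (identical at all mutually unambiguous sites) with
    exactly *one* of them; otherwise it stays a distinct haplotype.
    Unambiguous sequences are processed first so that ambiguity never
    absorbs a cleanly determined state.
    """
    table: list[Haplotype] = []
    index: dict[str, Haplotype] = {}

    for rec in seqs.records:
        if _is_ambiguous(rec.sequence):
            continue
        hap = index.get(rec.sequence)
        if hap is None:
            hap = Haplotype(rec.sequence, 0)
            index[rec.sequence] = hap
            table.append(hap)
        hap.count += 1
        hap.species.add(rec.species)

    for rec in seqs.records:
        if not _is_ambiguous(rec.sequence):
            continue
        hap = index.get(rec.sequence)
        if hap is None:
            matches = [h for h in table if _compatible(rec.sequence, h.sequence)]
            if len(matches) == 1:
                hap = matches[0]
            else:
                hap = Haplotype(rec.sequence, 0)
                index[rec.sequence] = hap
                table.append(hap)
        hap.count += 1
        hap.species.add(rec.species)

    return HaplotypeTable(table, seqs.length)


def haplotype_diversity(ht: HaplotypeTable) -> tuple[float, float]:
    """Nei's haplotype (gene) diversity with its sampling standard deviation.

    Hd = n/(n−1) · (1 − Σ p_i²); the variance is Nei's (1987) estimator

        V(Hd) = 2/(n(n−1)) · [ 2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)² ].
    """
    n = ht.n
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got {n}")
    p = ht.counts() / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    hd = n / (n - 1) * (1.0 - sum2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    return hd, float(np.sqrt(max(var, 0.0)))


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def nucleotide_diversity(seqs: AlignedSequenceSet) -> tuple[float, float]:
    """Per-site nucleotide diversity pi over all C(n,2) sequence pairs.

    Each pair contributes its proportion of differing sites among the sites
    where both sequences are unambiguous (pairwise deletion of N and gaps).
    The standard deviation uses Nei's (1987) sampling variance

        V(pi) = (n+1)/(3(n−1)L) · pi + 2(n²+n+3)/(9n(n−1)) · pi².

    Internally identical sequences are grouped first, so cost scales with
    the number of distinct sequences, not the sample size.
    """
    n = seqs.n
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got {n}")
    L = seqs.length

    uniq: dict[str, int] = {}
    for rec in seqs.records:
        uniq[rec.sequence] = uniq.get(rec.sequence, 0) + 1
    states = list(uniq.keys())
    counts = np.asarray([uniq[s] for s in states], dtype=float)
    arrays = [_seq_array(s) for s in states]
    valid = [np.isin(a, [b"A", b"C", b"G", b"T"]) for a in arrays]

    total = 0.0
    for i, j in itertools.combinations(range(len(states)), 2):
        both = valid[i] & valid[j]
        comparable = int(both.sum())
        if comparable == 0:
            raise ValueError(
                "a sequence pair shares no unambiguous site; pi undefined"
            )
        diffs = int((arrays[i][both] != arrays[j][both]).sum())
        total += counts[i] * counts[j] * diffs / comparable

    npairs = n * (n - 1) / 2.0
    pi = total / npairs
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + 2.0 * (n**2 + n + 3) / (
        9.0 * n * (n - 1)
    ) * pi**2
    return float(pi), float(np.sqrt(max(var, 0.0)))


def _translate_frame(seq: str, offset: int) -> str:
    body = seq[offset:]
    body = body[: len(body) - len(body) % 3]
    if not body:
        raise ValueError("sequence too short to translate in this frame")
    # gaps inside codons are treated as missing data
    return str(Seq(body.replace("-", "N")).translate(table=VERTEBRATE_MITO_TABLE))


def detect_frame(seq: str) -> int:
    """Reading frame (1-based) with zero internal stop codons.

    Barcode amplicons do not start in-frame universally, so the frame is
    inferred; exactly one stop-free frame must exist.
    """
    good = [f for f in (1, 2, 3) if "*" not in _translate_frame(seq, f - 1)]
    if len(good) != 1:
        raise ValueError(
            f"frame detection failed: {len(good)} stop-free frames "
            f"({good or 'none'}); force a frame explicitly"
        )
    return good[0]


def translate_coi(seq: str, frame: int | str = "auto") -> str:
    """Translate a COI barcode under the vertebrate mitochondrial code.

    ``frame`` is 1, 2, 3 or ``"auto"``.  A trailing partial codon is
    dropped; codons containing ambiguity translate to ``X``.  An internal
    stop in a forced frame is an error (in the vertebrate mitochondrial
    code AGA/AGG are stops and TGA is tryptophan).
    """
    if frame == "auto":
        frame = detect_frame(seq)
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2, 3 or 'auto', got {frame!r}")
    protein = _translate_frame(seq, frame - 1)
    if "*" in protein:
        raise ValueError(
            f"internal stop codon at protein position {protein.index('*')} in frame {frame}"
        )
    return protein


def _consensus_frame(sequences: Sequence[str], frame: int | str) -> int:
    """A single frame valid (stop-free) for every haplotype of an alignment."""
    if frame != "auto":
        return int(frame)
    good = []
    for f in (1, 2, 3):
        try:
            for s in sequences:
                if "*" in _translate_frame(s, f - 1):
                    break
            else:
                good.append(f)
        except ValueError:
            continue
    if len(good) != 1:
        raise ValueError(
            f"frame detection over the alignment failed: {len(good)} stop-free "
            f"frames ({good or 'none'})"
        )
    return good[0]


def collapse_proteins(ht: HaplotypeTable, frame: int | str = "auto") -> ProteinTable:
    """Translate haplotypes and collapse to unique polypeptide variants.

    With ``frame="auto"`` one consensus frame is required to be stop-free
    across *all* haplotypes (they are aligned, hence share a frame).
    """
    f = _consensus_frame([h.sequence for h in ht.haplotypes], frame)
    table: list[ProteinVariant] = []
    index: dict[str, ProteinVariant] = {}
    for hap in ht.haplotypes:
        try:
            protein = translate_coi(hap.sequence, f)
        except ValueError as exc:
            raise ValueError(
                f"haplotype {hap.sequence[:20]}... failed translation: {exc}"
            ) from exc
        var = index.get(protein)
        if var is None:
            var = ProteinVariant(protein, 0)
            index[protein] = var
            table.append(var)
        var.count += hap.count
        var.species |= hap.species
    return ProteinTable(table)


def haplotypes_per_protein(ht: HaplotypeTable, pt: ProteinTable) -> float:
    """k/P — distinct DNA haplotypes per distinct polypeptide variant."""
    if pt.P < 1:
        raise ValueError("no protein variants")
    return ht.k / pt.P


def diversity_summary(
    seqs: AlignedSequenceSet, frame: int | str = "auto"
) -> tuple[DiversitySummary, HaplotypeTable, ProteinTable]:
    """Full pooled-diversity block: k, P, k/P, Hd (sd), pi (sd)."""
    ht = collapse_haplotypes(seqs)
    pt = collapse_proteins(ht, frame)
    hd, hd_sd = haplotype_diversity(ht)
    pi, pi_sd = nucleotide_diversity(seqs)
    summary = DiversitySummary(
        k=ht.k,
        P=pt.P,
        ratio=haplotypes_per_protein(ht, pt),
        Hd=hd,
        Hd_sd=hd_sd,
        pi=pi,
        pi_sd=pi_sd,
        n=seqs.n,
    )
    return summary, ht, pt
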