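"""Readers and writers for every external representation the pipeline touches.

Sequences travel as FASTA with a fixed header dialect
``>sample_id|Genus_species[|region]`` (underscores in the species field are
read as spaces).  Catch statistics, taxonomy and trophic levels are
tab-separated tables with required headers; community profiles are written
as JSON (round-trip safe) or flat TSV; trees as newick; haplotype networks
as an edge list or GML.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "CatchRecord",
    "TaxonomyRecord",
    "TrophicRecord",
    "FormatError",
    "normalize_species",
    "read_fasta",
    "write_fasta",
    "read_catch_table",
    "read_taxonomy_table",
    "read_trophic_table",
    "write_profile",
    "read_profile",
    "write_newick",
    "write_network",
    "read_network_edges",
]

_DNA_ALPHABET = frozenset("ACGTN-")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


def normalize_species(name: str) -> str:
    """Normalization used to join species keys across input files.

    Collapses internal whitespace and case-folds; scientific names are
    treated as authoritative and no common-name resolution is attempted.
    """
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class SequenceRecord:
    """One sequenced individual: a species-labelled aligned barcode read."""

    sample_id: str
    species: str
    sequence: str
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for sample {self.sample_id!r}")
        if not self.species.strip():
            raise FormatError(f"empty species for sample {self.sample_id!r}")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"illegal character {self.sequence[pos]!r} at position {pos} "
                f"in sequence of sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class CatchRecord:
    """A species and its annual catch tonnage."""

    species: str
    tonnage: float

    def __post_init__(self) -> None:
        if self.tonnage < 0:
            raise FormatError(
                f"negative tonnage {self.tonnage} for species {self.species!r}"
            )


#: the six Linnean ranks of a taxonomy record, most inclusive first
TAXONOMY_RANKS = ("phylum", "class_", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonomyRecord:
    """Fixed six-rank Linnean lineage for one species."""

    species: str
    genus: str
    family: str
    order: str
    class_: str
    phylum: str

    def __post_init__(self) -> None:
        for rank in TAXONOMY_RANKS:
            if not getattr(self, rank).strip():
                raise FormatError(
                    f"empty {rank.rstrip('_')} in taxonomy of {self.species!r}"
                )

    def lineage(self) -> tuple[str, ...]:
        """Lineage from phylum down to species."""
        return tuple(getattr(self, rank) for rank in TAXONOMY_RANKS)


@dataclass(frozen=True)
class TrophicRecord:
    species: str
    trophic_level: float

    def __post_init__(self) -> None:
        if not self.trophic_level > 0:
            raise FormatError(
                f"trophic level must be positive, got {self.trophic_level} "
                f"for {self.species!r}"
            )


# ---------------------------------------------------------------------------
# FASTA

_HEADER_RE = re.compile(r"^(?P<sample>[^|]+)\|(?P<species>[^|]+)(?:\|(?P<region>[^|]*))?$")


def read_fasta(path) -> list[SequenceRecord]:
    """Read species-labelled barcode sequences.

    Headers must follow ``sample_id|Genus_species[|region]``; underscores in
    the species field become spaces and sequences are upper-cased.  Input
    order is preserved.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        m = _HEADER_RE.match(header)
        if m is None:
            raise FormatError(f"malformed FASTA header (expected 'sample_id|Genus_species[|region]'): >{header}")
        species = m.group("species").replace("_", " ").strip()
        if not species:
            raise FormatError(f"missing species field in FASTA header: >{header}")
        region = m.group("region")
        records.append(
            SequenceRecord(
                sample_id=m.group("sample").strip(),
                species=species,
                sequence=str(rec.seq).upper(),
                region=region.strip() if region else None,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records in the dialect :func:`read_fasta` reads back."""
    out = []
    for r in records:
        header = f"{r.sample_id}|{r.species.replace(' ', '_')}"
        if r.region:
            header += f"|{r.region}"
        out.append(_BioSeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(out, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# tables


def _read_table(path, columns: tuple[str, ...], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_number(text: str, context: str) -> float:
    """Parse a numeral that may carry thousands separators ('16,086')."""
    cleaned = text.strip().replace(",", "") if re.fullmatch(r"[\d,]+(\.\d+)?", text.strip()) else text.strip()
    try:
        return float(cleaned)
    except ValueError:
        raise FormatError(f"unparseable number {text!r} in {context}") from None


def read_catch_table(path, sep: str = "\t") -> list[CatchRecord]:
    """Read a species → annual-tonnage table (TSV by default)."""
    df = _read_table(path, ("species", "tonnage"), sep)
    records, seen = [], set()
    for _, row in df.iterrows():
        sp = " ".join(str(row["species"]).split())
        key = normalize_species(sp)
        if key in seen:
            raise FormatError(f"duplicate species {sp!r} in catch table")
        seen.add(key)
        records.append(CatchRecord(sp, _parse_number(str(row["tonnage"]), f"tonnage of {sp!r}")))
    return records


def _check_hierarchy(records: list[TaxonomyRecord]) -> None:
    # every taxon must have a unique parent one rank up
    for child_rank, parent_rank in zip(TAXONOMY_RANKS[::-1], TAXONOMY_RANKS[-2::-1]):
        parent_of: dict[str, str] = {}
        for r in records:
            child, parent = getattr(r, child_rank), getattr(r, parent_rank)
            if child in parent_of and parent_of[child] != parent:
                raise FormatError(
                    f"inconsistent taxonomy: {child_rank.rstrip('_')} {child!r} mapped to "
                    f"both {parent_of[child]!r} and {parent!r} at rank {parent_rank.rstrip('_')}"
                )
            parent_of[child] = parent


def read_taxonomy_table(path, sep: str = "\t") -> list[TaxonomyRecord]:
    """Read six-rank lineages; the class column may be named 'class' or 'class_'."""
    df = _read_table(path, ("species", "genus", "family", "order", "phylum"), sep)
    if "class" in df.columns:
        df = df.rename(columns={"class": "class_"})
    if "class_" not in df.columns:
        raise FormatError(f"{path}: missing required column(s) ['class']")
    records = [
        TaxonomyRecord(
            species=" ".join(str(row["species"]).split()),
            genus=str(row["genus"]).strip(),
            family=str(row["family"]).strip(),
            order=str(row["order"]).strip(),
            class_=str(row["class_"]).strip(),
            phylum=str(row["phylum"]).strip(),
        )
        for _, row in df.iterrows()
    ]
    _check_hierarchy(records)
    return records


def read_trophic_table(path, sep: str = "\t") -> list[TrophicRecord]:
    df = _read_table(path, ("species", "trophic_level"), sep)
    return [
        TrophicRecord(
            " ".join(str(row["species"]).split()),
            _parse_number(str(row["trophic_level"]), f"trophic level of {row['species']!r}"),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# profile / tree / network output


def write_profile(profile, path, format: str = "json") -> None:
    """Serialize a community profile as JSON (round-trip safe) or flat TSV."""
    data = profile.to_dict() if hasattr(profile, "to_dict") else dict(profile)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        lines = ["field\tvalue"]
        for key, value in data.items():
            lines.append(f"{key}\t{json.dumps(value, sort_keys=True)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown profile format {format!r}")


def read_profile(path):
    """Load a JSON profile written by :func:`write_profile`."""
    from .profile_pipeline import CommunityProfile

    return CommunityProfile.from_dict(json.loads(Path(path).read_text()))


def write_newick(tree, path) -> None:
    """Write a scikit-bio ``TreeNode`` (or anything with ``.write``) as newick."""
    tree.write(str(path), format="newick")


def write_network(graph: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Write a haplotype network as a TSV edge list or GML.

    Nodes carry ``kind`` (observed|median), ``count`` and ``species``
    attributes; edges carry a ``mutations`` label.
    """
    path = Path(path)
    if format == "edge_tsv":
        lines = ["state_a\tstate_b\tmutations"]
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((u, v))
            lines.append(f"{a}\t{b}\t{data['mutations']}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "gml":
        g = nx.Graph()
        for node, data in graph.nodes(data=True):
            g.add_node(
                node,
                kind=data.get("kind", "observed"),
                count=int(data.get("count", 0)),
                species=",".join(sorted(data.get("species", ()))),
            )
        for u, v, data in graph.edges(data=True):
            g.add_edge(u, v, mutations=int(data["mutations"]))
        nx.write_gml(g, str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_edges(path) -> list[tuple[str, str, int]]:
    """Read back an ``edge_tsv`` network edge list."""
    lines = Path(path).read_text().strip().splitlines()
    if lines and lines[0] == "state_a\tstate_b\tmutations":
        lines = lines[1:]
    edges = []
    for line in lines:
        a, b, m = line.split("\t")
        edges.append((a, b, int(m)))
    return edges


def dataclass_to_dict(obj) -> dict:
    return dataclasses.asdict(obj)
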