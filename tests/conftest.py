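import pytest

from fishmeta.io_formats import SequenceRecord, TaxonomyRecord
from fishmeta.sequence_diversity import AlignedSequenceSet
from fishmeta.synthetic_community import CommunitySpec, SpeciesSpec


def aligned(*seqs: str, species: str = "Test sp") -> AlignedSequenceSet:
    """Quick aligned sample from plain sequence strings."""
    return AlignedSequenceSet.from_records(
        tuple(
            SequenceRecord(sample_id=f"s{i}", species=species, sequence=s)
            for i, s in enumerate(seqs)
        )
    )


def _chordate(species, genus, family, order):
    return TaxonomyRecord(species, genus, family, order, "Actinopterygii", "Chordata")


@pytest.fixture
def salmonid_taxonomy():
    """Two congeneric salmonids (the river-fishery species pair)."""
    return [
        _chordate("Salmo trutta", "Salmo", "Salmonidae", "Salmoniformes"),
        _chordate("Salmo salar", "Salmo", "Salmonidae", "Salmoniformes"),
    ]


@pytest.fixture
def cantabric_taxonomy():
    """Four marine species: two confamilial scombrids plus two further orders."""
    return [
        _chordate("Scomber scombrus", "Scomber", "Scombridae", "Perciformes"),
        _chordate("Thunnus alalunga", "Thunnus", "Scombridae", "Perciformes"),
        _chordate("Sardina pilchardus", "Sardina", "Clupeidae", "Clupeiformes"),
        _chordate("Micromesistius poutassou", "Micromesistius", "Gadidae", "Gadiformes"),
    ]


@pytest.fixture
def river_community_spec(salmonid_taxonomy):
    """Two congeners sharing one polypeptide: 38 + 2 samples, 3 + 1 haplotypes.

    Mirrors a river sport fishery dominated by brown trout with a small
    Atlantic salmon catch; all variation (within and between species) is
    synonymous, so the pooled sample holds 4 haplotypes but 1 protein.
    """
    trutta, salar = salmonid_taxonomy
    return CommunitySpec(
        species=(
            SpeciesSpec(
                "Salmo trutta", trutta, tonnage=348.6, n_haplotypes=3,
                n_samples=38, trophic_level=3.5,
            ),
            SpeciesSpec(
                "Salmo salar", salar, tonnage=9.2, n_haplotypes=1,
                n_samples=2, trophic_level=4.4,
            ),
        ),
        length=300,
        divergence=8,
        n=40,
        seed=11,
        divergence_synonymous=True,
    )
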