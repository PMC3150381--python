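import itertools
import random

import numpy as np
import pytest

from fishmeta.io_formats import TaxonomyRecord
from fishmeta.taxonomic_distinctness import (
    STEP_WEIGHT,
    build_taxonomy_tree,
    path_weight,
    path_weight_matrix,
    total_taxonomic_distinctness,
    total_taxonomic_path_length,
)


def _rec(species, genus=None, family=None, order=None, class_=None, phylum=None):
    return TaxonomyRecord(
        species,
        genus or f"G_{species}",
        family or f"F_{species}",
        order or f"O_{species}",
        class_ or f"C_{species}",
        phylum or f"P_{species}",
    )


class TestTreeConstruction:
    def test_two_congeners_have_seven_edges(self, salmonid_taxonomy):
        assert build_taxonomy_tree(salmonid_taxonomy).n_edges == 7

    def test_single_species_has_six_edges(self):
        assert build_taxonomy_tree([_rec("Solo sp")]).n_edges == 6

    def test_two_phyla_have_twelve_edges(self):
        tree = build_taxonomy_tree([_rec("Sp one"), _rec("Sp two")])
        assert tree.n_edges == 12

    def test_inconsistent_hierarchy_rejected(self):
        records = [
            TaxonomyRecord("A sp", "Ga", "Fa", "Oa", "Ca", "Pa"),
            TaxonomyRecord("B sp", "Ga", "Fb", "Oa", "Ca", "Pa"),
        ]
        with pytest.raises(ValueError, match="Ga"):
            build_taxonomy_tree(records)


class TestPathWeight:
    def test_same_species_is_zero(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        assert path_weight(tree, "Salmo trutta", "Salmo trutta") == 0.0

    def test_congeners(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        assert path_weight(tree, "Salmo trutta", "Salmo salar") == pytest.approx(
            STEP_WEIGHT
        )

    def test_confamilials(self, cantabric_taxonomy):
        tree = build_taxonomy_tree(cantabric_taxonomy)
        assert path_weight(tree, "Scomber scombrus", "Thunnus alalunga") == pytest.approx(
            2 * STEP_WEIGHT
        )

    def test_different_phyla_score_100(self):
        tree = build_taxonomy_tree([_rec("Sp one"), _rec("Sp two")])
        assert path_weight(tree, "Sp one", "Sp two") == pytest.approx(100.0)

    def test_unknown_species_errors(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        with pytest.raises(KeyError):
            path_weight(tree, "Salmo trutta", "Missing sp")


def _random_taxonomy(rng, n_species):
    """Random nested taxonomy with shared taxa at every rank."""
    records = []
    for i in range(n_species):
        phylum = f"P{rng.randint(0, 1)}"
        class_ = f"{phylum}C{rng.randint(0, 1)}"
        order = f"{class_}O{rng.randint(0, 1)}"
        family = f"{order}F{rng.randint(0, 1)}"
        genus = f"{family}G{rng.randint(0, 1)}"
        records.append(TaxonomyRecord(f"sp{i}", genus, family, order, class_, phylum))
    return records


class TestTTD:
    def test_two_congeners(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        ttd = total_taxonomic_distinctness(tree, ["Salmo trutta", "Salmo salar"])
        assert round(ttd, 1) == 33.3

    def test_four_marine_species(self, cantabric_taxonomy):
        tree = build_taxonomy_tree(cantabric_taxonomy)
        ttd = total_taxonomic_distinctness(tree, [r.species for r in cantabric_taxonomy])
        assert round(ttd, 1) == 244.4

    def test_all_different_phyla_gives_100_per_species(self):
        for s in (2, 4, 6):
            records = [_rec(f"sp{i}") for i in range(s)]
            tree = build_taxonomy_tree(records)
            ttd = total_taxonomic_distinctness(tree, [r.species for r in records])
            assert ttd == pytest.approx(100.0 * s)

    def test_matches_brute_force_double_loop(self):
        rng = random.Random(99)
        for _ in range(10):
            records = _random_taxonomy(rng, rng.randint(2, 6))
            tree = build_taxonomy_tree(records)
            species = [r.species for r in records]
            expected = 0.0
            for i, a in enumerate(species):
                acc = sum(
                    path_weight(tree, a, b) for j, b in enumerate(species) if j != i
                )
                expected += acc / (len(species) - 1)
            assert total_taxonomic_distinctness(tree, species) == pytest.approx(expected)

    def test_adding_new_phylum_strictly_increases_ttd(self):
        rng = random.Random(5)
        records = _random_taxonomy(rng, 4)
        species = [r.species for r in records]
        tree_small = build_taxonomy_tree(records)
        extended = records + [_rec("Alien sp")]
        tree_big = build_taxonomy_tree(extended)
        assert total_taxonomic_distinctness(
            tree_big, species + ["Alien sp"]
        ) > total_taxonomic_distinctness(tree_small, species)

    def test_fewer_than_two_species_errors(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        with pytest.raises(ValueError):
            total_taxonomic_distinctness(tree, ["Salmo trutta"])


class TestOmegaUltrametricity:
    def test_random_taxonomies_are_ultrametric(self):
        rng = random.Random(17)
        for _ in range(10):
            records = _random_taxonomy(rng, 6)
            tree = build_taxonomy_tree(records)
            omega, labels = path_weight_matrix(tree, [r.species for r in records])
            for i, j, k in itertools.permutations(range(len(labels)), 3):
                assert omega[i, k] <= max(omega[i, j], omega[j, k]) + 1e-9


class TestTotalPathLength:
    def test_two_congeners(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        value = total_taxonomic_path_length(tree, ["Salmo trutta", "Salmo salar"])
        assert round(value, 1) == 116.7

    def test_four_marine_species(self, cantabric_taxonomy):
        tree = build_taxonomy_tree(cantabric_taxonomy)
        value = total_taxonomic_path_length(tree, [r.species for r in cantabric_taxonomy])
        assert round(value, 1) == 266.7

    def test_single_species_scores_100(self):
        tree = build_taxonomy_tree([_rec("Solo sp")])
        assert total_taxonomic_path_length(tree, ["Solo sp"]) == pytest.approx(100.0)

    def test_monotone_under_adding_species(self):
        rng = random.Random(23)
        records = _random_taxonomy(rng, 6)
        tree = build_taxonomy_tree(records)
        species = [r.species for r in records]
        values = [
            total_taxonomic_path_length(tree, species[: i + 1])
            for i in range(len(species))
        ]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_adding_congener_adds_exactly_one_step(self, salmonid_taxonomy):
        tree = build_taxonomy_tree(salmonid_taxonomy)
        one = total_taxonomic_path_length(tree, ["Salmo trutta"])
        two = total_taxonomic_path_length(tree, ["Salmo trutta", "Salmo salar"])
        assert two - one == pytest.approx(STEP_WEIGHT)
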