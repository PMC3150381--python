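import itertools
import random

import numpy as np
import pytest

from conftest import aligned
from fishmeta.sequence_diversity import (
    HaplotypeTable,
    collapse_haplotypes,
    collapse_proteins,
    detect_frame,
    haplotype_diversity,
    haplotypes_per_protein,
    nucleotide_diversity,
    translate_coi,
)


class TestCollapseHaplotypes:
    def test_identical_sequences_collapse(self):
        ht = collapse_haplotypes(aligned(*(["ACGT"] * 5)))
        assert ht.k == 1 and ht.haplotypes[0].count == 5

    def test_distinct_sequences_kept(self):
        ht = collapse_haplotypes(aligned("ACGT", "ACGT", "ACGA"))
        assert ht.k == 2
        assert sorted(h.count for h in ht.haplotypes) == [1, 2]

    def test_ambiguous_merges_into_unique_compatible(self):
        ht = collapse_haplotypes(aligned("ACGT", "ACGN", "AGGT"))
        assert ht.k == 2
        assert sorted(h.count for h in ht.haplotypes) == [1, 2]

    def test_ambiguous_with_two_compatible_stays_distinct(self):
        # ACNT is compatible with both ACGT and ACAT
        ht = collapse_haplotypes(aligned("ACGT", "ACAT", "ACNT"))
        assert ht.k == 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            aligned("ACGT", "ACG")

    def test_species_sets_recorded(self):
        from fishmeta.io_formats import SequenceRecord
        from fishmeta.sequence_diversity import AlignedSequenceSet

        seqs = AlignedSequenceSet.from_records(
            (
                SequenceRecord("a", "Sp one", "ACGT"),
                SequenceRecord("b", "Sp two", "ACGT"),
            )
        )
        ht = collapse_haplotypes(seqs)
        assert ht.haplotypes[0].species == {"Sp one", "Sp two"}


class TestHaplotypeDiversity:
    def test_all_unique_gives_exactly_one(self):
        # algebraic identity: (n/(n-1)) * (1 - 1/n) = 1
        for n in (2, 5, 17):
            states = itertools.islice(itertools.product("ACGT", repeat=4), n)
            ht = collapse_haplotypes(aligned(*("".join(c) for c in states)))
            hd, _ = haplotype_diversity(ht)
            assert hd == pytest.approx(1.0)

    def test_single_haplotype_gives_zero(self):
        hd, sd = haplotype_diversity(collapse_haplotypes(aligned("AAAA", "AAAA")))
        assert hd == 0.0 and sd == 0.0

    def test_two_plus_two(self):
        hd, _ = haplotype_diversity(collapse_haplotypes(aligned("ACGT", "ACGT", "ACGA", "ACGA")))
        assert hd == pytest.approx(4 / 3 * 0.5)

    def test_sample_duplication_changes_only_the_bias_factor(self):
        seqs = ["ACGT", "ACGA", "ACGA", "TCGA"]
        hd1, _ = haplotype_diversity(collapse_haplotypes(aligned(*seqs)))
        hd2, _ = haplotype_diversity(collapse_haplotypes(aligned(*(seqs * 2))))
        n = len(seqs)
        expected_ratio = (2 * n / (2 * n - 1)) / (n / (n - 1))
        assert hd2 / hd1 == pytest.approx(expected_ratio)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            haplotype_diversity(collapse_haplotypes(aligned("ACGT")))


def brute_force_pi(seqs):
    """Independent oracle: double loop over pairs and sites."""
    total, pairs = 0.0, 0
    for a, b in itertools.combinations(seqs, 2):
        diffs = comparable = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                comparable += 1
                diffs += x != y
        total += diffs / comparable
        pairs += 1
    return total / pairs


class TestNucleotideDiversity:
    def test_identical_sequences_give_zero(self):
        pi, sd = nucleotide_diversity(aligned("ACGT", "ACGT", "ACGT"))
        assert pi == 0.0

    def test_single_pair(self):
        pi, _ = nucleotide_diversity(aligned("AAAAAAAAAA", "AAAAAAAAAT"))
        assert pi == pytest.approx(0.1)

    def test_four_sequence_example(self):
        pi, _ = nucleotide_diversity(aligned("AAAA", "AAAT", "AATT", "TTTT"))
        assert pi == pytest.approx((0.25 + 0.5 + 1.0 + 0.25 + 0.75 + 0.5) / 6)

    def test_matches_brute_force_oracle_on_random_samples(self):
        rng = random.Random(202)
        for _ in range(20):
            n = rng.randint(2, 8)
            L = rng.randint(4, 20)
            seqs = [
                "".join(rng.choice("ACGTACGTN") for _ in range(L)) for _ in range(n)
            ]
            # ensure every pair is comparable somewhere
            seqs = [s[:-1] + "A" for s in seqs]
            assert nucleotide_diversity(aligned(*seqs))[0] == pytest.approx(
                brute_force_pi(seqs)
            )

    def test_permutation_invariance(self):
        seqs = ["ACGT", "AAGT", "ACTT", "ACGA"]
        pi1, _ = nucleotide_diversity(aligned(*seqs))
        pi2, _ = nucleotide_diversity(aligned(*reversed(seqs)))
        assert pi1 == pytest.approx(pi2)

    def test_zero_comparable_sites_errors(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(aligned("ANNN", "NAAA", "NTTT"))


class TestTranslation:
    def test_basic_codons(self):
        assert translate_coi("ATGGCC", 1) == "MA"

    def test_tga_is_tryptophan_in_vertebrate_mitochondria(self):
        assert translate_coi("TGA", 1) == "W"

    def test_aga_is_a_stop_in_vertebrate_mitochondria(self):
        with pytest.raises(ValueError, match="stop"):
            translate_coi("AGA", 1)

    def test_ambiguous_codon_translates_to_x(self):
        assert translate_coi("ATGNNN", 1) == "MX"

    def test_trailing_partial_codon_dropped(self):
        assert translate_coi("ATGGCCA", 1) == "MA"

    def test_frame_auto_detection(self):
        # frame 1 starts TAG (stop), frame 2 starts AGA (stop); frame 3 reads GAA TGG
        seq = "TAGAATGGCC"
        assert detect_frame(seq) == 3
        assert translate_coi(seq, "auto") == "EW"

    def test_frame_auto_ambiguous_errors(self):
        with pytest.raises(ValueError, match="frame"):
            translate_coi("AAAAAA", "auto")  # every frame stop-free


class TestProteins:
    def test_synonymous_third_positions_collapse(self):
        # CTT/CTC/CTA all encode Leu
        ht = collapse_haplotypes(aligned("CTTATG", "CTCATG", "CTAATG"))
        pt = collapse_proteins(ht, frame=1)
        assert pt.P == 1 and pt.proteins[0].count == 3

    def test_identical_protein_across_species_merges(self):
        from fishmeta.io_formats import SequenceRecord
        from fishmeta.sequence_diversity import AlignedSequenceSet

        seqs = AlignedSequenceSet.from_records(
            (
                SequenceRecord("a", "Salmo trutta", "CTTATG"),
                SequenceRecord("b", "Salmo salar", "CTCATG"),
            )
        )
        pt = collapse_proteins(collapse_haplotypes(seqs), frame=1)
        assert pt.P == 1
        assert pt.proteins[0].species == {"Salmo trutta", "Salmo salar"}

    def test_nonsynonymous_changes_stay_distinct(self):
        ht = collapse_haplotypes(aligned("ATGGCC", "ATGTCC", "ATGCCC"))
        pt = collapse_proteins(ht, frame=1)
        assert pt.P == 3

    def test_ratio(self):
        ht = collapse_haplotypes(aligned("CTTATG", "CTCATG", "CTAATG", "CTGATG"))
        pt = collapse_proteins(ht, frame=1)
        assert haplotypes_per_protein(ht, pt) == pytest.approx(4.0)

    def test_ratio_is_at_least_one(self):
        # translation is a function of the DNA sequence, so k >= P
        rng = random.Random(7)
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        codons = [c for c in codons if c not in ("TAA", "TAG", "AGA", "AGG")]
        for _ in range(10):
            seqs = ["".join(rng.choice(codons) for _ in range(5)) for _ in range(6)]
            ht = collapse_haplotypes(aligned(*seqs))
            pt = collapse_proteins(ht, frame=1)
            assert haplotypes_per_protein(ht, pt) >= 1.0
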