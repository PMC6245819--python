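"""Genetic-code engine: substitution outcomes, potential sites, composition."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mutburden import codon
from mutburden.codon import (
    CodingSequence,
    SubstitutionClass,
    classify_substitution,
    composition_stats,
    conservation_index,
    count_potential_sites,
    nonsense_capable_codons,
    read_cds_fasta,
    sequence_features,
)


def oracle_classify(ref_codon: str, pos: int, alt: str) -> SubstitutionClass:
    """Independent route: mutate the string, translate with Biopython."""
    alt_codon = ref_codon[:pos] + alt + ref_codon[pos + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return SubstitutionClass.SILENT
    if alt_aa == "*":
        return SubstitutionClass.NONSENSE
    if ref_aa == "*":
        return SubstitutionClass.STOP_LOSS
    return SubstitutionClass.MISSENSE


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref,pos,alt,expected_codon,expected_class",
        [
            # arginine (CGG) -> glutamine (CAG): the classic oncogenic R->Q
            ("CGG", 1, "A", "CAG", SubstitutionClass.MISSENSE),
            ("CTG", 2, "A", "CTA", SubstitutionClass.SILENT),  # Leu -> Leu
            ("TGG", 1, "A", "TAG", SubstitutionClass.NONSENSE),  # Trp -> stop
            ("TAA", 2, "G", "TAG", SubstitutionClass.SILENT),  # stop retained
            ("TAA", 0, "C", "CAA", SubstitutionClass.STOP_LOSS),  # stop -> Gln
        ],
    )
    def test_examples(self, ref, pos, alt, expected_codon, expected_class):
        out = classify_substitution(ref, pos, alt)
        assert out.alt_codon == expected_codon
        assert out.klass is expected_class

    def test_case_insensitive(self):
        assert classify_substitution("cgg", 1, "a").klass is SubstitutionClass.MISSENSE

    @pytest.mark.parametrize(
        "ref,pos,alt",
        [("CGN", 1, "A"), ("CGG", 1, "G"), ("CGG", 3, "A"), ("CGG", 1, "X")],
    )
    def test_rejected_inputs(self, ref, pos, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, pos, alt)

    def test_agrees_with_translation_oracle_exhaustively(self):
        for ref in codon.ALL_CODONS:
            for pos in range(3):
                for alt in "ACGT":
                    if alt == ref[pos]:
                        continue
                    assert (
                        classify_substitution(ref, pos, alt).klass
                        is oracle_classify(ref, pos, alt)
                    )


def oracle_site_counts(sequence: str) -> dict[SubstitutionClass, int]:
    counts = {k: 0 for k in SubstitutionClass}
    for i in range(len(sequence)):
        for alt in "ACGT":
            if alt == sequence[i]:
                continue
            ref_codon = sequence[3 * (i // 3) : 3 * (i // 3) + 3]
            counts[oracle_classify(ref_codon, i % 3, alt)] += 1
    return counts


class TestPotentialSites:
    def test_single_codon_atg(self):
        # ATG encodes Met alone; every substitution changes the amino acid
        sites = count_potential_sites(CodingSequence("m", "ATG"))
        assert sites.n_total_sns == 9
        assert sites.n_missense == 9
        assert sites.n_nonsense == sites.n_silent == sites.n_stop_loss == 0

    def test_three_codon_example_matches_oracle(self):
        seq = "ATGTGGTAA"
        sites = count_potential_sites(CodingSequence("g", seq))
        oracle = oracle_site_counts(seq)
        assert sites.n_total_sns == 3 * len(seq) == 27
        assert sites.n_missense == oracle[SubstitutionClass.MISSENSE]
        assert sites.n_nonsense == oracle[SubstitutionClass.NONSENSE]
        assert sites.n_silent == oracle[SubstitutionClass.SILENT]
        assert sites.n_stop_loss == oracle[SubstitutionClass.STOP_LOSS]

    def test_random_cds_agree_with_brute_force(self, rng):
        for _ in range(100):
            n = 3 * int(rng.integers(1, 101))  # up to 300 nt
            seq = "".join(rng.choice(list("ACGT"), size=n))
            sites = count_potential_sites(CodingSequence("r", seq))
            oracle = oracle_site_counts(seq)
            assert sites.n_missense == oracle[SubstitutionClass.MISSENSE]
            assert sites.n_nonsense == oracle[SubstitutionClass.NONSENSE]
            assert sites.n_silent == oracle[SubstitutionClass.SILENT]
            assert sites.n_stop_loss == oracle[SubstitutionClass.STOP_LOSS]

    @given(st.text(alphabet="ACGT", min_size=3, max_size=120).filter(lambda s: len(s) % 3 == 0))
    @settings(max_examples=50, derandomize=True)
    def test_partition_sums_to_3n(self, seq):
        sites = count_potential_sites(CodingSequence("p", seq))
        total = sites.n_missense + sites.n_nonsense + sites.n_silent + sites.n_stop_loss
        assert total == sites.n_total_sns == 3 * len(seq)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            CodingSequence("bad", "ATGA")


class TestNonsenseCapableCodons:
    def test_exactly_21_members(self):
        assert len(nonsense_capable_codons()) == 21

    def test_known_members_and_non_members(self):
        capable = nonsense_capable_codons()
        assert {"TGG", "TAC", "TCA"} <= capable
        assert "ATG" not in capable

    def test_membership_matches_enumeration(self):
        capable = nonsense_capable_codons()
        for ref in codon.ALL_CODONS:
            reachable = any(
                ref[:p] + alt + ref[p + 1 :] in codon.STOP_CODONS
                for p in range(3)
                for alt in "ACGT"
                if alt != ref[p]
            )
            assert (ref in capable) == reachable


class TestComposition:
    def test_equal_composition_maximizes_nd(self):
        stats = composition_stats(CodingSequence("e", "ACGTACGTACGT"))
        assert stats.nd == pytest.approx(0.75)

    def test_homopolymer(self):
        stats = composition_stats(CodingSequence("h", "AAAAAA"))
        assert stats.p_a == 1.0
        assert stats.nd == 0.0
        assert stats.cpg_fraction == 0.0

    def test_cg_repeat(self):
        stats = composition_stats(CodingSequence("c", "CGCGCG"))
        assert stats.cpg_fraction == pytest.approx(0.5)
        assert stats.nd == pytest.approx(0.5)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=300).filter(lambda s: len(s) % 3 == 0))
    @settings(max_examples=100, derandomize=True)
    def test_invariants(self, seq):
        stats = composition_stats(CodingSequence("q", seq))
        assert stats.p_a + stats.p_c + stats.p_g + stats.p_t == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= stats.nd <= 0.75
        single_base = max(stats.p_a, stats.p_c, stats.p_g, stats.p_t) == 1.0
        assert (stats.nd == 0.0) == single_base
        # ND equals the direct two-draw collision complement
        assert stats.nd == pytest.approx(
            1 - (stats.p_a**2 + stats.p_c**2 + stats.p_g**2 + stats.p_t**2)
        )

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            CodingSequence("n", "ATGNNN")


class TestConservationIndex:
    @pytest.mark.parametrize(
        "n_orth,expected", [(0, 1), (1, 1), (2, 2), (3, 2), (4, 3), (20, 11)]
    )
    def test_binning_rule(self, n_orth, expected):
        assert conservation_index(n_orth).index == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            conservation_index(-1)


class TestFastaIngestion:
    def test_longest_transcript_kept_with_tie_break(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(
            ">GENE1|t1\nATGTAA\n"
            ">GENE1|t2\nATGAAATAA\n"
            ">GENE2|b\nATGTGGTAA\n"
            ">GENE2|a\nATGCCCTAA\n"  # same length as |b: smaller id wins
            ">GENE3\nATGTAG\n"
        )
        genes = read_cds_fasta(fa)
        assert genes["GENE1"].sequence == "ATGAAATAA"
        assert genes["GENE2"].sequence == "ATGCCCTAA"
        assert genes["GENE3"].length_nt == 6

    def test_feature_table_columns(self):
        df = sequence_features([CodingSequence("a", "ATGTGGTAA")])
        assert list(df.columns) == codon.SEQUENCE_FEATURE_COLUMNS
        assert df.loc["a", "cds_length"] == 9
        # partition again, through the table
        assert (
            df.loc["a", ["n_potential_missense", "n_potential_nonsense", "n_potential_silent"]].sum()
            <= 27
        )
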