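import itertools

import pytest

from macontrast import (
    CodonChange,
    CodonStatus,
    CodonUsageTable,
    GeneAnnotation,
    Genome,
    MutationRecord,
    SubstitutionClass,
    codon_change_of,
    collapse_substitution,
    gc_composition_test,
    plant_mutations,
    revcomp,
    summarize_spectrum,
    tally_usage_vectors,
    usage_vector,
)
from macontrast.spectra_codon import UsageVector

BASES = "ACGT"
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class TestCollapseSubstitution:
    @pytest.mark.parametrize(
        "ref, alt, klass, transition",
        [
            ("G", "A", SubstitutionClass.GC_TO_AT, True),
            ("C", "T", SubstitutionClass.GC_TO_AT, True),
            ("A", "G", SubstitutionClass.AT_TO_GC, True),
            ("A", "T", SubstitutionClass.AT_TO_TA, False),
            ("G", "C", SubstitutionClass.GC_TO_CG, False),
            ("C", "A", SubstitutionClass.GC_TO_TA, False),
        ],
    )
    def test_examples(self, ref, alt, klass, transition):
        c = collapse_substitution(ref, alt)
        assert c is klass
        assert c.is_transition is transition

    def test_strand_collapse_symmetry_all_12_pairs(self):
        """Complementing both bases never changes the base-pair class."""
        for ref, alt in itertools.permutations(BASES, 2):
            assert collapse_substitution(ref, alt) is collapse_substitution(
                COMPLEMENT[ref], COMPLEMENT[alt]
            )

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            collapse_substitution("A", "A")


class TestSummarizeSpectrum:
    def test_empty_input_all_zero(self):
        s = summarize_spectrum([])
        assert s.n_total == 0
        assert all(v == 0 for v in s.counts.values())

    def test_counts_sum_and_grouping(self):
        recs = [
            MutationRecord("a", 1, "G", "A"),
            MutationRecord("b", 2, "C", "A"),
            MutationRecord("c", 3, "A", "G"),
            MutationRecord("d", 4, "T", "A"),
        ]
        s = summarize_spectrum(recs)
        assert s.n_total == 4
        assert s.gc_to_at_or_ta == 2  # G>A plus C>A
        assert s.transitions == 2

    def test_permutation_invariance(self):
        recs = [
            MutationRecord(f"r{i}", i + 1, ref, alt)
            for i, (ref, alt) in enumerate(itertools.permutations(BASES, 2))
        ]
        assert summarize_spectrum(recs).counts == summarize_spectrum(recs[::-1]).counts

    def test_planted_probabilities_recovered_within_3_sigma(self, genome_100k):
        probs = [0.45, 0.15, 0.05, 0.15, 0.05, 0.15]
        n = 1000
        recs = plant_mutations(genome_100k, n, probs, seed=77)
        s = summarize_spectrum(recs)
        for klass, p in zip(SubstitutionClass, probs):
            sd = (n * p * (1 - p)) ** 0.5
            assert abs(s.counts[klass] - n * p) <= 3 * sd


# NCBI amino-acid string for the standard code, codon order TTT, TTC, TTA,
# TTG, CTT, ... (bases ordered T, C, A, G). Independent of the Biopython
# table the implementation uses. The bacterial code (table 11) translates
# identically; it differs only in start codons.
_ORACLE_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORACLE_ORDER = "TCAG"


def oracle_translate(codon: str) -> str:
    i1, i2, i3 = (_ORACLE_ORDER.index(b) for b in codon)
    return _ORACLE_AA[16 * i1 + 4 * i2 + i3]


class TestCodonChange:
    @pytest.mark.parametrize(
        "before, after, status",
        [
            ("GAA", "GAG", CodonStatus.SYNONYMOUS),
            ("TGG", "TGA", CodonStatus.NONSENSE),
            ("AAA", "GAA", CodonStatus.MISSENSE),
        ],
    )
    def test_status_examples(self, before, after, status):
        assert CodonChange(before, after).status is status

    def test_all_549_changes_match_independent_oracle(self):
        """Status of every single-base change from a sense codon agrees with
        an independently coded genetic-code oracle."""
        n_checked = 0
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if oracle_translate(codon) == "*":
                continue
            for pos, alt in itertools.product(range(3), BASES):
                if alt == codon[pos]:
                    continue
                after = codon[:pos] + alt + codon[pos + 1 :]
                got = CodonChange(codon, after).status
                aa0, aa1 = oracle_translate(codon), oracle_translate(after)
                if aa1 == "*":
                    expect = CodonStatus.NONSENSE
                elif aa0 == aa1:
                    expect = CodonStatus.SYNONYMOUS
                else:
                    expect = CodonStatus.MISSENSE
                assert got is expect, f"{codon}->{after}"
                n_checked += 1
        assert n_checked == 549

    def test_multi_base_change_rejected(self):
        with pytest.raises(ValueError):
            CodonChange("AAA", "GGA")


class TestCodonChangeOf:
    def test_plus_strand_gene(self):
        #          123456789
        g = Genome("t", "AAATGGAAGAATAACCC")  # ATG GAA GAA TAA at 3..14
        gene = GeneAnnotation("g1", 3, 14, "+")
        rec = MutationRecord("m", 8, "A", "G")  # codon 2 GAA -> GAG
        change = codon_change_of(rec, g, gene)
        assert (change.codon_before, change.codon_after) == ("GAA", "GAG")
        assert change.status is CodonStatus.SYNONYMOUS

    def test_minus_strand_gene_read_on_coding_strand(self):
        # coding CDS ATG TGG TAA; the genome carries its reverse complement,
        # so codon 2 (TGG) appears as CCA on the forward strand at 6..8
        cds = "ATGTGGTAA"
        g = Genome("t", "CC" + revcomp(cds) + "GG")
        gene = GeneAnnotation("g1", 3, 11, "-")
        assert g.sequence[5:8] == "CCA"
        # forward A->T at position 8 is coding T->A at codon 2 position 1
        rec = MutationRecord("m", 8, "A", "T")
        change = codon_change_of(rec, g, gene)
        assert change.codon_before == "TGG"
        assert change.codon_after == "AGG"
        assert change.status is CodonStatus.MISSENSE

    def test_minus_strand_nonsense(self):
        cds = "ATGTGGTAA"
        g = Genome("t", "CC" + revcomp(cds) + "GG")
        gene = GeneAnnotation("g1", 3, 11, "-")
        # forward C->T at position 7 is coding G->A: TGG -> TAG (stop)
        rec = MutationRecord("m", 7, "C", "T")
        change = codon_change_of(rec, g, gene)
        assert (change.codon_before, change.codon_after) == ("TGG", "TAG")
        assert change.status is CodonStatus.NONSENSE

    def test_position_outside_gene(self, toy_genome):
        gene = GeneAnnotation("g1", 2, 7, "+")
        with pytest.raises(ValueError):
            codon_change_of(MutationRecord("m", 9, "C", "T"), toy_genome, gene)


class TestUsageVector:
    table = CodonUsageTable({"AAA": 0.75, "AAG": 0.25, "GGT": 0.5, "GGC": 0.5})

    def test_down_example(self):
        assert usage_vector(CodonChange("AAA", "AAG"), self.table, 1.5) is UsageVector.DOWN

    def test_up_antisymmetric(self):
        assert usage_vector(CodonChange("AAG", "AAA"), self.table, 1.5) is UsageVector.UP

    @pytest.mark.parametrize("rho", [1.0001, 1.5, 10.0])
    def test_equal_fractions_similar_for_any_rho(self, rho):
        assert usage_vector(CodonChange("GGT", "GGC"), self.table, rho) is UsageVector.SIMILAR

    def test_antisymmetry_over_all_synonymous_pairs(self, uniform_table):
        import random

        rng = random.Random(11)
        freqs = {c: rng.uniform(0.1, 10.0) for c in uniform_table.frequencies}
        table = CodonUsageTable(freqs)
        for before in list(freqs)[:200]:
            for pos, alt in itertools.product(range(3), BASES):
                if alt == before[pos]:
                    continue
                after = before[:pos] + alt + before[pos + 1 :]
                if after not in freqs:
                    continue
                change = CodonChange(before, after)
                if change.status is not CodonStatus.SYNONYMOUS:
                    continue
                fwd = usage_vector(change, table, 1.5)
                rev = usage_vector(CodonChange(after, before), table, 1.5)
                assert (fwd is UsageVector.DOWN) == (rev is UsageVector.UP)
                assert (fwd is UsageVector.SIMILAR) == (rev is UsageVector.SIMILAR)

    def test_non_synonymous_rejected(self):
        with pytest.raises(ValueError):
            usage_vector(CodonChange("AAA", "GAA"), self.table)

    def test_tally_splits_by_vector(self):
        changes = [
            CodonChange("AAA", "AAG"),  # down
            CodonChange("AAG", "AAA"),  # up
            CodonChange("GGT", "GGC"),  # similar
            CodonChange("AAA", "GAA"),  # missense: ignored
        ]
        t = tally_usage_vectors(changes, self.table, 1.5)
        assert (t.down, t.similar, t.up, t.n_synonymous) == (1, 1, 1, 3)


class TestGcCompositionTest:
    def test_center_is_one_under_doubling(self):
        # observed exactly n·p with integer expectation
        assert gc_composition_test(5, 10, 0.5) == 1.0

    def test_lacI_like_composition(self):
        """56.3% G·C over 1083 bp vs genomic 50.8%: exact binomial two-tail.

        Frozen from direct summation of the Binomial(1083, 0.508) tail
        (doubling convention): ≈3.0×10⁻⁴.
        """
        p = gc_composition_test(610, 1083, 0.508)
        assert p == pytest.approx(3.04e-4, rel=5e-3)

    def test_extreme_tail_closed_form(self):
        assert gc_composition_test(0, 10, 0.5) == pytest.approx(2 * 0.5**10)

    def test_minlike_alternative(self):
        from scipy.stats import binomtest

        assert gc_composition_test(610, 1083, 0.508, method="minlike") == pytest.approx(
            binomtest(610, 1083, 0.508).pvalue
        )
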