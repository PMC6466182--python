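"""Variant calling, homopolymer adjudication, coding effects, ORF accounting."""

import warnings

import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from phagemosaic.alignment import build_trio_alignment, classify_sites, find_homopolymer_runs
from phagemosaic.io import GenomeRecord, OrfRecord
from phagemosaic.variants import (
    VariantCall,
    adjudicate_variants,
    annotate_effect,
    call_variants,
    count_aa_differences,
    count_orf_crossovers,
)


def _pipeline_variants(a, b, r, min_len=4):
    aln = build_trio_alignment(a, b, r)
    sites = classify_sites(aln)
    return call_variants(
        sites,
        find_homopolymer_runs(a, min_len),
        find_homopolymer_runs(b, min_len),
    )


class TestCallVariants:
    def test_clean_substitution_has_zero_context(self):
        a = GenomeRecord("a", "ACGTACGTACGTGACGT")
        r = GenomeRecord("r", "ACGTACGTACGTTACGT")
        (v,) = _pipeline_variants(a, a, r)
        assert v.kind == "substitution" and v.homopolymer_context == 0
        assert (v.allele_a, v.allele_r) == ("G", "T")

    def test_deletion_in_shared_homopolymer_run(self):
        a = GenomeRecord("a", "ACGTCGTGCAAAAAGTACGTCACGTGACTG")
        r = GenomeRecord("r", "ACGTCGTGCAAAAGTACGTCACGTGACTG")  # one A dropped
        (v,) = _pipeline_variants(a, a, r)
        assert v.kind == "indel" and v.homopolymer_context == 5

    def test_triallelic_column_is_a_variant_not_a_vote(self):
        a = GenomeRecord("a", "ACGTAACGTACGTACGTACGT")
        b = GenomeRecord("b", "ACGTACCGTACGTACGTACGT")
        r = GenomeRecord("r", "ACGTATCGTACGTACGTACGT")
        aln = build_trio_alignment(a, b, r)
        sites = classify_sites(aln)
        assert sum(1 for s in sites if s.is_informative) == 0
        (v,) = call_variants(sites, [], [])
        assert v.kind == "substitution" and (v.allele_a, v.allele_b, v.allele_r) == (
            "A",
            "C",
            "T",
        )

    def test_no_calls_from_informative_sites(self, toy_trio):
        a, b, r = toy_trio
        assert _pipeline_variants(a, b, r) == []


class TestAdjudicate:
    @pytest.mark.parametrize(
        "kind,context,expected",
        [
            ("substitution", 0, "accepted_mutation"),
            ("substitution", 7, "accepted_mutation"),  # never auto-suspected
            ("indel", 5, "suspected_error"),
            ("indel", 3, "accepted_mutation"),
        ],
    )
    def test_rule(self, kind, context, expected):
        v = VariantCall(10, "A", "A", "T" if kind == "substitution" else "",
                        kind, context)
        (out,) = adjudicate_variants([v], min_run=4)
        assert out.status == expected

    def test_idempotent_and_status_only(self):
        v = VariantCall(10, "AA", "AA", "A", "indel", 6)
        once = adjudicate_variants([v])
        twice = adjudicate_variants(once)
        assert once == twice
        assert once[0] == v.__class__(**{**v.__dict__, "status": "suspected_error"})


class TestAnnotateEffect:
    ORF = OrfRecord("orf1", 1, 9)
    GENOME = GenomeRecord("r", "ATGGTTTAACCCCC")  # codons ATG GTT TAA

    def _sub(self, pos, parent_base, r_base):
        return VariantCall(pos, parent_base, parent_base, r_base, "substitution", 0)

    def test_missense(self):
        # parents had GCT (Ala) at codon 2; recombinant carries GTT (Val)
        v = annotate_effect(self._sub(5, "C", "T"), [self.ORF], self.GENOME)
        assert v.effect == "missense"

    def test_synonymous(self):
        # recombinant GTT vs parental GTC: both Val
        v = annotate_effect(self._sub(6, "C", "T"), [self.ORF], self.GENOME)
        assert v.effect == "synonymous"

    def test_nonsense(self):
        # recombinant TAA at codon 2 (GTT -> TTT would be Phe; use G->T at 4 then
        # construct a genome whose codon 2 is TAA only in the recombinant)
        genome = GenomeRecord("r", "ATGTAATAACC")
        v = annotate_effect(self._sub(4, "G", "T"), [OrfRecord("o", 1, 9)], genome)
        assert v.effect == "nonsense"

    def test_intergenic(self):
        v = annotate_effect(self._sub(12, "C", "A"), [self.ORF], self.GENOME)
        assert v.effect == "intergenic"

    def test_beyond_genome_rejected(self):
        with pytest.raises(ValueError, match="beyond genome"):
            annotate_effect(self._sub(99, "C", "A"), [self.ORF], self.GENOME)

    @pytest.mark.parametrize("delta_len,expected",
                             [(1, "frameshift_candidate"), (3, "missense")])
    def test_indel_in_frame_vs_frameshift(self, delta_len, expected):
        v = VariantCall(5, "G" * delta_len, "G" * delta_len, "", "indel", 0)
        out = annotate_effect(v, [self.ORF], self.GENOME)
        assert out.effect == expected

    def test_reverse_strand_codon_logic(self):
        # reverse ORF 9->1; recombinant gene reads ATG AAT TAA, parents had
        # G at genome position 4, i.e. gene codon2 AAC: Asn->Asn, synonymous
        genome = GenomeRecord("r", "TTAATTCATCC")
        orf = OrfRecord("o", 9, 1)
        v = annotate_effect(self._sub(4, "G", "A"), [orf], genome)
        assert v.effect == "synonymous"

    def test_engineered_synonymous_never_missense_across_code(self):
        # all 64 codons x all single-base changes, vs a direct translation oracle
        bases = "ACGT"
        for c1 in bases:
            for c2 in bases:
                for c3 in bases:
                    codon = c1 + c2 + c3
                    genome = GenomeRecord("r", codon + "TAA")
                    orf = OrfRecord("o", 1, 6)
                    for i in range(3):
                        for alt in bases:
                            if alt == codon[i]:
                                continue
                            mutant = codon[:i] + alt + codon[i + 1 :]
                            rec = GenomeRecord("r", mutant + "TAA")
                            v = VariantCall(i + 1, codon[i], codon[i], alt,
                                            "substitution", 0)
                            out = annotate_effect(v, [orf], rec)
                            same_aa = str(Seq(mutant).translate(table=11)) == str(
                                Seq(codon).translate(table=11)
                            )
                            if same_aa:
                                assert out.effect == "synonymous", (codon, mutant)
                            else:
                                assert out.effect in ("missense", "nonsense")


class TestCountOrfCrossovers:
    ORFS = [OrfRecord("01", 10, 39), OrfRecord("02", 70, 41), OrfRecord("03", 100, 129)]

    def test_assignment_and_intergenic_bucket(self):
        summ = count_orf_crossovers([15, 50, 45, 95], self.ORFS)
        by_id = {s.orf_id: s for s in summ}
        assert by_id["01"].n_crossovers == 1
        assert by_id["02"].crossover_positions == (45, 50)
        assert by_id["03"].n_crossovers == 0  # zero-count ORFs included
        assert by_id["IG02-03"].n_crossovers == 1 and by_id["IG02-03"].is_intergenic

    def test_empty_input_gives_all_zeros(self):
        summ = count_orf_crossovers([], self.ORFS)
        assert [s.n_crossovers for s in summ] == [0, 0, 0]

    def test_overlap_double_counts_with_warning(self):
        orfs = [OrfRecord("x", 1, 30), OrfRecord("y", 20, 50)]
        with pytest.warns(UserWarning, match="overlapping"):
            summ = count_orf_crossovers([25], orfs)
        assert sum(s.n_crossovers for s in summ) == 2

    @given(st.lists(st.integers(1, 150), max_size=30))
    def test_event_conservation(self, positions):
        summ = count_orf_crossovers(positions, self.ORFS)
        assert sum(s.n_crossovers for s in summ) == len(positions)


class TestCountAaDifferences:
    def test_identical_trio_has_no_differences(self):
        g = GenomeRecord("g", "ATGGCTGCTGCTGCTTAAACG")
        aln = build_trio_alignment(g, g, g)
        orf = OrfRecord("o", 1, 18)
        assert count_aa_differences(orf, aln, "A") == 0

    def test_engineered_differences_against_one_parent(self):
        # 9-codon ORF; parent B differs at two nonsynonymous and one synonymous codon
        r_seq = "ATGGCTGAAACCGGGTTTAAACTGTAA" + "CGA"
        b_seq = list(r_seq)
        b_seq[3] = "A"  # codon2 GCT->ACT (Thr vs Ala): nonsynonymous
        b_seq[8] = "G"  # codon3 GAA->GAG: synonymous
        b_seq[13] = "A"  # codon5 GGG->GAG (Glu vs Gly): nonsynonymous
        b = GenomeRecord("b", "".join(b_seq))
        r = GenomeRecord("r", r_seq)
        a = GenomeRecord("a", r_seq)
        aln = build_trio_alignment(a, b, r)
        orf = OrfRecord("o", 1, 27)
        assert count_aa_differences(orf, aln, "B") == 2
        assert count_aa_differences(orf, aln, "A") == 0

    def test_reverse_strand_matches_forward_complement(self):
        fwd_r = "ATGGCTGAAACCGGGTTTAAACTGTAA"
        fwd_b = "ATGACTGAAACCGGGTTTAAACTGTAA"  # one nonsyn change
        rc = lambda s: str(Seq(s).reverse_complement())
        pad = "CCGGA"
        r_f = GenomeRecord("r", fwd_r + pad)
        b_f = GenomeRecord("b", fwd_b + pad)
        aln_f = build_trio_alignment(b_f, b_f, r_f)
        n_f = count_aa_differences(OrfRecord("o", 1, 27), aln_f, "A")

        r_r = GenomeRecord("r", pad + rc(fwd_r))
        b_r = GenomeRecord("b", pad + rc(fwd_b))
        aln_r = build_trio_alignment(b_r, b_r, r_r)
        n_r = count_aa_differences(OrfRecord("o", 32, 6), aln_r, "A")
        assert n_f == n_r == 1

    def test_orf_past_genome_end_rejected(self):
        g = GenomeRecord("g", "ATGGCTTAA")
        aln = build_trio_alignment(g, g, g)
        with pytest.raises(ValueError, match="past genome end"):
            count_aa_differences(OrfRecord("o", 1, 12), aln, "A")

    def test_parental_gap_counts_as_difference_with_warning(self):
        r_seq = "ATGGCTGAAACCTAAGGCAT"
        a_seq = "ATGGCTGAACCTAAGGCAT"  # 1 bp deletion inside the ORF
        r = GenomeRecord("r", r_seq)
        a = GenomeRecord("a", a_seq)
        aln = build_trio_alignment(a, r, r)
        with pytest.warns(UserWarning, match="frameshift"):
            n = count_aa_differences(OrfRecord("o", 1, 15), aln, "A")
        assert n >= 1
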