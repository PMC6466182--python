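"""Trio alignment construction, site classification, homopolymer scanning."""

import re

import pytest
from hypothesis import given, strategies as st

from phagemosaic.alignment import (
    AlignmentError,
    GAP,
    build_trio_alignment,
    classify_sites,
    find_homopolymer_runs,
)
from phagemosaic.io import GenomeRecord
from phagemosaic.simulate import SyntheticConfig, generate_parent_pair, generate_recombinant


def _classes(sites):
    return {s.resolution for s in sites}


class TestBuildTrioAlignment:
    def test_identical_trio_has_no_gaps_and_no_signal(self):
        seq = ("ACGT" * 25)[:100]
        g = GenomeRecord("g", seq)
        aln = build_trio_alignment(g, g, g)
        assert aln.n_columns == 100
        assert GAP not in aln.row_a + aln.row_b + aln.row_r
        assert _classes(classify_sites(aln)) == {"uninformative"}

    def test_gapless_toy_coordinates_are_identity(self, toy_trio):
        a, b, r = toy_trio
        aln = build_trio_alignment(a, b, r)
        assert aln.n_columns == 12
        assert list(aln.pos_r) == list(range(1, 13))

    def test_single_deletion_in_recombinant(self):
        a = GenomeRecord("a", "ACGTACGTACGTACGTACGT")
        r = GenomeRecord("r", "ACGTACGTAGTACGTACGT")  # drop C at position 10
        aln = build_trio_alignment(a, a, r)
        assert aln.row_r.count(GAP) == 1
        assert aln.row_a.count(GAP) == 0
        events = [s for s in classify_sites(aln) if s.site_class == "gap_event"]
        assert len(events) == 1 and events[0].resolution == "neither_parent"

    def test_degapping_recovers_inputs(self):
        cfg = SyntheticConfig(rng_seed=11, genome_length=3000, n_crossovers=3)
        pa, pb = generate_parent_pair(cfg)
        rec, _ = generate_recombinant(pa, pb, cfg)
        aln = build_trio_alignment(pa, pb, rec)
        assert aln.degapped("A") == pa.sequence
        assert aln.degapped("B") == pb.sequence
        assert aln.degapped("R") == rec.sequence

    def test_prealigned_mode_roundtrip(self, toy_trio, tmp_path):
        a, b, r = toy_trio
        p = tmp_path / "aln.fasta"
        p.write_text(f">A\n{a.sequence}\n>B\n{b.sequence}\n>R\n{r.sequence}\n")
        aln = build_trio_alignment(a, b, r, mode="prealigned", prealigned=p)
        assert aln.n_columns == 12

    def test_prealigned_wrong_row_count(self, toy_trio, tmp_path):
        a, b, r = toy_trio
        p = tmp_path / "aln.fasta"
        p.write_text(f">A\n{a.sequence}\n>B\n{b.sequence}\n")
        with pytest.raises(AlignmentError, match="2 rows"):
            build_trio_alignment(a, b, r, mode="prealigned", prealigned=p)

    def test_prealigned_must_match_inputs(self, toy_trio):
        a, b, r = toy_trio
        rows = [a.sequence, b.sequence, "ACTTACGTACGA"]  # last base differs
        with pytest.raises(AlignmentError, match="does not reproduce"):
            build_trio_alignment(a, b, r, mode="prealigned", prealigned=rows)


class TestClassifySites:
    def test_toy_informative_sites(self, toy_trio):
        a, b, r = toy_trio
        sites = classify_sites(build_trio_alignment(a, b, r))
        by_pos = {s.r_position: s.resolution for s in sites}
        assert by_pos[3] == "inform_B" and by_pos[8] == "inform_A"
        others = [s for s in sites if s.r_position not in (3, 8)]
        assert all(s.resolution == "uninformative" for s in others)

    def test_neither_parent_column(self):
        a = GenomeRecord("a", "AAGAA")
        r = GenomeRecord("r", "AATAA")
        sites = classify_sites(build_trio_alignment(a, a, r))
        assert [s.resolution for s in sites] == ["uninformative"] * 2 + [
            "neither_parent"
        ] + ["uninformative"] * 2

    def test_contiguous_gap_run_collapses_to_one_event(self):
        a = GenomeRecord("a", "ACGTACGTTTACGTACGT")
        r = GenomeRecord("r", "ACGTACGACGTACGT")  # 3 bp deletion
        aln = build_trio_alignment(a, a, r)
        events = [s for s in classify_sites(aln) if s.site_class == "gap_event"]
        assert len(events) == 1 and events[0].width == 3

    def test_parent_specific_indel_is_informative(self):
        # B carries an insertion the recombinant also lacks -> informative for A
        a = GenomeRecord("a", "ACGTACGTACGTACGTACGT")
        b = GenomeRecord("b", "ACGTACGTACTTTGTACGTACGT")
        r = GenomeRecord("r", "ACGTACGTACGTACGTACGT")
        aln = build_trio_alignment(a, b, r)
        events = [s for s in classify_sites(aln) if s.site_class == "gap_event"]
        assert events and all(e.resolution == "inform_A" for e in events)

    def test_n_columns_are_uninformative(self):
        a = GenomeRecord("a", "AAGAA")
        b = GenomeRecord("b", "AATAA")
        r = GenomeRecord("r", "AANAA")
        sites = classify_sites(build_trio_alignment(a, b, r))
        assert all(s.resolution == "uninformative" for s in sites)

    def test_parent_swap_mirrors_labels(self):
        cfg = SyntheticConfig(rng_seed=5, genome_length=2000, n_crossovers=2)
        pa, pb = generate_parent_pair(cfg)
        rec, _ = generate_recombinant(pa, pb, cfg)
        fwd = classify_sites(build_trio_alignment(pa, pb, rec))
        swp = classify_sites(build_trio_alignment(pb, pa, rec))
        flip = {"inform_A": "inform_B", "inform_B": "inform_A"}
        fwd_labels = [
            (s.anchor_position, flip[s.resolution]) for s in fwd if s.is_informative
        ]
        swp_labels = [(s.anchor_position, s.resolution) for s in swp if s.is_informative]
        assert fwd_labels == swp_labels

    def test_site_bookkeeping_matches_mutation_count(self):
        # SNP-only parents: every parental difference is one informative site,
        # every de-novo substitution one neither-parent site
        cfg = SyntheticConfig(
            rng_seed=13, genome_length=4000, indel_rate=0.0, n_crossovers=3,
            n_mutations=2,
        )
        pa, pb = generate_parent_pair(cfg)
        rec, truth = generate_recombinant(pa, pb, cfg)
        n_diff = sum(x != y for x, y in zip(pa.sequence, pb.sequence))
        sites = classify_sites(build_trio_alignment(pa, pb, rec))
        n_inform = sum(1 for s in sites if s.is_informative)
        n_neither = sum(1 for s in sites if s.resolution == "neither_parent")
        assert n_inform == n_diff
        assert n_neither == len(truth.true_mutations)


class TestHomopolymerRuns:
    @pytest.mark.parametrize(
        "seq,min_len,expected",
        [
            ("AAAATTG", 4, [(1, 4, "A", 4)]),
            ("AAAATTTT", 4, [(1, 4, "A", 4), (5, 8, "T", 4)]),
            ("ACGT", 2, []),
            ("NNNNN", 2, []),
        ],
    )
    def test_examples(self, seq, min_len, expected):
        runs = find_homopolymer_runs(GenomeRecord("g", seq), min_len)
        assert [(r.start, r.end, r.base, r.run_length) for r in runs] == expected

    def test_min_len_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            find_homopolymer_runs(GenomeRecord("g", "AAAA"), 1)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=400), st.integers(2, 6))
    def test_matches_regex_scan_oracle(self, seq, min_len):
        oracle = [
            (m.start() + 1, m.end(), m.group()[0], len(m.group()))
            for m in re.finditer(r"(.)\1*", seq)
            if len(m.group()) >= min_len
        ]
        runs = find_homopolymer_runs(GenomeRecord("g", seq), min_len)
        assert [(r.start, r.end, r.base, r.run_length) for r in runs] == oracle
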