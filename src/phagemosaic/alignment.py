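"""Three-way alignment of two parent genomes against a recombinant.

The real inputs are near-identical (>99% nucleotide identity between the
two parents), so the internal aligner chains unique shared k-mers as
anchors and closes the inter-anchor gaps with exact global edit-distance
alignments (edlib), pairwise against the recombinant, then merges the two
pairwise alignments column-wise on the recombinant's coordinates.

Every column is classified by parental informativeness:

* ``uninformative`` — all three bases agree (or a column contains N);
* ``inform_A`` / ``inform_B`` — parents differ and the recombinant matches
  exactly one of them (the substrate of crossover inference);
* ``neither_parent`` — the recombinant matches neither parent (a candidate
  de-novo mutation or sequencing error);
* ``gap_event`` — a maximal run of columns gapped in the same subset of
  rows, collapsed into one record because a contiguous indel is a single
  evidentiary event, not one per base.  Each gap event additionally carries
  a ``resolution`` giving its evidentiary reading under the same matching
  rule (a parent-specific indel inherited by the recombinant is informative
  for that parent, gap status included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .io import GenomeRecord, read_fasta

GAP = "-"

SITE_CLASSES = ("uninformative", "inform_A", "inform_B", "neither_parent", "gap_event")


class AlignmentError(ValueError):
    """Inputs that cannot be aligned in the requested mode."""


# ---------------------------------------------------------------------------
# pairwise helpers


def pairwise_global(query: str, target: str) -> tuple[str, str]:
    """Optimal global (Needleman-Wunsch) alignment via edlib.

    Returns the two gapped rows.  Empty inputs are handled explicitly.
    """
    if not query and not target:
        return "", ""
    if not query:
        return GAP * len(target), target
    if not target:
        return query, GAP * len(query)
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"]


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    first: dict[str, int] = {}
    repeated: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in first:
            repeated.add(kmer)
        else:
            first[kmer] = i
    return {m: p for m, p in first.items() if m not in repeated}


def _anchor_chain(sa: str, sb: str, sr: str, k: int) -> list[tuple[int, int, int]]:
    """Greedy co-linear chain of k-mers unique in all three sequences.

    Returns 0-based (posA, posB, posR) triples, non-overlapping and strictly
    increasing in every coordinate.  Greedy selection by recombinant
    position is adequate for near-identical inputs.
    """
    ua, ub, ur = (
        _unique_kmer_positions(sa, k),
        _unique_kmer_positions(sb, k),
        _unique_kmer_positions(sr, k),
    )
    shared = set(ua) & set(ub) & set(ur)
    triples = sorted(((ur[m], ua[m], ub[m]) for m in shared))
    chain: list[tuple[int, int, int]] = []
    last_a = last_b = last_r = -1
    for pr, pa, pb in triples:
        if pa > last_a and pb > last_b and pr > last_r:
            chain.append((pa, pb, pr))
            last_a, last_b, last_r = pa + k - 1, pb + k - 1, pr + k - 1
    return chain


def _merge_on_ref(
    a_row: str, ra_row: str, b_row: str, rb_row: str
) -> tuple[list[str], list[str], list[str]]:
    """Merge two pairwise alignments that share the same reference sequence.

    ``(a_row, ra_row)`` aligns parent A against the recombinant and
    ``(b_row, rb_row)`` parent B; the degapped reference rows are identical.
    Insertions relative to the reference from the two parents at the same
    locus are co-aligned against each other, so a deletion shared by the
    recombinant yields matched parental columns rather than two staggered
    single-parent events.
    """
    out_a: list[str] = []
    out_b: list[str] = []
    out_r: list[str] = []
    i = j = 0
    na, nb = len(a_row), len(b_row)
    while i < na or j < nb:
        ins_a = []
        while i < na and ra_row[i] == GAP:
            ins_a.append(a_row[i])
            i += 1
        ins_b = []
        while j < nb and rb_row[j] == GAP:
            ins_b.append(b_row[j])
            j += 1
        if ins_a or ins_b:
            sa, sb = "".join(ins_a), "".join(ins_b)
            qa, qb = (sa, sb) if sa == sb else pairwise_global(sa, sb)
            for ca, cb in zip(qa, qb):
                out_a.append(ca)
                out_b.append(cb)
                out_r.append(GAP)
        if i < na and j < nb:
            if ra_row[i] != rb_row[j] or ra_row[i] == GAP:
                raise AssertionError("reference streams desynchronised")
            out_a.append(a_row[i])
            out_b.append(b_row[j])
            out_r.append(ra_row[i])
            i += 1
            j += 1
        elif i < na or j < nb:
            raise AssertionError("reference streams desynchronised")
    return out_a, out_b, out_r


# ---------------------------------------------------------------------------
# the trio alignment container


@dataclass
class TrioAlignment:
    """Column-indexed alignment of parent A, parent B and the recombinant.

    Rows are gapped strings of equal length with no all-gap column.
    ``pos_a``/``pos_b``/``pos_r`` map each column to the 1-based ungapped
    position in the corresponding sequence (0 at gap columns).
    """

    row_a: str
    row_b: str
    row_r: str

    def __post_init__(self) -> None:
        if not (len(self.row_a) == len(self.row_b) == len(self.row_r)):
            raise AlignmentError("alignment rows have unequal lengths")
        for c, (a, b, r) in enumerate(zip(self.row_a, self.row_b, self.row_r)):
            if a == b == r == GAP:
                raise AlignmentError(f"all-gap column at index {c}")
        self.pos_a = self._positions(self.row_a)
        self.pos_b = self._positions(self.row_b)
        self.pos_r = self._positions(self.row_r)

    @staticmethod
    def _positions(row: str) -> np.ndarray:
        arr = np.frombuffer(row.encode(), dtype=np.uint8) != ord(GAP)
        pos = np.cumsum(arr)
        pos[~arr] = 0
        return pos.astype(np.int64)

    @property
    def n_columns(self) -> int:
        return len(self.row_r)

    def column(self, c: int) -> tuple[str, str, str]:
        return (self.row_a[c], self.row_b[c], self.row_r[c])

    def degapped(self, which: str) -> str:
        row = {"A": self.row_a, "B": self.row_b, "R": self.row_r}[which]
        return row.replace(GAP, "")

    def column_of_r_position(self) -> np.ndarray:
        """Inverse map: 1-based recombinant position -> column index."""
        cols = np.flatnonzero(self.pos_r)
        out = np.empty(len(cols) + 1, dtype=np.int64)
        out[0] = -1
        out[1:] = cols
        return out


def build_trio_alignment(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    recombinant: GenomeRecord,
    mode: str = "internal",
    k_anchor: int = 21,
    prealigned: "str | Sequence[str] | None" = None,
) -> TrioAlignment:
    """Build the three-way alignment.

    ``internal`` mode chains unique shared ``k_anchor``-mers and aligns the
    inter-anchor gaps with edlib, pairwise against the recombinant, then
    merges on the recombinant.  ``prealigned`` mode ingests an aligned FASTA
    (path) or three gapped row strings, in parent-A / parent-B / recombinant
    order, and only validates them.
    """
    if mode == "prealigned":
        if prealigned is None:
            raise AlignmentError("prealigned mode requires an aligned input")
        if isinstance(prealigned, (str, bytes)) or hasattr(prealigned, "__fspath__"):
            rows = [r.sequence for r in _read_aligned_fasta(prealigned)]
        else:
            rows = [str(r).upper() for r in prealigned]
        if len(rows) != 3:
            raise AlignmentError(f"prealigned input has {len(rows)} rows, expected 3")
        aln = TrioAlignment(*rows)
        _check_roundtrip(aln, parent_a, parent_b, recombinant)
        return aln
    if mode != "internal":
        raise ValueError(f"unknown mode {mode!r}")

    sa, sb, sr = parent_a.sequence, parent_b.sequence, recombinant.sequence
    chain = _anchor_chain(sa, sb, sr, k_anchor)
    if not chain and max(len(sa), len(sb), len(sr)) > 50_000:
        raise AlignmentError(
            "no shared unique k-mer anchors found; the sequences may be too "
            "divergent for internal mode -- align them externally and use "
            "prealigned mode"
        )

    out_a: list[str] = []
    out_b: list[str] = []
    out_r: list[str] = []
    prev_a = prev_b = prev_r = 0
    k = k_anchor
    for pa, pb, pr in chain + [(len(sa), len(sb), len(sr))]:
        seg_a, seg_b, seg_r = sa[prev_a:pa], sb[prev_b:pb], sr[prev_r:pr]
        if seg_a or seg_b or seg_r:
            a_al, ra_al = pairwise_global(seg_a, seg_r)
            b_al, rb_al = pairwise_global(seg_b, seg_r)
            ca, cb, cr = _merge_on_ref(a_al, ra_al, b_al, rb_al)
            out_a.extend(ca)
            out_b.extend(cb)
            out_r.extend(cr)
        if (pa, pb, pr) != (len(sa), len(sb), len(sr)):
            anchor = sr[pr : pr + k]
            out_a.extend(anchor)
            out_b.extend(anchor)
            out_r.extend(anchor)
            prev_a, prev_b, prev_r = pa + k, pb + k, pr + k
    aln = TrioAlignment("".join(out_a), "".join(out_b), "".join(out_r))
    _check_roundtrip(aln, parent_a, parent_b, recombinant)
    return aln


def _read_aligned_fasta(path) -> list[GenomeRecord]:
    # aligned FASTA rows contain '-', which GenomeRecord rejects; read raw
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rows.append(_Row(rec.id, str(rec.seq).upper()))
    if not rows:
        raise AlignmentError(f"{path}: no aligned FASTA records")
    return rows


@dataclass(frozen=True)
class _Row:
    id: str
    sequence: str


def _check_roundtrip(aln, parent_a, parent_b, recombinant) -> None:
    for which, rec in (("A", parent_a), ("B", parent_b), ("R", recombinant)):
        if rec is None:
            continue
        if aln.degapped(which) != rec.sequence:
            raise AlignmentError(
                f"degapped row {which} does not reproduce input sequence "
                f"{rec.id!r}"
            )


# ---------------------------------------------------------------------------
# site classification


@dataclass(frozen=True)
class SiteRecord:
    """One (possibly collapsed) alignment column with its evidentiary class.

    ``site_class`` is ``gap_event`` for collapsed indel runs; ``resolution``
    then gives the evidentiary reading (informative / neither / uninformative)
    under the matching rule, and equals ``site_class`` for plain columns.
    ``r_position`` is the 1-based recombinant position of the first base in
    the record (None when the recombinant is gapped); ``r_flank`` is the last
    recombinant base strictly before the record (0 at the genome start).
    ``a_lo``/``a_hi`` (and b) bound the record in parent coordinates, used
    for homopolymer-context lookups.
    """

    column: int
    width: int
    site_class: str
    resolution: str
    alleles: tuple[str, str, str]
    r_position: Optional[int]
    r_flank: int
    a_lo: int
    a_hi: int
    b_lo: int
    b_hi: int

    @property
    def anchor_position(self) -> int:
        """Recombinant coordinate used for ordering and segment bookkeeping."""
        return self.r_position if self.r_position is not None else self.r_flank

    @property
    def anchor_left(self) -> int:
        """Last recombinant base of the site's evidence (used as the left
        bound of a following crossover's ambiguity interval).

        A record gapped in the recombinant sits between bases ``r_flank``
        and ``r_flank + 1``; its evidence straddles that junction.
        """
        if self.r_position is None:
            return self.r_flank
        return self.r_position + len(self.alleles[2]) - 1

    @property
    def anchor_right(self) -> int:
        """First recombinant base of the site's evidence (used as the right
        bound of a preceding crossover's ambiguity interval)."""
        return self.r_position if self.r_position is not None else self.r_flank + 1

    @property
    def is_informative(self) -> bool:
        return self.resolution in ("inform_A", "inform_B")

    @property
    def parent(self) -> Optional[str]:
        if self.resolution == "inform_A":
            return "A"
        if self.resolution == "inform_B":
            return "B"
        return None


def _classify(a: str, b: str, r: str, a_gap: bool, b_gap: bool, r_gap: bool) -> str:
    if "N" in a or "N" in b or "N" in r:
        return "uninformative"
    r_eq_a = (r_gap == a_gap) and (r == a)
    r_eq_b = (r_gap == b_gap) and (r == b)
    parents_eq = (a_gap == b_gap) and (a == b)
    if parents_eq:
        return "uninformative" if r_eq_a else "neither_parent"
    if r_eq_a:
        return "inform_A"
    if r_eq_b:
        return "inform_B"
    return "neither_parent"


def classify_sites(alignment: TrioAlignment) -> list[SiteRecord]:
    """Classify every column; collapse same-pattern gap runs into one record.

    The returned records are in column order and partition the collapsed
    column count: one record per ungapped column plus one per maximal run of
    columns gapped in the same subset of rows.
    """
    ra, rb, rr = alignment.row_a, alignment.row_b, alignment.row_r
    pos_a, pos_b, pos_r = alignment.pos_a, alignment.pos_b, alignment.pos_r
    n = alignment.n_columns
    records: list[SiteRecord] = []
    c = 0
    while c < n:
        a, b, r = ra[c], rb[c], rr[c]
        pattern = (a == GAP, b == GAP, r == GAP)
        if pattern == (False, False, False):
            records.append(
                SiteRecord(
                    column=c,
                    width=1,
                    site_class=_classify(a, b, r, False, False, False),
                    resolution=_classify(a, b, r, False, False, False),
                    alleles=(a, b, r),
                    r_position=int(pos_r[c]),
                    r_flank=int(pos_r[c]) - 1,
                    a_lo=int(pos_a[c]),
                    a_hi=int(pos_a[c]),
                    b_lo=int(pos_b[c]),
                    b_hi=int(pos_b[c]),
                )
            )
            c += 1
            continue
        # collapse a maximal run with the same gap pattern
        c0 = c
        while c < n and (ra[c] == GAP, rb[c] == GAP, rr[c] == GAP) == pattern:
            c += 1
        sa = ra[c0:c].replace(GAP, "")
        sb = rb[c0:c].replace(GAP, "")
        sr = rr[c0:c].replace(GAP, "")
        a_gap, b_gap, r_gap = pattern
        resolution = _classify(sa, sb, sr, a_gap, b_gap, r_gap)
        flank_r = _flank(pos_r, c0)
        records.append(
            SiteRecord(
                column=c0,
                width=c - c0,
                site_class="gap_event",
                resolution=resolution,
                alleles=(sa, sb, sr),
                r_position=None if r_gap else int(pos_r[c0]),
                r_flank=flank_r,
                a_lo=int(pos_a[c0]) if not a_gap else _flank(pos_a, c0),
                a_hi=int(pos_a[c - 1]) if not a_gap else _flank(pos_a, c0) + 1,
                b_lo=int(pos_b[c0]) if not b_gap else _flank(pos_b, c0),
                b_hi=int(pos_b[c - 1]) if not b_gap else _flank(pos_b, c0) + 1,
            )
        )
    return records


def _flank(pos: np.ndarray, c0: int) -> int:
    return int(pos[:c0].max(initial=0))


# ---------------------------------------------------------------------------
# homopolymer runs


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one repeated base, 1-based inclusive coordinates."""

    sequence_id: str
    start: int
    end: int
    base: str
    run_length: int


def find_homopolymer_runs(genome: GenomeRecord, min_len: int = 4) -> list[HomopolymerRun]:
    """All maximal runs of identical A/C/G/T bases with length >= ``min_len``.

    N stretches are never reported as runs.  ``min_len`` must be >= 2.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = genome.sequence
    runs: list[HomopolymerRun] = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] != "N" and j - i >= min_len:
            runs.append(HomopolymerRun(genome.id, i + 1, j, seq[i], j - i))
        i = j
    return runs
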