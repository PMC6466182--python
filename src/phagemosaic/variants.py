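"""De-novo variant calls, homopolymer adjudication and per-ORF accounting.

A recombinant derived from two parents should match one of them everywhere;
sites matching neither parent are either genuine de-novo mutations or
sequencing artifacts.  Pyrosequencing chemistry miscounts homopolymer run
lengths, so indels sitting in (or immediately next to) a parental
homopolymer run of at least ``min_run`` bases are adjudicated as suspected
sequencing errors; substitutions are never auto-suspected.

Per-ORF summaries mirror the crossover table of the study system: each
crossover is assigned to the ORF whose interval contains its reported
position, positions between ORFs go to named intergenic buckets, and
amino-acid difference counts against each parent are computed by strand-aware
codon comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .alignment import HomopolymerRun, SiteRecord, TrioAlignment
from .io import GenomeRecord, OrfRecord

EFFECTS = ("missense", "synonymous", "intergenic", "frameshift_candidate", "nonsense")


@dataclass(frozen=True)
class VariantCall:
    """A site where the recombinant matches neither parent.

    ``r_position`` is the 1-based recombinant coordinate (for deletions in
    the recombinant, the flanking base to the left).  ``homopolymer_context``
    is the longest parental homopolymer run overlapping or immediately
    adjacent (within 1 bp) to the site; 0 when there is none.
    """

    r_position: int
    allele_a: str
    allele_b: str
    allele_r: str
    kind: str  # "substitution" | "indel"
    homopolymer_context: int
    status: str = "accepted_mutation"
    effect: Optional[str] = None
    a_lo: int = 0
    a_hi: int = 0
    b_lo: int = 0
    b_hi: int = 0


@dataclass(frozen=True)
class OrfCrossoverSummary:
    """Crossover count and amino-acid differences for one ORF (or one
    intergenic bucket)."""

    orf_id: str
    n_crossovers: int
    crossover_positions: tuple[int, ...]
    aa_diff_vs_a: Optional[int] = None
    aa_diff_vs_b: Optional[int] = None
    is_intergenic: bool = False

    def __post_init__(self) -> None:
        if self.n_crossovers != len(self.crossover_positions):
            raise ValueError("n_crossovers != number of positions")


# ---------------------------------------------------------------------------


def _max_run_near(runs: Sequence[HomopolymerRun], lo: int, hi: int) -> int:
    best = 0
    for run in runs:
        if run.start <= hi + 1 and run.end >= lo - 1:
            best = max(best, run.run_length)
    return best


def call_variants(
    sites: Iterable[SiteRecord],
    runs_a: Sequence[HomopolymerRun],
    runs_b: Sequence[HomopolymerRun],
) -> list[VariantCall]:
    """One :class:`VariantCall` per neither-parent site record.

    Informative and uninformative sites never produce calls.  Homopolymer
    context is the longest run in either parent overlapping or within 1 bp
    of the site's footprint in that parent's coordinates.
    """
    calls: list[VariantCall] = []
    for s in sites:
        if s.resolution != "neither_parent":
            continue
        kind = "substitution" if s.site_class != "gap_event" else "indel"
        context = max(
            _max_run_near(runs_a, s.a_lo, s.a_hi),
            _max_run_near(runs_b, s.b_lo, s.b_hi),
        )
        calls.append(
            VariantCall(
                r_position=s.r_position if s.r_position is not None else s.r_flank,
                allele_a=s.alleles[0],
                allele_b=s.alleles[1],
                allele_r=s.alleles[2],
                kind=kind,
                homopolymer_context=context,
                a_lo=s.a_lo,
                a_hi=s.a_hi,
                b_lo=s.b_lo,
                b_hi=s.b_hi,
            )
        )
    return calls


def adjudicate_variants(
    variants: Iterable[VariantCall], min_run: int = 4
) -> list[VariantCall]:
    """Set each call's status: indels in homopolymer context >= ``min_run``
    become ``suspected_error``; everything else is ``accepted_mutation``.

    Only the status field changes; the operation is idempotent.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    out = []
    for v in variants:
        suspected = v.kind == "indel" and v.homopolymer_context >= min_run
        out.append(replace(v, status="suspected_error" if suspected else "accepted_mutation"))
    return out


# ---------------------------------------------------------------------------
# coding effects


def _containing_orfs(orfs: Sequence[OrfRecord], pos: int) -> list[OrfRecord]:
    return [o for o in orfs if o.span[0] <= pos <= o.span[1]]


def annotate_effect(
    variant: VariantCall,
    orfs: Sequence[OrfRecord],
    recombinant: GenomeRecord,
) -> VariantCall:
    """Classify a variant's coding effect by codon comparison.

    Substitutions inside an ORF are missense / synonymous / nonsense by
    translating the recombinant codon against the codons carrying each
    parental allele (standard bacterial code; reverse-strand ORFs are
    reverse-complemented first).  Indels inside an ORF are
    ``frameshift_candidate`` when the length change is not a multiple of 3,
    else treated as an in-frame change (missense).  Positions in no ORF are
    intergenic.
    """
    pos = variant.r_position
    if pos > recombinant.length:
        raise ValueError(
            f"variant position {pos} beyond genome length {recombinant.length}"
        )
    hits = _containing_orfs(orfs, pos) if pos >= 1 else []
    if not hits:
        return replace(variant, effect="intergenic")
    orf = hits[0]
    if variant.kind == "indel":
        delta = len(variant.allele_r) - max(len(variant.allele_a), len(variant.allele_b))
        effect = "frameshift_candidate" if delta % 3 != 0 else "missense"
        return replace(variant, effect=effect)

    seq = recombinant.sequence
    if orf.strand == "forward":
        gene = seq[orf.start - 1 : orf.stop]
        idx = pos - orf.start
        sub_a = _complement_free(variant.allele_a)
        sub_b = _complement_free(variant.allele_b)
    else:
        gene = str(Seq(seq[orf.stop - 1 : orf.start]).reverse_complement())
        idx = orf.start - pos
        sub_a = _complement(variant.allele_a)
        sub_b = _complement(variant.allele_b)
    ci = idx // 3
    codon_r = gene[3 * ci : 3 * ci + 3]
    if len(codon_r) < 3:
        warnings.warn(
            f"variant at {pos} falls in a truncated trailing codon of ORF "
            f"{orf.orf_id}", stacklevel=2,
        )
        return replace(variant, effect="missense")
    within = idx % 3
    codon_a = codon_r[:within] + sub_a + codon_r[within + 1 :]
    codon_b = codon_r[:within] + sub_b + codon_r[within + 1 :]
    aa_r = str(Seq(codon_r).translate(table=11))
    aa_parents = {str(Seq(codon_a).translate(table=11)),
                  str(Seq(codon_b).translate(table=11))}
    if aa_r in aa_parents:
        effect = "synonymous"
    elif aa_r == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return replace(variant, effect=effect)


def _complement_free(base: str) -> str:
    return base


def _complement(base: str) -> str:
    return str(Seq(base).complement())


# ---------------------------------------------------------------------------
# per-ORF accounting


def count_orf_crossovers(
    breakpoints: Sequence,
    orfs: Sequence[OrfRecord],
    intergenic_labels: bool = True,
) -> list[OrfCrossoverSummary]:
    """Assign crossover positions to ORFs; conserve the event total.

    ``breakpoints`` may be :class:`~phagemosaic.mosaic.BreakpointCall`
    objects (their reported positions are used) or bare integer positions.
    Positions covered by no ORF go to an intergenic bucket named after the
    flanking ORFs (``IG<left>-<right>``).  A position inside overlapping
    ORFs is counted in each, with a warning making the double count
    explicit.  Zero-count ORFs are included, in genome order.
    """
    positions = [
        bp if isinstance(bp, int) else bp.reported_position for bp in breakpoints
    ]
    ordered = sorted(orfs, key=lambda o: o.span[0])
    per_orf: dict[str, list[int]] = {o.orf_id: [] for o in ordered}
    intergenic: dict[str, list[int]] = {}
    for pos in positions:
        hits = _containing_orfs(ordered, pos)
        if len(hits) > 1:
            warnings.warn(
                f"position {pos} lies in overlapping ORFs "
                f"{[o.orf_id for o in hits]}; counted in each", stacklevel=2,
            )
        if hits:
            for o in hits:
                per_orf[o.orf_id].append(pos)
            continue
        if not intergenic_labels:
            continue
        left = None
        right = None
        for o in ordered:
            if o.span[1] < pos:
                left = o
            elif o.span[0] > pos and right is None:
                right = o
        label = f"IG{left.orf_id if left else 'start'}-{right.orf_id if right else 'end'}"
        intergenic.setdefault(label, []).append(pos)

    summaries = [
        OrfCrossoverSummary(
            orf_id=o.orf_id,
            n_crossovers=len(per_orf[o.orf_id]),
            crossover_positions=tuple(sorted(per_orf[o.orf_id])),
        )
        for o in ordered
    ]
    for label in sorted(intergenic, key=lambda lb: min(intergenic[lb])):
        summaries.append(
            OrfCrossoverSummary(
                orf_id=label,
                n_crossovers=len(intergenic[label]),
                crossover_positions=tuple(sorted(intergenic[label])),
                is_intergenic=True,
            )
        )
    return summaries


def count_aa_differences(
    orf: OrfRecord,
    alignment: TrioAlignment,
    vs_parent: str,
) -> int:
    """Codon positions where the recombinant's residue differs from the one
    encoded by the chosen parent's aligned bases.

    Codons containing a parental gap, or spanning a parental insertion,
    count as differences and trigger a frameshift warning; a trailing
    partial codon is ignored.
    """
    if vs_parent not in ("A", "B"):
        raise ValueError("vs_parent must be 'A' or 'B'")
    r_len = int(alignment.pos_r.max(initial=0))
    lo, hi = orf.span
    if hi > r_len:
        raise ValueError(f"ORF {orf.orf_id} extends past genome end ({r_len} bp)")
    col_of = alignment.column_of_r_position()
    cols = [int(col_of[p]) for p in range(lo, hi + 1)]
    parent_row = alignment.row_a if vs_parent == "A" else alignment.row_b
    r_chars = [alignment.row_r[c] for c in cols]
    p_chars = [parent_row[c] for c in cols]
    # parental insertion strictly between consecutive ORF positions
    ins_after = [
        any(parent_row[c] != "-" for c in range(c1 + 1, c2))
        for c1, c2 in zip(cols, cols[1:])
    ] + [False]
    if orf.strand == "reverse":
        comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N", "-": "-"}
        r_chars = [comp[c] for c in reversed(r_chars)]
        p_chars = [comp[c] for c in reversed(p_chars)]
        ins_after = [False] + list(reversed(ins_after[:-1]))
        # re-index: insertion after genome position i sits before it in gene order
        ins_after = ins_after[1:] + [False]

    n_codons = len(r_chars) // 3
    diffs = 0
    frameshift = False
    for k in range(n_codons):
        rp = r_chars[3 * k : 3 * k + 3]
        pp = p_chars[3 * k : 3 * k + 3]
        span_ins = any(ins_after[3 * k : 3 * k + 2])
        if "-" in pp or span_ins:
            diffs += 1
            frameshift = True
            continue
        aa_r = str(Seq("".join(rp)).translate(table=11))
        aa_p = str(Seq("".join(pp)).translate(table=11))
        if aa_r != aa_p:
            diffs += 1
    if frameshift:
        warnings.warn(
            f"ORF {orf.orf_id}: parental gaps/insertions inside the reading "
            f"frame vs parent {vs_parent}; affected codons counted as "
            f"differences (frameshift candidate)", stacklevel=2,
        )
    return diffs
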