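"""Synthetic mosaic-genome generator with known ground truth.

The generator emulates the study system: two parent genomes at >99%
nucleotide identity (SNPs, short indels, planted homopolymer runs) and a
recombinant assembled from a known crossover list, with optional planted
de-novo substitutions and homopolymer sequencing-error indels.  Defaults
match the study conditions: a 73,050 bp genome, 0.5% substitution
divergence, 48 crossovers and one de-novo point mutation.

Ground truth is recorded in recombinant-frame coordinates.  A crossover
between identical parental stretches is undetectable in principle; the
truth object therefore also carries ``expected_detectable_crossovers``,
the minimal switch count consistent with the informative-site pattern
(adjacent true crossovers with no parental difference between them cancel
in pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alignment import SiteRecord, find_homopolymer_runs, pairwise_global
from .io import GenomeRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the seed is mandatory (no wall-clock default).

    Rates are per base: ``snp_rate`` 0.005 and ``indel_rate`` 0.0005 put
    the parents just inside the >99% identity regime of the real pair.
    ``guarantee_separation`` forces at least one parental-difference column
    into every inter-crossover segment, making every crossover detectable.
    ``n_error_indels`` plants single-base deletions inside shared
    homopolymer runs, emulating pyrosequencing artifacts.
    """

    rng_seed: int
    genome_length: int = 73_050
    snp_rate: float = 0.005
    indel_rate: float = 0.0005
    indel_max_len: int = 4
    homopolymer_seed_count: int = 50
    homopolymer_len_range: tuple[int, int] = (4, 8)
    n_crossovers: int = 48
    crossover_positions: Optional[tuple[int, ...]] = None
    n_mutations: int = 1
    n_error_indels: int = 0
    guarantee_separation: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.snp_rate <= 0.2 and 0 <= self.indel_rate <= 0.2):
            raise ValueError("rates must be in [0, 0.2]")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.homopolymer_len_range[0] > self.homopolymer_len_range[1]:
            raise ValueError("bad homopolymer_len_range")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one synthetic recombinant, recombinant-frame."""

    true_crossovers: tuple[int, ...]
    true_mutations: tuple[tuple[int, str], ...]
    true_error_indels: tuple[int, ...]
    parent_of_origin: str  # one of "AB" per recombinant base
    expected_detectable_crossovers: int

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["true_mutations"] = [list(m) for m in self.true_mutations]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------


def generate_parent_pair(config: SyntheticConfig) -> tuple[GenomeRecord, GenomeRecord]:
    """Draw parent A uniformly (with planted homopolymer runs) and derive
    parent B by applying SNPs and short indels at the configured rates.

    Deterministic given ``rng_seed``: the same seed yields byte-identical
    sequences.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.genome_length
    a = rng.choice(_BASES, size=L)
    lo, hi = config.homopolymer_len_range
    for _ in range(config.homopolymer_seed_count):
        start = int(rng.integers(0, L - hi))
        run_len = int(rng.integers(lo, hi + 1))
        a[start : start + run_len] = a[start]
    a_seq = "".join(a)

    sub_mask = rng.random(L) < config.snp_rate
    indel_mask = rng.random(L) < config.indel_rate
    b_parts: list[str] = []
    i = 0
    while i < L:
        if indel_mask[i]:
            length = int(rng.integers(1, config.indel_max_len + 1))
            if rng.random() < 0.5:  # insertion in B before position i
                b_parts.append("".join(rng.choice(_BASES, size=length)))
            else:  # deletion of the next `length` bases
                i += length
                continue
        if i < L:
            base = a_seq[i]
            if sub_mask[i]:
                choices = [c for c in "ACGT" if c != base]
                base = choices[int(rng.integers(0, 3))]
            b_parts.append(base)
        i += 1
    b_seq = "".join(b_parts)
    return (
        GenomeRecord("parentA", a_seq, "synthetic parent A"),
        GenomeRecord("parentB", b_seq, "synthetic parent B"),
    )


def generate_recombinant(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    config: SyntheticConfig,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Assemble a recombinant by switching parental source at each crossover.

    The recombinant copies parent A up to the first crossover and alternates
    thereafter; each truth coordinate is the last recombinant base taken
    from the outgoing parent.  De-novo substitutions are applied afterwards
    at positions where the parents agree, and recorded.  Random crossovers
    are confined to the interior of the parental-difference span so that
    undetectable crossovers always cancel pairwise.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    a_row, b_row = pairwise_global(parent_a.sequence, parent_b.sequence)
    ncols = len(a_row)
    diff_idx = [i for i in range(ncols) if a_row[i] != b_row[i]]

    if config.crossover_positions is not None:
        boundaries: set[int] = set()
        targets = sorted(config.crossover_positions)
    else:
        k = config.n_crossovers
        targets = []
        if k == 0:
            boundaries = set()
        elif len(diff_idx) < k + 1:
            raise ValueError(
                f"only {len(diff_idx)} parental differences; cannot place "
                f"{k} separated crossovers"
            )
        elif config.guarantee_separation:
            # switch strictly between two difference columns, inside the
            # agreement region, so every segment carries >= 1 informative
            # site; stay clear of indel columns, whose placement within a
            # repeat is alignment-ambiguous and would smear the junction
            margin = max(10, config.indel_max_len + 2)
            allowed = np.ones(ncols, dtype=bool)
            for g in range(ncols):
                if a_row[g] == "-" or b_row[g] == "-":
                    allowed[max(0, g - margin) : g + margin + 1] = False
            interiors: list[list[int]] = []
            for s in range(len(diff_idx) - 1):
                lo, hi = diff_idx[s] + 1, diff_idx[s + 1]
                ok = [c for c in range(lo, hi) if allowed[c]]
                if ok:
                    interiors.append(ok)
            if len(interiors) < k:
                raise ValueError(
                    f"only {len(interiors)} separable slots for {k} crossovers"
                )
            slots = sorted(
                int(i) for i in rng.choice(len(interiors), size=k, replace=False)
            )
            boundaries = {
                int(interiors[s][int(rng.integers(0, len(interiors[s])))])
                for s in slots
            }
        else:
            span = np.arange(diff_idx[0] + 1, diff_idx[-1] + 1)
            boundaries = set(int(x) for x in rng.choice(span, size=k, replace=False))

    r_chars: list[str] = []
    origin: list[str] = []
    true_crossovers: list[int] = []
    diff_labels: list[str] = []  # active parent at each parental-difference column
    agree: list[int] = []  # R positions where parents agree
    gap_anchors: list[int] = []  # R coordinate of every indel column
    active = "A"
    diff_set = set(diff_idx)
    pending = list(targets)
    for i in range(ncols):
        if i in boundaries:
            true_crossovers.append(len(r_chars))
            active = "B" if active == "A" else "A"
        ca, cb = a_row[i], b_row[i]
        ch = ca if active == "A" else cb
        if i in diff_set:
            diff_labels.append(active)
        if ca == "-" or cb == "-":
            gap_anchors.append(len(r_chars))
        if ch != "-":
            r_chars.append(ch)
            origin.append(active)
            if ca == cb:
                agree.append(len(r_chars))
        if pending and len(r_chars) == pending[0]:
            true_crossovers.append(len(r_chars))
            pending.pop(0)
            active = "B" if active == "A" else "A"
    if pending:
        raise ValueError(f"crossover positions beyond recombinant end: {pending}")

    # plant substitutions only in unambiguous context: outside homopolymer
    # runs and clear of parental indels, where a substitution reads as a
    # substitution rather than as an indel rearrangement
    blocked: set[int] = set()
    interim = GenomeRecord("interim", "".join(r_chars))
    for run in find_homopolymer_runs(interim, min_len=4):
        blocked.update(range(run.start - 1, run.end + 2))
    margin = max(10, config.indel_max_len + 2)
    for g in gap_anchors:
        blocked.update(range(g - margin, g + margin + 1))
    eligible = [p for p in agree if p not in blocked]

    detectable = sum(1 for x, y in zip(diff_labels, diff_labels[1:]) if x != y)

    # de-novo substitutions at parent-agreement positions
    true_mutations: list[tuple[int, str]] = []
    if config.n_mutations > 0:
        picks = sorted(
            int(p) for p in rng.choice(eligible, size=config.n_mutations, replace=False)
        )
        for pos in picks:
            old = r_chars[pos - 1]
            choices = [c for c in "ACGT" if c != old]
            new = choices[int(rng.integers(0, 3))]
            r_chars[pos - 1] = new
            true_mutations.append((pos, new))

    # planted homopolymer-error deletions (1 bp inside shared runs)
    true_error_indels: list[int] = []
    if config.n_error_indels > 0:
        mutated = {p for p, _ in true_mutations}
        agree_set = set(agree)
        interim = GenomeRecord("interim", "".join(r_chars))
        runs = [
            r
            for r in find_homopolymer_runs(interim, min_len=4)
            if all(p in agree_set and p not in mutated for p in range(r.start, r.end + 1))
        ]
        if len(runs) < config.n_error_indels:
            raise ValueError(
                f"only {len(runs)} clean homopolymer runs available for "
                f"{config.n_error_indels} planted error indels"
            )
        chosen = sorted(
            (runs[int(i)] for i in rng.choice(len(runs), size=config.n_error_indels, replace=False)),
            key=lambda r: r.start,
            reverse=True,
        )
        for run in chosen:  # right to left, so earlier loci are unaffected
            del_pos = run.start  # delete one base; run shrinks by 1
            del r_chars[del_pos - 1]
            del origin[del_pos - 1]
            true_crossovers = [p - 1 if p >= del_pos else p for p in true_crossovers]
            true_mutations = [
                (p - 1 if p >= del_pos else p, b) for p, b in true_mutations
            ]
            true_error_indels = [p - 1 if p >= del_pos else p for p in true_error_indels]
            true_error_indels.append(del_pos - 1)  # left-flank coordinate
        true_error_indels.sort()

    truth = SyntheticTruth(
        true_crossovers=tuple(true_crossovers),
        true_mutations=tuple(true_mutations),
        true_error_indels=tuple(true_error_indels),
        parent_of_origin="".join(origin),
        expected_detectable_crossovers=detectable,
    )
    rec = GenomeRecord("recombinant", "".join(r_chars), "synthetic recombinant")
    return rec, truth


def expected_detectable(truth: SyntheticTruth, sites: Sequence[SiteRecord]) -> int:
    """Parity-reduction oracle over an observed informative-site pattern.

    Adjacent true crossovers with no informative site between them cancel in
    pairs; the result is the minimal switch count consistent with the
    pattern: the number of adjacent informative-site pairs separated by an
    odd number of true crossovers.
    """
    anchors = sorted(s.anchor_position for s in sites if s.is_informative)
    count = 0
    for p1, p2 in zip(anchors, anchors[1:]):
        n_between = sum(1 for c in truth.true_crossovers if p1 <= c < p2)
        if n_between % 2 == 1:
            count += 1
    return count


def write_synthetic_trio(
    config: SyntheticConfig, outdir: str | Path
) -> tuple[GenomeRecord, GenomeRecord, GenomeRecord, SyntheticTruth]:
    """Generate a full trio and write FASTA + truth JSON into ``outdir``."""
    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pa, pb = generate_parent_pair(config)
    rec, truth = generate_recombinant(pa, pb, config)
    write_fasta([pa], outdir / "parentA.fasta")
    write_fasta([pb], outdir / "parentB.fasta")
    write_fasta([rec], outdir / "recombinant.fasta")
    truth.to_json(outdir / "truth.json")
    return pa, pb, rec, truth
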