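"""Readers and writers for the external formats the pipeline touches.

Genomes travel as plain FASTA, ORF tables as 4/5-column TSV or GFF3,
crossover fixtures as TSV with semicolon-separated position lists, and
host-range spot matrices as CSV with strain rows and phage columns.

Coordinates in all external files are 1-based inclusive; reverse-strand
ORFs are encoded with start > stop in TSV (explicit strand in GFF3).
Thousands separators ("33,215") are stripped on parse, since the printed
tables that these files transcribe use them.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file (bad character, bad token, duplicate id...)."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a documented invariant."""


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class GenomeRecord:
    """An ungapped nucleotide sequence over {A,C,G,T,N}.

    Sequences are upper-cased on construction; gap characters are rejected.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            ch = sorted(bad)[0]
            pos = seq.index(ch) + 1
            raise ParseError(
                f"record {self.id!r}: illegal character {ch!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Raises :class:`ParseError` on an empty file, duplicate ids, or
    characters outside {A,C,G,T,N} (case-insensitive).
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, str(rec.seq), rec.description))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    out = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# ORF tables


@dataclass(frozen=True)
class OrfRecord:
    """An annotated open reading frame, 1-based inclusive coordinates.

    ``strand`` is ``"reverse"`` iff ``start > stop`` (the convention of the
    source tables); ``size == |start - stop| + 1`` always.
    """

    orf_id: str
    start: int
    stop: int
    function_label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.stop < 1:
            raise ValidationError(f"ORF {self.orf_id}: coordinates must be >= 1")
        if self.start == self.stop:
            raise ValidationError(f"ORF {self.orf_id}: start == stop")
        if self.size % 3 != 0:
            warnings.warn(
                f"ORF {self.orf_id}: size {self.size} not divisible by 3",
                stacklevel=2,
            )

    @property
    def strand(self) -> str:
        return "reverse" if self.start > self.stop else "forward"

    @property
    def size(self) -> int:
        return abs(self.start - self.stop) + 1

    @property
    def span(self) -> tuple[int, int]:
        """(min, max) genomic interval, strand-agnostic."""
        return (min(self.start, self.stop), max(self.start, self.stop))


def _int(token: str) -> int:
    return int(token.replace(",", "").strip())


def read_orf_table(path: str | Path, dialect: str = "tsv") -> list[OrfRecord]:
    """Read an ORF coordinate table (``tsv`` or ``gff3`` dialect).

    TSV columns: orf_id, start, stop[, size[, function]]; ``#`` lines are
    comments.  A size column that disagrees with ``|start-stop|+1`` is a
    :class:`ValidationError`.  Records are returned in genome order by
    ``min(start, stop)``.
    """
    path = Path(path)
    orfs: list[OrfRecord] = []
    if dialect == "tsv":
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                if row[0].strip().lower() in ("orf_id", "orf"):
                    continue  # header
                if len(row) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
                orf_id = row[0].strip()
                start, stop = _int(row[1]), _int(row[2])
                rec = OrfRecord(
                    orf_id,
                    start,
                    stop,
                    function_label=row[4].strip() if len(row) > 4 else "",
                )
                if len(row) > 3 and row[3].strip():
                    size = _int(row[3])
                    if size != rec.size:
                        raise ValidationError(
                            f"{path}:{lineno}: ORF {orf_id} size column {size}"
                            f" != |start-stop|+1 == {rec.size}"
                        )
                orfs.append(rec)
    elif dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
                start, end, strand, attrs = parts[3], parts[4], parts[6], parts[8]
                lo, hi = _int(start), _int(end)
                if strand == "-":
                    lo, hi = hi, lo  # encode reverse as start > stop
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                orf_id = attr_map.get("ID") or attr_map.get("Name") or f"orf{lineno}"
                orfs.append(
                    OrfRecord(orf_id, lo, hi, function_label=attr_map.get("product", ""))
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    orfs.sort(key=lambda o: o.span[0])
    return orfs


# ---------------------------------------------------------------------------
# crossover tables


@dataclass(frozen=True)
class CrossoverTableRow:
    """One row of a per-ORF crossover table.

    ``orf_id`` may be an intergenic tag such as ``IG44-45``; positions are
    1-based recombinant-genome coordinates, strictly increasing.
    """

    orf_id: str
    n_crossovers: int
    crossover_positions: tuple[int, ...]
    missense_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_crossovers != len(self.crossover_positions):
            raise ValidationError(
                f"row {self.orf_id}: n_crossovers {self.n_crossovers}"
                f" != {len(self.crossover_positions)} listed positions"
            )
        pos = self.crossover_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError(
                f"row {self.orf_id}: positions not strictly increasing"
            )


def read_crossover_table(path: str | Path) -> list[CrossoverTableRow]:
    """Read a crossover TSV: orf_id, n_crossovers, positions (``;``-separated).

    A ``missense`` token appended to the count column (e.g. ``6+1 missense``)
    sets the row's missense flag.
    """
    path = Path(path)
    rows: list[CrossoverTableRow] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if row[0].strip().lower() in ("orf_id", "orf"):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            count_tok = row[1].strip().lower()
            missense = "missense" in count_tok
            n = _int(count_tok.split("+")[0].replace("(", " ").split()[0])
            positions = tuple(
                _int(tok) for tok in row[2].split(";") if tok.strip()
            )
            rows.append(CrossoverTableRow(row[0].strip(), n, positions, missense))
    return rows


# ---------------------------------------------------------------------------
# host-range spot matrices


@dataclass(frozen=True)
class HostRangeMatrix:
    """Boolean lysis matrix, phages x strains."""

    phage_ids: tuple[str, ...]
    strain_ids: tuple[str, ...]
    lysis: np.ndarray  # bool, shape (n_phages, n_strains)

    def __post_init__(self) -> None:
        if self.lysis.shape != (len(self.phage_ids), len(self.strain_ids)):
            raise ValidationError(
                f"lysis matrix shape {self.lysis.shape} does not match"
                f" {len(self.phage_ids)} phages x {len(self.strain_ids)} strains"
            )

    def column(self, phage_id: str) -> np.ndarray:
        try:
            i = self.phage_ids.index(phage_id)
        except ValueError:
            raise KeyError(f"unknown phage id {phage_id!r}") from None
        return self.lysis[i]


def read_host_matrix(path: str | Path) -> HostRangeMatrix:
    """Read a spot-assay CSV: strain rows, phage columns, cells ``+`` or empty.

    ``+`` parses to True, empty/whitespace to False; any other token is a
    :class:`ParseError`.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise ParseError(f"{path}: empty host matrix")
    phage_ids = tuple(tok.strip() for tok in rows[0][1:])
    strain_ids = []
    cells = []
    for lineno, row in enumerate(rows[1:], 2):
        strain_ids.append(row[0].strip())
        vals = []
        for j, tok in enumerate(row[1:], 1):
            tok = tok.strip()
            if tok == "+":
                vals.append(True)
            elif tok == "":
                vals.append(False)
            else:
                raise ParseError(
                    f"{path}:{lineno}: unknown cell token {tok!r}"
                    f" (column {phage_ids[j-1] if j <= len(phage_ids) else j})"
                )
        # pad short rows (trailing blanks dropped by some writers)
        vals += [False] * (len(phage_ids) - len(vals))
        cells.append(vals)
    lysis = np.array(cells, dtype=bool).T  # -> phage x strain
    return HostRangeMatrix(phage_ids, tuple(strain_ids), lysis)
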