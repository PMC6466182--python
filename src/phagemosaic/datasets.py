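"""Bundled fixtures transcribing the study's printed tables.

The crossover table and the 29 recombinant-ORF coordinate rows are
transcriptions of the printed per-ORF accounting; the remaining 63 ORF
rows are synthetic placeholders (so the full 92-ORF accounting is
exercisable) and are labelled as such in the file.  The recombinant genome
length of 73,050 bp is inferred from the terminal-repeat note rather than
printed directly.
"""

from __future__ import annotations

from importlib import resources

from .hostrange import EOPRecord, read_eop_table
from .io import (
    CrossoverTableRow,
    HostRangeMatrix,
    OrfRecord,
    read_crossover_table,
    read_host_matrix,
    read_orf_table,
)

#: Total recombinant genome length in bp (inferred, see module docstring).
RECOMBINANT_GENOME_LENGTH = 73_050

#: The recombinant's terminal segments are parent-A (Pa2) material.
FIRST_PARENT = "A"


def _path(name: str):
    return resources.files("phagemosaic.data") / name


def load_orf_table() -> list[OrfRecord]:
    """All 92 ORFs (29 printed + 63 synthetic placeholders), genome order."""
    return read_orf_table(_path("orfs_phi176_synthetic_fill.tsv"), dialect="tsv")


def load_crossover_table() -> list[CrossoverTableRow]:
    """The printed per-ORF crossover accounting (48 events)."""
    return read_crossover_table(_path("crossovers_phi176.tsv"))


def crossover_positions() -> list[int]:
    """All printed crossover positions, sorted."""
    return sorted(p for row in load_crossover_table() for p in row.crossover_positions)


def load_host_matrix(which: str) -> HostRangeMatrix:
    """Spot matrices: ``"input_cocktail"`` (parents + pooled rounds) or
    ``"round30_isolates"`` (individual output phages)."""
    names = {
        "input_cocktail": "hostrange_input_cocktail.csv",
        "round30_isolates": "hostrange_round30_isolates.csv",
    }
    return read_host_matrix(_path(names[which]))


def load_eop_table() -> list[EOPRecord]:
    """EOP records of the four clinical-strain isolates."""
    return read_eop_table(_path("eop_round30_isolates.csv"))
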