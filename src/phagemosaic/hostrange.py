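"""Host-range breadth, efficiency of plating, and endpoint statistics.

Breadth is the fraction of tested bacterial strains a phage lyses in a
spot assay.  EOP (efficiency of plating) is the titer of a phage on a test
strain divided by its titer on its isolation host; titers below the plaque
detection limit yield explicitly censored records carrying the detection
bound rather than zero, because a "no plaques" cell is not the same
observation as a measured small ratio.  The serial-dilution endpoint rule
is read strictly: the protocol endpoint is reached only when *more than*
the threshold fraction of strains lyse at (or beyond) the threshold
dilution.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .io import HostRangeMatrix, ParseError


@dataclass(frozen=True)
class EOPRecord:
    """Efficiency of plating for one phage on one strain.

    When ``censored`` is true, ``eop`` holds the detection bound (the EOP is
    known only to be below it).
    """

    phage_id: str
    strain_id: str
    eop: float
    censored: bool = False
    sd: Optional[float] = None
    is_isolation_strain: bool = False


@dataclass(frozen=True)
class BreadthSummary:
    phage_id: str
    n_lysed: int
    n_tested: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_lysed <= self.n_tested):
            raise ValueError("n_lysed must be within [0, n_tested]")

    @property
    def breadth_percent(self) -> float:
        return 100.0 * self.n_lysed / self.n_tested


def compute_breadth(matrix: HostRangeMatrix, phage_id: str) -> BreadthSummary:
    """Count lysed strains for one phage column of a spot matrix."""
    col = matrix.column(phage_id)  # raises KeyError for unknown phage
    return BreadthSummary(phage_id, int(col.sum()), int(col.size))


def compute_eop(
    titer_test: float,
    titer_isolation: float,
    detection_limit: float = 10.0,
    phage_id: str = "",
    strain_id: str = "",
    is_isolation_strain: bool = False,
) -> EOPRecord:
    """Titer ratio against the isolation host, censored below detection.

    ``detection_limit`` is the smallest countable titer (pfu/mL); a test
    titer below it returns a censored record bounded by
    ``detection_limit / titer_isolation``.
    """
    if titer_isolation <= 0:
        raise ValueError("isolation-host titer must be > 0")
    if titer_test < detection_limit:
        return EOPRecord(
            phage_id,
            strain_id,
            eop=detection_limit / titer_isolation,
            censored=True,
            is_isolation_strain=is_isolation_strain,
        )
    return EOPRecord(
        phage_id,
        strain_id,
        eop=titer_test / titer_isolation,
        is_isolation_strain=is_isolation_strain,
    )


def endpoint_check(
    lysis_by_strain_and_dilution: Mapping[str, Iterable[int]],
    strain_fraction: float = 0.8,
    dilution_threshold: int = 7,
) -> bool:
    """Serial-dilution endpoint rule (strict inequality).

    ``lysis_by_strain_and_dilution`` maps each strain to the dilution
    exponents (d for a 10^-d dilution) at which lysis was observed.  True
    iff strictly more than ``strain_fraction`` of strains show lysis at a
    dilution at least as deep as ``10^-dilution_threshold``.
    """
    if not lysis_by_strain_and_dilution:
        raise ValueError("empty lysis table")
    n = len(lysis_by_strain_and_dilution)
    hits = sum(
        1
        for exps in lysis_by_strain_and_dilution.values()
        if any(e >= dilution_threshold for e in exps)
    )
    return hits / n > strain_fraction


def flag_better_on_other_host(eops: Sequence[EOPRecord]) -> list[str]:
    """Phages with a measured EOP > 1 on any non-isolation strain.

    Censored records never trigger the flag.  Order of first appearance is
    preserved.
    """
    flagged: list[str] = []
    for rec in eops:
        if rec.is_isolation_strain or rec.censored:
            continue
        if rec.eop > 1 and rec.phage_id not in flagged:
            flagged.append(rec.phage_id)
    return flagged


def read_eop_table(path: str | Path) -> list[EOPRecord]:
    """Read a long-format EOP CSV: phage,strain,eop,sd,is_isolation[,censor_bound].

    An ``eop`` cell of ``-`` marks a censored observation; its bound is
    taken from the ``censor_bound`` column.
    """
    path = Path(path)
    records: list[EOPRecord] = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#")]
        for lineno, row in enumerate(csv.DictReader(lines), 2):
            tok = row["eop"].strip()
            censored = tok == "-"
            if censored:
                bound = row.get("censor_bound", "").strip()
                if not bound:
                    raise ParseError(
                        f"{path}:{lineno}: censored cell without censor_bound"
                    )
                eop = float(bound)
                sd = None
            else:
                eop = float(tok)
                sd_tok = row.get("sd", "").strip()
                sd = float(sd_tok) if sd_tok and sd_tok != "-" else None
            records.append(
                EOPRecord(
                    phage_id=row["phage"].strip(),
                    strain_id=row["strain"].strip(),
                    eop=eop,
                    censored=censored,
                    sd=sd,
                    is_isolation_strain=row["is_isolation"].strip() in ("1", "true", "True"),
                )
            )
    if not records:
        raise ParseError(f"{path}: empty EOP table")
    return records
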