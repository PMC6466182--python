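"""Parental ancestry assignment along a recombinant genome.

The inference rule works in base-pair order, left to right: the current
parent is set by the first informative site, and every informative site
whose parent differs from the current one marks a crossover.  The reported
crossover coordinate is the last recombinant base that still matches the
outgoing parent — a convention, not a localisation — so every breakpoint
also carries its full ambiguity interval, bounded by the flanking
parent-exclusive informative sites.

Because a crossover between two identical stretches of parental sequence
changes nothing, the inferred count is a lower bound on the true number of
recombination events.  ``min_crossovers_oracle`` provides an independent
dynamic-programming check that the greedy left-to-right rule is
parsimony-minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .alignment import SiteRecord


@dataclass(frozen=True)
class BreakpointCall:
    """A single parental switch with its ambiguity interval.

    ``reported_position`` is the last recombinant base matching the
    outgoing parent; the true crossover lies somewhere in
    (``interval_left``, ``interval_right``), the positions of the flanking
    parent-exclusive informative sites.
    """

    index: int
    from_parent: str
    to_parent: str
    reported_position: int
    interval_left: int
    interval_right: int
    n_uninformative_between: int

    def __post_init__(self) -> None:
        if self.from_parent == self.to_parent:
            raise ValueError("breakpoint must switch parents")
        if not (self.interval_left <= self.reported_position < self.interval_right):
            raise ValueError(
                f"reported position {self.reported_position} outside interval "
                f"[{self.interval_left}, {self.interval_right})"
            )


@dataclass(frozen=True)
class MosaicSegment:
    """A maximal single-parent stretch, 1-based inclusive coordinates."""

    start: int
    stop: int
    parent: str  # "A", "B" or "unknown"

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"segment start {self.start} > stop {self.stop}")

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass(frozen=True)
class MosaicMap:
    """Ordered parental segments tiling the recombinant genome."""

    segments: tuple[MosaicSegment, ...]
    breakpoints: tuple[BreakpointCall, ...]
    genome_length: int
    fraction_a: float
    fraction_b: float

    def __post_init__(self) -> None:
        expected = 1
        for seg in self.segments:
            if seg.start != expected:
                raise ValueError(
                    f"segments do not tile the genome: expected start {expected},"
                    f" got {seg.start}"
                )
            expected = seg.stop + 1
        if expected != self.genome_length + 1:
            raise ValueError(
                f"segments end at {expected - 1}, genome length {self.genome_length}"
            )
        known = [s for s in self.segments if s.parent != "unknown"]
        for s1, s2 in zip(known, known[1:]):
            if s1.parent == s2.parent:
                raise ValueError("consecutive segments share a parent")

    @property
    def n_crossovers(self) -> int:
        return len(self.breakpoints)


@dataclass(frozen=True)
class ProtocolParams:
    """Amplification parameters of the serial-selection protocol."""

    burst_size: float
    replication_rounds: int

    def __post_init__(self) -> None:
        if self.burst_size <= 1:
            raise ValueError("burst_size must be > 1")
        if self.replication_rounds < 1:
            raise ValueError("replication_rounds must be >= 1")


# ---------------------------------------------------------------------------


def _informative(sites: Iterable) -> list[tuple[int, int, str]]:
    """Extract (left_anchor, right_anchor, parent) for informative sites.

    Point sites have equal anchors; indel events gapped in the recombinant
    straddle a junction and carry ``(flank, flank + 1)``.
    """
    out = []
    for s in sites:
        if isinstance(s, SiteRecord):
            if s.is_informative:
                out.append((s.anchor_left, s.anchor_right, s.parent))
        elif isinstance(s, tuple):
            out.append((int(s[0]), int(s[0]), str(s[1])))
        else:
            raise TypeError(f"cannot interpret site {s!r}")
    return out


def infer_mosaic(sites: Sequence, genome_length: int) -> MosaicMap:
    """Assign parental ancestry by the left-to-right last-identity rule.

    ``sites`` are :class:`SiteRecord` objects in genome order (or bare
    ``(position, parent)`` tuples for informative sites).  Neither-parent
    sites never vote on ancestry — they are candidate mutations — but they
    do displace the reported crossover coordinate, which must be a base
    actually matching the outgoing parent.  Leading and trailing stretches
    with no informative site inherit the adjacent segment's parent; with no
    informative sites at all the whole genome is a single ``unknown``
    segment.
    """
    informative = _informative(sites)
    neither_positions = {
        s.r_position
        for s in sites
        if isinstance(s, SiteRecord)
        and s.resolution == "neither_parent"
        and s.r_position is not None
    }
    if informative and genome_length < max(p for p, _, _ in informative):
        raise ValueError(
            f"genome_length {genome_length} smaller than max site position"
        )
    if not informative:
        return MosaicMap(
            segments=(MosaicSegment(1, genome_length, "unknown"),),
            breakpoints=(),
            genome_length=genome_length,
            fraction_a=math.nan,
            fraction_b=math.nan,
        )

    segments: list[MosaicSegment] = []
    breakpoints: list[BreakpointCall] = []
    current = informative[0][2]
    last_current_left = informative[0][0]
    seg_start = 1
    for left, right, parent in informative[1:]:
        if parent != current:
            interval_left = last_current_left
            interval_right = right
            reported = interval_right - 1
            while reported > interval_left and reported in neither_positions:
                reported -= 1
            reported = max(reported, seg_start)  # guard zero-length segments
            n_neither = sum(
                1 for p in neither_positions if interval_left < p < interval_right
            )
            n_uninf = max(interval_right - interval_left - 1 - n_neither, 0)
            breakpoints.append(
                BreakpointCall(
                    index=len(breakpoints),
                    from_parent=current,
                    to_parent=parent,
                    reported_position=reported,
                    interval_left=interval_left,
                    interval_right=interval_right,
                    n_uninformative_between=n_uninf,
                )
            )
            segments.append(MosaicSegment(seg_start, reported, current))
            seg_start = reported + 1
            current = parent
        last_current_left = left
    segments.append(MosaicSegment(seg_start, genome_length, current))
    frac_a = sum(s.length for s in segments if s.parent == "A") / genome_length
    return MosaicMap(
        segments=tuple(segments),
        breakpoints=tuple(breakpoints),
        genome_length=genome_length,
        fraction_a=frac_a,
        fraction_b=1.0 - frac_a,
    )


def min_crossovers_oracle(sites: Sequence) -> tuple[int, list[str]]:
    """Exact minimal number of parental switches explaining all informative
    sites, by dynamic programming over (site, parent) states.

    Accepts :class:`SiteRecord` lists, ``(position, parent)`` tuples, or a
    bare sequence of ``"A"``/``"B"`` labels.  Ties are broken toward the
    latest possible switch.  Returns ``(count, optimal parent path)``.
    """
    if sites and isinstance(sites[0], str):
        labels = list(sites)
    else:
        labels = [p for _, _, p in _informative(sites)]
    if not labels:
        return 0, []
    inf = float("inf")
    # cost[p] = min switches for the prefix ending with the chain in parent p
    cost = {p: (0 if p == labels[0] else inf) for p in "AB"}
    back: list[dict[str, Optional[str]]] = [{p: None for p in "AB"}]
    for lab in labels[1:]:
        ncost = {}
        nback = {}
        for p in "AB":
            if p != lab:
                ncost[p] = inf
                nback[p] = None
                continue
            # prefer staying (latest possible switch) on ties
            stay = cost[p]
            switch = cost["A" if p == "B" else "B"] + 1
            if stay <= switch:
                ncost[p], nback[p] = stay, p
            else:
                ncost[p], nback[p] = switch, "A" if p == "B" else "B"
        cost = ncost
        back.append(nback)
    final = min("AB", key=lambda p: cost[p])
    path = [final]
    for bk in reversed(back[1:]):
        path.append(bk[path[-1]])
    path.reverse()
    return int(cost[final]), path


def heritage_fraction(mosaic: MosaicMap) -> tuple[float, float]:
    """Base-pair-weighted fraction of the genome from each parent.

    Raises if the map contains ``unknown`` segments (interval accounting
    would be needed instead).
    """
    if any(s.parent == "unknown" for s in mosaic.segments):
        raise ValueError(
            "mosaic contains unknown segments; heritage fractions are "
            "undefined -- account for the unknown intervals explicitly"
        )
    return (mosaic.fraction_a, mosaic.fraction_b)


def mosaic_from_crossovers(
    positions: Sequence[int],
    genome_length: int,
    first_parent: str = "A",
) -> MosaicMap:
    """Reconstruct a mosaic map from a printed crossover-position list.

    Segments alternate starting from ``first_parent``; each position is the
    last base of its outgoing segment.  Breakpoint intervals are degenerate
    (the printed table carries point estimates only).
    """
    positions = sorted(positions)
    if positions and (positions[0] < 1 or positions[-1] >= genome_length):
        raise ValueError("crossover positions must lie inside [1, L)")
    other = "B" if first_parent == "A" else "A"
    segments = []
    breakpoints = []
    start = 1
    current = first_parent
    for i, pos in enumerate(positions):
        segments.append(MosaicSegment(start, pos, current))
        nxt = other if current == first_parent else first_parent
        breakpoints.append(
            BreakpointCall(
                index=i,
                from_parent=current,
                to_parent=nxt,
                reported_position=pos,
                interval_left=pos,
                interval_right=pos + 1,
                n_uninformative_between=0,
            )
        )
        start = pos + 1
        current = nxt
    segments.append(MosaicSegment(start, genome_length, current))
    frac_a = sum(s.length for s in segments if s.parent == "A") / genome_length
    return MosaicMap(
        segments=tuple(segments),
        breakpoints=tuple(breakpoints),
        genome_length=genome_length,
        fraction_a=frac_a,
        fraction_b=1.0 - frac_a,
    )


def amplification_estimate(params, replication_rounds: Optional[int] = None) -> float:
    """Progeny count from exponential amplification: burst_size ** rounds.

    Accepts a :class:`ProtocolParams` or ``(burst_size, rounds)`` directly.
    """
    if isinstance(params, ProtocolParams):
        burst, rounds = params.burst_size, params.replication_rounds
    else:
        if replication_rounds is None:
            raise TypeError("pass ProtocolParams or (burst_size, rounds)")
        burst, rounds = ProtocolParams(params, replication_rounds).burst_size, replication_rounds
    return float(burst) ** rounds
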