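"""End-to-end orchestration: align, classify, infer mosaic, call variants,
summarise per ORF, and write machine-readable reports.

Outputs are deterministic given inputs and parameters; run metadata
(parameter values, input checksums, timestamp) is isolated in its own file
so that the analytic reports are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__
from .alignment import (
    SiteRecord,
    TrioAlignment,
    build_trio_alignment,
    classify_sites,
    find_homopolymer_runs,
)
from .io import GenomeRecord, OrfRecord, read_fasta, read_orf_table
from .mosaic import MosaicMap, infer_mosaic
from .variants import (
    OrfCrossoverSummary,
    VariantCall,
    adjudicate_variants,
    annotate_effect,
    call_variants,
    count_aa_differences,
    count_orf_crossovers,
)

logger = logging.getLogger("phagemosaic")

GenomeInput = Union[str, Path, GenomeRecord]


@dataclass
class PipelineConfig:
    """Inputs and parameters for one pipeline run.

    Genome fields accept FASTA paths or in-memory records.  ``outdir`` may
    be None for an in-memory run.
    """

    parent_a: GenomeInput
    parent_b: GenomeInput
    recombinant: GenomeInput
    orf_table: Optional[Union[str, Path]] = None
    orf_dialect: str = "tsv"
    prealigned: Optional[Union[str, Path]] = None
    k_anchor: int = 21
    min_run: int = 4
    min_len_homopolymer: int = 4
    compute_aa_diffs: bool = True
    outdir: Optional[Union[str, Path]] = None
    log_level: str = "INFO"


@dataclass
class ReportBundle:
    """All stage outputs of a run, plus paths of any files written."""

    alignment: TrioAlignment
    sites: list[SiteRecord]
    mosaic: MosaicMap
    variants: list[VariantCall]
    orf_summaries: list[OrfCrossoverSummary]
    summary: dict
    paths: dict = field(default_factory=dict)


def _load_genome(value: GenomeInput, role: str) -> GenomeRecord:
    if isinstance(value, GenomeRecord):
        return value
    records = read_fasta(value)
    if len(records) != 1:
        raise ValueError(f"{role}: expected exactly one FASTA record, got {len(records)}")
    return records[0]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; stage errors propagate with the stage name."""
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()

    def _stage(name, fn, *args, **kwargs):
        t = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t)
        return result

    pa = _load_genome(config.parent_a, "parent_a")
    pb = _load_genome(config.parent_b, "parent_b")
    rec = _load_genome(config.recombinant, "recombinant")

    if config.prealigned is not None:
        alignment = _stage(
            "align", build_trio_alignment, pa, pb, rec,
            mode="prealigned", prealigned=config.prealigned,
        )
    else:
        alignment = _stage(
            "align", build_trio_alignment, pa, pb, rec,
            mode="internal", k_anchor=config.k_anchor,
        )
    sites = _stage("classify", classify_sites, alignment)
    mosaic = _stage("mosaic", infer_mosaic, sites, rec.length)
    runs_a = find_homopolymer_runs(pa, min_len=config.min_len_homopolymer)
    runs_b = find_homopolymer_runs(pb, min_len=config.min_len_homopolymer)
    variants = _stage("variants", call_variants, sites, runs_a, runs_b)
    variants = adjudicate_variants(variants, min_run=config.min_run)

    orfs: list[OrfRecord] = []
    orf_summaries: list[OrfCrossoverSummary] = []
    if config.orf_table is not None:
        orfs = read_orf_table(config.orf_table, dialect=config.orf_dialect)
        variants = [annotate_effect(v, orfs, rec) for v in variants]
        orf_summaries = _stage(
            "orfsummary", count_orf_crossovers, mosaic.breakpoints, orfs
        )
        if config.compute_aa_diffs:
            import dataclasses

            by_id = {o.orf_id: o for o in orfs}
            orf_summaries = [
                dataclasses.replace(
                    s,
                    aa_diff_vs_a=count_aa_differences(by_id[s.orf_id], alignment, "A"),
                    aa_diff_vs_b=count_aa_differences(by_id[s.orf_id], alignment, "B"),
                )
                if not s.is_intergenic
                else s
                for s in orf_summaries
            ]

    n_accepted = sum(1 for v in variants if v.status == "accepted_mutation")
    summary = {
        "n_crossovers": mosaic.n_crossovers,
        "fraction_A": mosaic.fraction_a,
        "fraction_B": mosaic.fraction_b,
        "genome_length": mosaic.genome_length,
        "n_segments": len(mosaic.segments),
        "n_variants": len(variants),
        "n_accepted_mutations": n_accepted,
        "n_suspected_errors": len(variants) - n_accepted,
        "n_informative_sites": sum(1 for s in sites if s.is_informative),
        "n_orfs": len(orfs),
    }
    bundle = ReportBundle(alignment, sites, mosaic, variants, orf_summaries, summary)
    if config.outdir is not None:
        _write_reports(bundle, config, (pa, pb, rec))
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return bundle


# ---------------------------------------------------------------------------
# report writing


def _write_reports(bundle: ReportBundle, config: PipelineConfig, genomes) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seg_path = outdir / "segments.tsv"
    with open(seg_path, "w") as fh:
        fh.write("start\tstop\tparent\n")
        for s in bundle.mosaic.segments:
            fh.write(f"{s.start}\t{s.stop}\t{s.parent}\n")

    bp_path = outdir / "breakpoints.tsv"
    with open(bp_path, "w") as fh:
        fh.write(
            "index\tfrom_parent\tto_parent\treported_position\t"
            "interval_left\tinterval_right\tn_uninformative_between\n"
        )
        for b in bundle.mosaic.breakpoints:
            fh.write(
                f"{b.index}\t{b.from_parent}\t{b.to_parent}\t{b.reported_position}\t"
                f"{b.interval_left}\t{b.interval_right}\t{b.n_uninformative_between}\n"
            )

    var_path = outdir / "variants.tsv"
    with open(var_path, "w") as fh:
        fh.write(
            "r_position\tallele_A\tallele_B\tallele_R\tkind\t"
            "homopolymer_context\tstatus\teffect\n"
        )
        for v in bundle.variants:
            fh.write(
                f"{v.r_position}\t{v.allele_a or '.'}\t{v.allele_b or '.'}\t"
                f"{v.allele_r or '.'}\t{v.kind}\t{v.homopolymer_context}\t"
                f"{v.status}\t{v.effect or '.'}\n"
            )

    paths = {"segments": seg_path, "breakpoints": bp_path, "variants": var_path}

    if bundle.orf_summaries:
        orf_path = outdir / "orf_summary.tsv"
        with open(orf_path, "w") as fh:
            fh.write(
                "orf_id\tn_crossovers\tcrossover_positions\t"
                "aa_diff_vs_A\taa_diff_vs_B\tintergenic\n"
            )
            for s in bundle.orf_summaries:
                pos = ";".join(map(str, s.crossover_positions)) or "."
                fh.write(
                    f"{s.orf_id}\t{s.n_crossovers}\t{pos}\t"
                    f"{s.aa_diff_vs_a if s.aa_diff_vs_a is not None else '.'}\t"
                    f"{s.aa_diff_vs_b if s.aa_diff_vs_b is not None else '.'}\t"
                    f"{int(s.is_intergenic)}\n"
                )
        paths["orf_summary"] = orf_path

    sum_path = outdir / "summary.json"
    sum_path.write_text(json.dumps(bundle.summary, indent=1, sort_keys=True) + "\n")
    paths["summary"] = sum_path

    meta = {
        "tool_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            "k_anchor": config.k_anchor,
            "min_run": config.min_run,
            "min_len_homopolymer": config.min_len_homopolymer,
        },
        "input_sha256": {
            g.id: hashlib.sha256(g.sequence.encode()).hexdigest() for g in genomes
        },
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    paths["metadata"] = meta_path
    bundle.paths = {k: str(v) for k, v in paths.items()}


def render_text_map(mosaic: MosaicMap, width: int = 100) -> str:
    """ASCII segment track: one glyph per bin of the genome (A/B/?)."""
    glyphs = {"A": "A", "B": "B", "unknown": "?"}
    L = mosaic.genome_length
    bp_per_char = max(1, L // width)
    out = []
    seg_iter = iter(mosaic.segments)
    seg = next(seg_iter)
    for start in range(1, L + 1, bp_per_char):
        while seg.stop < start:
            seg = next(seg_iter)
        out.append(glyphs[seg.parent])
    return "".join(out)
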