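"""End-to-end pipeline stages and run manifests.

``run_simulate`` writes a synthetic screen to disk (SAM + optional FASTQ
per sample, sample sheet, truth tables, gene BED); ``run_screen`` takes
alignments + sample sheet + annotation through VIS calling, the filtering
cascade, the statistics, candidate selection and verification;
``run_validate`` runs the single-cell fraction-positive validation.  Every
stage records its inputs, configuration, seeds and record counts in a JSON
run manifest so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .scrna import concordance, validate_genes
from .screen_stats import (
    filter_replicate_concordance,
    filter_singletons,
    filter_treatment_concordance,
    scatter_table,
    screen_tests,
    select_candidates,
    summarize_partitions,
    verify_candidates,
    volcano_table,
)
from .synthetic import (
    CloneTable,
    GenomeModel,
    ScreenDesign,
    read_bed,
    simulate_screen,
    write_bed,
    write_fastq,
    write_sam,
)
from .vis_calling import (
    LocusSampleMatrix,
    SAMPLE_COLUMNS,
    annotate_loci,
    call_vis,
    filter_alignments,
    quantify,
    read_sam,
    write_loci_bed,
    write_matrix_tsvs,
)

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_screen", "run_validate", "SchemaError", "ScreenOutput"]


class SchemaError(ValueError):
    """Malformed tabular input (missing columns, bad labels)."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(
    outdir: Path,
    stage: str,
    *,
    config: PipelineConfig,
    seeds: Mapping[str, int] | None = None,
    inputs: Sequence[Path] = (),
    counts: Mapping[str, int] | None = None,
) -> Path:
    manifest = {
        "tool": "visscreen",
        "version": __version__,
        "stage": stage,
        "config": config.to_dict(),
        "seeds": dict(seeds or {}),
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "counts": dict(counts or {}),
    }
    path = outdir / f"manifest.{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(
    design: ScreenDesign,
    clones: CloneTable,
    genome: GenomeModel,
    seed: int,
    outdir: str | Path,
    *,
    config: PipelineConfig | None = None,
    emit_reads: bool = False,
) -> dict[str, Path]:
    """Simulate a screen and write all artifacts to ``outdir``."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_screen(design, clones, genome, seed, emit_reads=emit_reads)

    paths: dict[str, Path] = {}
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    sim.samples.to_csv(paths["sample_sheet"], sep="\t", index=False)
    paths["annotation"] = outdir / "genes.bed"
    write_bed(genome.genes, paths["annotation"])
    paths["truth_directions"] = outdir / "truth_directions.tsv"
    sim.truth_directions.to_csv(paths["truth_directions"], sep="\t", index_label="clone_id")
    paths["truth_abundances"] = outdir / "truth_abundances.tsv"
    sim.truth_abundances.to_csv(paths["truth_abundances"], sep="\t", index_label="clone_id")
    paths["clones"] = outdir / "truth_clones.tsv"
    sim.clones.clones.to_csv(paths["clones"], sep="\t", index=False)

    sam_dir = outdir / "alignments"
    sam_dir.mkdir(exist_ok=True)
    for sample_id, grp in sim.alignments.groupby("sample_id"):
        write_sam(grp, genome, sam_dir / f"{sample_id}.sam", read_length=design.read_length)
    paths["alignments_dir"] = sam_dir
    if emit_reads:
        fq_dir = outdir / "reads"
        fq_dir.mkdir(exist_ok=True)
        for sample_id, reads in sim.reads.items():
            write_fastq(reads, fq_dir / f"{sample_id}.fastq")
        paths["reads_dir"] = fq_dir

    _write_manifest(
        outdir,
        "simulate",
        config=config,
        seeds={"rng_seed": seed},
        counts={
            "samples": len(sim.samples),
            "alignments": len(sim.alignments),
            "clones": len(clones),
        },
    )
    return paths


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenOutput:
    matrix_raw: LocusSampleMatrix
    matrix: LocusSampleMatrix           # after the full filtering cascade
    results: dict[str, pd.DataFrame]    # treatment -> ScreenResult table
    candidates: pd.DataFrame
    partition: pd.DataFrame
    stage_counts: dict[str, int]


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample sheet {path} missing column(s): {missing}")
    bad = samples[~samples["biological_replicate"].isin(["pLN1", "pLN2"])]
    if len(bad):
        raise SchemaError(
            f"sample sheet rows {list(bad.index + 2)}: biological_replicate must be pLN1/pLN2"
        )
    return samples.set_index("sample_id")


def screen_from_frames(
    alignments: pd.DataFrame,
    samples: pd.DataFrame,
    genome: GenomeModel,
    config: PipelineConfig | None = None,
) -> ScreenOutput:
    """VIS calling + cascade + statistics on in-memory frames."""
    config = config or PipelineConfig()
    scfg = config.screen
    filtered = filter_alignments(alignments, config.vis.mapq_min)
    loci = call_vis(filtered, config.vis.window_bp)
    loci = annotate_loci(loci, genome)
    matrix_raw = quantify(
        loci, filtered, samples, min_reads_detect=config.vis.min_reads_detect
    )
    m1 = filter_singletons(matrix_raw)
    m2 = filter_replicate_concordance(m1)
    m3 = filter_treatment_concordance(m2, scfg.control_label)

    present = set(m3.samples["treatment"])
    discovery = [t for t in scfg.candidate_treatments if t in present]
    results = {t: screen_tests(m3, t, scfg) for t in discovery}
    gene_map = m3.loci["nearest_gene"].to_dict()
    candidates = select_candidates(results, gene_map, scfg)

    verification = [t for t in scfg.verification_treatments if t in present]
    if len(candidates) and verification:
        candidates = verify_candidates(candidates, m3, verification)

    stage_counts = {
        "loci_total": len(matrix_raw.loci),
        "singletons_removed": matrix_raw.detected.shape[0] - m1.detected.shape[0],
        "replicate_discordant_removed": m1.detected.shape[0] - m2.detected.shape[0],
        "treatment_discordant_removed": m2.detected.shape[0] - m3.detected.shape[0],
        "loci_tested": m3.detected.shape[0],
        "candidate_genes": len(candidates),
    }
    partition = summarize_partitions(
        {
            "cascade": {
                "total": stage_counts["loci_total"],
                "exclusions": {
                    "singletons": stage_counts["singletons_removed"],
                    "replicate_discordant": stage_counts["replicate_discordant_removed"],
                    "treatment_discordant": stage_counts["treatment_discordant_removed"],
                },
                "retained": stage_counts["loci_tested"],
            }
        }
    ).table
    return ScreenOutput(
        matrix_raw=matrix_raw,
        matrix=m3,
        results=results,
        candidates=candidates,
        partition=partition,
        stage_counts=stage_counts,
    )


def run_screen(
    alignment_paths: Sequence[str | Path],
    sample_sheet: str | Path,
    annotation: str | Path,
    outdir: str | Path,
    *,
    config: PipelineConfig | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ScreenOutput:
    """File-based screen run: SAM files in, result tables out."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = load_sample_sheet(sample_sheet)
    genes = read_bed(annotation)

    frames = []
    for i, path in enumerate(alignment_paths):
        sid = sample_ids[i] if sample_ids else Path(path).stem
        if sid not in samples.index:
            raise SchemaError(f"alignment file {path}: sample {sid!r} not in sample sheet")
        frames.append(read_sam(path, sample_id=sid))
    alignments = pd.concat(frames, ignore_index=True)

    # chromosome lengths from SAM headers are not required: infer an upper
    # bound from the data so annotation distances remain well defined.
    chrom_lengths: dict[str, int] = {}
    for chrom, grp in alignments.groupby("chromosome"):
        chrom_lengths[chrom] = int(grp["position"].max()) + 1
    for _, g in genes.iterrows():
        chrom_lengths[g["chromosome"]] = max(
            chrom_lengths.get(g["chromosome"], 0), int(g["end"])
        )
    genome = GenomeModel(chromosomes=chrom_lengths, genes=genes)

    out = screen_from_frames(alignments, samples, genome, config)

    write_loci_bed(out.matrix_raw.loci, outdir / "loci.bed")
    write_matrix_tsvs(out.matrix_raw, outdir / "vis")
    result_rows = [tab.reset_index() for tab in out.results.values()]
    if result_rows:
        all_results = pd.concat(result_rows, ignore_index=True)
        all_results.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
        pd.concat(
            [scatter_table(t.reset_index().set_index("locus_id")) for t in out.results.values()]
        ).to_csv(outdir / "scatter_source.tsv", sep="\t", index_label="locus_id")
        pd.concat(
            [volcano_table(t.reset_index().set_index("locus_id")) for t in out.results.values()]
        ).to_csv(outdir / "volcano_source.tsv", sep="\t", index_label="locus_id")
    out.candidates.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
    out.partition.to_csv(outdir / "partition_summary.tsv", sep="\t", index=False)

    _write_manifest(
        outdir,
        "screen",
        config=config,
        inputs=[Path(sample_sheet), Path(annotation)],
        counts=out.stage_counts,
    )
    return out


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------

def run_validate(
    counts: pd.DataFrame,
    labels: pd.Series,
    candidates: pd.DataFrame,
    outdir: str | Path,
    *,
    config: PipelineConfig | None = None,
    screen_directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fraction-positive validation of the candidate gene list."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(candidates) == 0:
        logger.warning("empty candidate list: nothing to validate")
        empty = pd.DataFrame()
        empty.to_csv(outdir / "validation_results.tsv", sep="\t")
        return empty
    result = validate_genes(
        counts,
        labels,
        list(candidates["gene"]),
        threshold=config.scrna.cpm_threshold,
        yates=config.scrna.yates,
        alias_map=config.scrna.alias_map,
    )
    if screen_directions is not None:
        result = concordance(result, screen_directions)
    result.to_csv(outdir / "validation_results.tsv", sep="\t", index_label="gene")
    _write_manifest(
        outdir,
        "validate",
        config=config,
        counts={"genes_tested": len(result), "cells": counts.shape[1]},
    )
    return result
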