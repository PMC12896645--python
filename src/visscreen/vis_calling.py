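"""Viral integration-site (VIS) calling from alignment records.

Alignments from all samples are pooled, filtered at MAPQ >= 20, and
collapsed per chromosome by single-linkage chaining: consecutive sorted
positions separated by at most ``window_bp`` (default 1000, closed
boundary) join the same locus, so locus identities are shared across
samples.  Each locus is then quantified per sample (read counts, reads per
million over VIS-assigned reads) and annotated with its nearest gene.

Coordinates are 0-based half-open throughout; a locus's representative
position is the lower median of its member read positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GenomeModel

logger = logging.getLogger(__name__)

__all__ = [
    "LocusSampleMatrix",
    "read_sam",
    "filter_alignments",
    "call_vis",
    "quantify",
    "annotate_loci",
    "write_loci_bed",
    "write_matrix_tsvs",
]

ALIGNMENT_COLUMNS = ["read_id", "sample_id", "chromosome", "position", "orientation", "mapq"]

SAMPLE_COLUMNS = ["sample_id", "treatment", "biological_replicate", "timepoint_months"]


@dataclass
class LocusSampleMatrix:
    """Cross-sample VIS table.

    ``loci``: locus_id, chromosome, start, end, representative_position,
    n_reads, n_plus, n_minus (+ nearest_gene/gene_distance after
    annotation), indexed by locus_id.
    ``samples``: sample metadata indexed by sample_id.
    ``read_counts`` / ``rpm`` / ``detected``: loci × samples frames.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    read_counts: pd.DataFrame
    rpm: pd.DataFrame
    detected: pd.DataFrame
    min_reads_detect: int = 1
    meta: dict = field(default_factory=dict)

    def subset(self, locus_ids) -> "LocusSampleMatrix":
        ids = list(locus_ids)
        return LocusSampleMatrix(
            loci=self.loci.loc[ids],
            samples=self.samples,
            read_counts=self.read_counts.loc[ids],
            rpm=self.rpm.loc[ids],
            detected=self.detected.loc[ids],
            min_reads_detect=self.min_reads_detect,
            meta=dict(self.meta),
        )

    def samples_for(self, treatment: str) -> list[str]:
        mask = self.samples["treatment"] == treatment
        return list(self.samples.index[mask])


def read_sam(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read mapped records from a SAM/BAM file into the alignment frame.

    Uses the leftmost reference position, MAPQ, and the reverse flag for
    orientation; unmapped and secondary/supplementary records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                (
                    rec.query_name,
                    sample_id if sample_id is not None else Path(path).stem,
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    rec.mapping_quality,
                )
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def filter_alignments(alignments: pd.DataFrame, mapq_min: int = 20) -> pd.DataFrame:
    """Drop records with mapping quality below ``mapq_min``; order preserved."""
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    return alignments[alignments["mapq"] >= mapq_min].reset_index(drop=True)


def call_vis(alignments: pd.DataFrame, window_bp: int = 1000) -> pd.DataFrame:
    """Collapse pooled read positions into loci by single-linkage chaining.

    Per chromosome, sorted positions whose consecutive gap is <= window_bp
    belong to one locus (transitive closure of the pairwise relation).
    Returns the locus table with stable ids ordered by (chromosome, start).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    rows = []
    for chrom in sorted(alignments["chromosome"].unique()):
        sub = alignments[alignments["chromosome"] == chrom]
        pos = np.sort(sub["position"].to_numpy())
        breaks = np.flatnonzero(np.diff(pos) > window_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(pos)]))
        orient = sub.sort_values("position", kind="mergesort")["orientation"].to_numpy()
        for lo, hi in zip(starts, ends):
            members = pos[lo:hi]
            n = hi - lo
            n_plus = int((orient[lo:hi] == "+").sum())
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(members[0]),
                    "end": int(members[-1]) + 1,
                    "representative_position": int(members[(n - 1) // 2]),
                    "n_reads": int(n),
                    "n_plus": n_plus,
                    "n_minus": int(n - n_plus),
                }
            )
    loci = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "start", "end", "representative_position",
            "n_reads", "n_plus", "n_minus",
        ],
    )
    loci = loci.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    loci.insert(0, "locus_id", [f"VIS{i + 1:05d}" for i in range(len(loci))])
    return loci.set_index("locus_id")


def _assign_loci(alignments: pd.DataFrame, loci: pd.DataFrame) -> pd.Series:
    """Map each alignment to the locus containing its position."""
    out = pd.Series(index=alignments.index, dtype=object)
    for chrom, sub in alignments.groupby("chromosome"):
        lsub = loci[loci["chromosome"] == chrom]
        if lsub.empty:
            raise ValueError(f"alignments on {chrom} fall outside all loci")
        starts = lsub["start"].to_numpy()
        ends = lsub["end"].to_numpy()
        idx = np.searchsorted(starts, sub["position"].to_numpy(), side="right") - 1
        if (idx < 0).any() or (sub["position"].to_numpy() >= ends[np.clip(idx, 0, None)]).any():
            raise ValueError(f"alignment outside all loci on {chrom} (pipeline misuse)")
        out.loc[sub.index] = lsub.index.to_numpy()[idx]
    return out


def quantify(
    loci: pd.DataFrame,
    alignments: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    min_reads_detect: int = 1,
) -> LocusSampleMatrix:
    """Per-locus × per-sample read counts, RPM, and detection flags.

    RPM normalizes each sample's locus counts to one million over the
    VIS-assigned reads of that sample; samples with zero assigned reads get
    all-zero RPM (logged).  Every alignment must fall inside a locus called
    on the same pooled input.
    """
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id")
    locus_of = _assign_loci(alignments, loci)
    tab = (
        pd.crosstab(locus_of, alignments["sample_id"])
        .reindex(index=loci.index, columns=samples.index, fill_value=0)
        .astype(int)
    )
    totals = tab.sum(axis=0)
    empty = totals[totals == 0].index
    if len(empty):
        logger.warning("samples with zero VIS-assigned reads: %s", list(empty))
    denom = totals.replace(0, 1)
    rpm = tab * 1e6 / denom
    detected = tab >= min_reads_detect
    return LocusSampleMatrix(
        loci=loci,
        samples=samples,
        read_counts=tab,
        rpm=rpm,
        detected=detected,
        min_reads_detect=min_reads_detect,
        meta={"rpm_denominator": "vis_assigned_reads_per_sample"},
    )


def annotate_loci(loci: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Attach nearest gene and distance to each locus.

    Distance is 0 when the representative position lies inside a gene,
    otherwise the gap to the nearest interval edge on the same chromosome.
    Equidistant ties go to the gene with the smaller start, then the
    lexicographically smaller name; chromosomes without genes yield None.
    """
    loci = loci.copy()
    names: list[object] = []
    dists: list[object] = []
    genes = genome.genes
    by_chrom = {c: g.sort_values(["start", "name"]) for c, g in genes.groupby("chromosome")}
    for row in loci.itertuples():
        g = by_chrom.get(row.chromosome)
        if g is None or g.empty:
            names.append(None)
            dists.append(np.nan)
            continue
        pos = row.representative_position
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        dist = np.where(
            (pos >= starts) & (pos < ends),
            0,
            np.where(pos < starts, starts - pos, pos - ends),
        )
        best = int(np.min(dist))
        cand = g.iloc[np.flatnonzero(dist == best)]
        cand = cand.sort_values(["start", "name"]).iloc[0]
        names.append(cand["name"])
        dists.append(best)
    loci["nearest_gene"] = names
    loci["gene_distance"] = dists
    return loci


def write_loci_bed(loci: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus_id, row in loci.iterrows():
            fh.write(
                f"{row['chromosome']}\t{row['start']}\t{row['end']}\t"
                f"{locus_id}\t{row['n_reads']}\t+\n"
            )


def write_matrix_tsvs(matrix: LocusSampleMatrix, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    paths = {}
    for name, frame in (
        ("read_counts", matrix.read_counts),
        ("rpm", matrix.rpm),
        ("detected", matrix.detected.astype(int)),
    ):
        p = prefix.parent / f"{prefix.name}.{name}.tsv"
        frame.to_csv(p, sep="\t", index_label="locus_id")
        paths[name] = p
    return paths
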