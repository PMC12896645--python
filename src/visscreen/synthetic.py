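"""Synthetic retroviral resistance screens with known ground truth.

This module emulates the experiment end to end so that every downstream
stage is testable without external data:

* a toy genome with a non-overlapping gene annotation,
* a clonal population of uniquely integrated cells (one integration per
  clone) with Dirichlet baseline abundances and per-treatment fitness
  weights,
* drug selection as discrete passages of fitness-weighted multinomial
  resampling (Wright–Fisher with selection), which produces both
  enrichment of resistant clones and neutral drift,
* junction sequencing of each sample: reads are drawn per clone
  proportionally to abundance and placed at the integration point plus a
  bounded sonication offset, with a configurable MAPQ mixture so the
  mapping-quality filter is exercised,
* a parental vs resistant single-cell expression matrix with planted
  per-gene positive-cell probabilities.

Randomness is hierarchical: each top-level operation takes one integer
seed, and per-sample streams are split off a ``numpy.random.SeedSequence``
so results are reproducible and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeModel",
    "CloneTable",
    "TreatmentArm",
    "ScreenDesign",
    "ScreenSimulation",
    "ReadRecord",
    "make_genome",
    "plant_integrations",
    "evolve_population",
    "simulate_sample",
    "simulate_screen",
    "simulate_scrna",
    "discovery_screen_design",
    "write_fastq",
    "write_sam",
    "write_bed",
]

# Stand-in adapter sequences flanking the genomic part of each amplicon.
# These are synthetic: the real vector LTR and linker oligos are custom and
# not modelled; any fixed non-repetitive sequence exercises the trimmer.
DEFAULT_LTR = "TGTGGAAAATCTCTAGCAGT"
DEFAULT_LINKER = "AGATCGGAAGAGCACACGTC"

REPLICATES = ("pLN1", "pLN2")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Chromosome lengths plus a sorted, non-overlapping gene annotation.

    ``genes`` has columns name/chromosome/start/end/strand with 0-based
    half-open coordinates, sorted by (chromosome, start).
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["name", "chromosome", "start", "end", "strand"]
        if list(self.genes.columns) != req:
            self.genes = self.genes.loc[:, req]
        if len(self.genes):
            if self.genes["name"].duplicated().any():
                raise ValueError("gene names must be unique")
            if (self.genes["start"] >= self.genes["end"]).any():
                raise ValueError("gene intervals need start < end")
            for _, g in self.genes.iterrows():
                length = self.chromosomes.get(g["chromosome"])
                if length is None or g["end"] > length or g["start"] < 0:
                    raise ValueError(f"gene {g['name']} outside its chromosome")
        self.genes = (
            self.genes.sort_values(["chromosome", "start"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))


@dataclass
class CloneTable:
    """Ground-truth integration clones.

    ``clones``: clone_id, chromosome, position, orientation, baseline_abundance.
    ``fitness``: clone × treatment per-passage multiplicative weights
    (missing treatment ⇒ neutral, weight 1).
    """

    clones: pd.DataFrame
    fitness: pd.DataFrame

    def __post_init__(self) -> None:
        total = float(self.clones["baseline_abundance"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline abundances sum to {total}, not 1")
        if (self.fitness.values <= 0).any():
            raise ValueError("fitness weights must be > 0")

    def __len__(self) -> int:
        return len(self.clones)

    def fitness_for(self, treatment: str) -> np.ndarray:
        """Per-clone weight vector for a treatment; absent names are neutral."""
        if treatment in self.fitness.columns:
            return self.fitness[treatment].to_numpy(float)
        logger.info("treatment %r absent from fitness table; treating as neutral", treatment)
        return np.ones(len(self), float)


@dataclass
class TreatmentArm:
    """One screen arm: samples per biological replicate and passage count."""

    name: str
    n_samples: dict[str, int]          # replicate label -> sample count
    n_passages: int = 8

    def __post_init__(self) -> None:
        if self.n_passages < 0:
            raise ValueError("n_passages must be >= 0")
        missing = [r for r in REPLICATES if self.n_samples.get(r, 0) == 0]
        if missing:
            logger.warning("treatment %s is unbalanced: no samples in %s", self.name, missing)

    @property
    def total(self) -> int:
        return sum(self.n_samples.values())


@dataclass
class ScreenDesign:
    treatments: list[TreatmentArm]
    reads_per_sample: int = 50_000
    population_size: int = 20_000
    read_length: int = 150
    offset_spread: int = 500
    passages_per_month: int = 2        # biweekly split

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        names = [t.name for t in self.treatments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate treatment names in design")

    @property
    def n_samples(self) -> int:
        return sum(t.total for t in self.treatments)


def discovery_screen_design(
    *,
    reads_per_sample: int = 50_000,
    population_size: int = 20_000,
    n_passages: int = 8,
) -> ScreenDesign:
    """The 60-sample discovery screen: 19 untreated controls plus 41 treated
    samples over six regimens, each split across the two biological
    replicates (split near-evenly; the exact per-replicate split is not a
    published quantity)."""
    counts = {
        "NC": 19,
        "tamoxifen": 8,
        "fulvestrant": 15,
        "ribociclib": 7,
        "palbociclib": 4,
        "abemaciclib": 4,
        "fulvestrant+ribociclib": 3,
    }
    arms = []
    for name, n in counts.items():
        half = n // 2
        arms.append(
            TreatmentArm(name, {"pLN1": n - half, "pLN2": half}, n_passages=n_passages)
        )
    return ScreenDesign(
        treatments=arms,
        reads_per_sample=reads_per_sample,
        population_size=population_size,
    )


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities lengths differ")


@dataclass
class ScreenSimulation:
    """Everything a screen run produces, with truth attached."""

    samples: pd.DataFrame                 # sample_id, treatment, replicate, timepoint_months
    alignments: pd.DataFrame              # read_id, sample_id, chromosome, position, orientation, mapq
    reads: dict[str, list[ReadRecord]] = field(default_factory=dict)
    truth_directions: pd.DataFrame = None  # clone_id × treatment -> enriched/depleted/neutral
    truth_abundances: pd.DataFrame = None  # clone_id × sample_id final abundances
    clones: CloneTable = None
    genome: GenomeModel = None


# ---------------------------------------------------------------------------
# Genome and clones
# ---------------------------------------------------------------------------

def make_genome(
    n_chromosomes: int,
    chrom_length: int,
    n_genes: int,
    rng_seed: int,
    *,
    gene_length: int = 2_000,
) -> GenomeModel:
    """Random genome with ``n_genes`` non-overlapping genes of fixed length
    spread uniformly over the chromosomes. Deterministic for a fixed seed;
    raises if the genes cannot be placed without overlap."""
    if n_chromosomes < 1 or chrom_length < 1:
        raise ValueError("need at least one chromosome of positive length")
    rng = np.random.default_rng(rng_seed)
    chroms = {f"chr{i + 1}": int(chrom_length) for i in range(n_chromosomes)}
    per_chrom = np.bincount(
        rng.integers(0, n_chromosomes, size=n_genes), minlength=n_chromosomes
    )
    rows = []
    gene_idx = 0
    for ci, (cname, clen) in enumerate(chroms.items()):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        # place k genes by sampling gap budget; infeasible if k*len > clen
        free = clen - k * gene_length
        if free < 0:
            raise ValueError(
                f"cannot place {k} genes of {gene_length} bp on {cname} ({clen} bp) without overlap"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        starts = cuts + gene_length * np.arange(k)
        for s in starts:
            gene_idx += 1
            rows.append((f"GENE{gene_idx:04d}", cname, int(s), int(s) + gene_length, "+"))
    genes = pd.DataFrame(rows, columns=["name", "chromosome", "start", "end", "strand"])
    return GenomeModel(chromosomes=chroms, genes=genes)


def plant_integrations(
    genome: GenomeModel,
    n_clones: int,
    fitness_spec: Mapping[str, Sequence[tuple[int, float]]] | None,
    rng_seed: int,
    *,
    concentration: float = 1.0,
    min_spacing: int = 0,
) -> CloneTable:
    """Plant ``n_clones`` uniquely integrated clones uniformly over the genome.

    ``fitness_spec`` maps treatment name → list of (clone index, per-passage
    weight); unlisted clones are neutral (weight 1). Baseline abundances are
    symmetric-Dirichlet(``concentration``). ``min_spacing`` > 0 redraws
    positions until all same-chromosome integration points are at least that
    far apart (rejection sampling), so locus↔clone identity stays decidable.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(rng_seed)
    chrom_names = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chrom_names], dtype=np.int64)
    probs = lengths / lengths.sum()

    for _attempt in range(1000):
        cidx = rng.choice(len(chrom_names), size=n_clones, p=probs)
        pos = rng.integers(0, lengths[cidx])
        if min_spacing <= 0:
            break
        ok = True
        df = pd.DataFrame({"c": cidx, "p": pos})
        for _, grp in df.groupby("c"):
            d = np.diff(np.sort(grp["p"].to_numpy()))
            if len(d) and d.min() < min_spacing:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not satisfy min_spacing after 1000 attempts")

    abundances = rng.dirichlet(np.full(n_clones, concentration))
    orientation = np.where(rng.random(n_clones) < 0.5, "+", "-")
    clones = pd.DataFrame(
        {
            "clone_id": [f"clone{i:04d}" for i in range(n_clones)],
            "chromosome": [chrom_names[i] for i in cidx],
            "position": pos.astype(int),
            "orientation": orientation,
            "baseline_abundance": abundances,
        }
    )
    fitness = pd.DataFrame(index=clones["clone_id"])
    fitness["NC"] = 1.0
    if fitness_spec:
        for treatment, entries in fitness_spec.items():
            col = np.ones(n_clones, float)
            for idx, weight in entries:
                if weight <= 0:
                    raise ValueError("fitness weights must be > 0")
                col[idx] = weight
            fitness[treatment] = col
    return CloneTable(clones=clones, fitness=fitness)


def truth_directions(clones: CloneTable) -> pd.DataFrame:
    """Expected per-treatment direction per clone from fitness weights."""
    out = pd.DataFrame(index=clones.clones["clone_id"])
    for treatment in clones.fitness.columns:
        w = clones.fitness[treatment].to_numpy(float)
        out[treatment] = np.select([w > 1, w < 1], ["enriched", "depleted"], "neutral")
    return out


# ---------------------------------------------------------------------------
# Selection and sequencing
# ---------------------------------------------------------------------------

def evolve_population(
    clones: CloneTable,
    treatment: str,
    n_passages: int,
    population_size: int,
    rng_seed: int | np.random.Generator,
) -> np.ndarray:
    """Wright–Fisher selection: each passage reweights abundances by the
    clone fitness for ``treatment`` and resamples ``population_size`` cells
    multinomially. ``n_passages = 0`` returns the baseline unchanged."""
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    a = clones.clones["baseline_abundance"].to_numpy(float).copy()
    f = clones.fitness_for(treatment)
    for _ in range(n_passages):
        w = a * f
        w_sum = w.sum()
        if w_sum <= 0:
            raise RuntimeError("population went extinct")
        counts = rng.multinomial(population_size, w / w_sum)
        a = counts / population_size
    return a


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_sample(
    clones: CloneTable,
    abundances: np.ndarray,
    reads_per_sample: int,
    genome: GenomeModel,
    rng_seed: int | np.random.Generator,
    *,
    sample_id: str = "sample",
    offset_spread: int = 500,
    read_length: int = 150,
    ltr: str = DEFAULT_LTR,
    linker: str = DEFAULT_LINKER,
    mapq_high: int = 60,
    mapq_high_frac: float = 0.95,
    emit_reads: bool = True,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw junction reads for one sample.

    Each read picks a clone with probability proportional to abundance. Its
    alignment sits at the integration point plus a sonication offset of at
    most ``offset_spread`` bp, always on the genomic side of the junction
    (downstream for ``+`` clones, upstream for ``-``). MAPQ is a mixture:
    ``mapq_high_frac`` of reads at ``mapq_high``, the rest uniform on 0–19
    so the quality filter has something to remove. Read sequences are
    LTR + random genomic flank + linker truncated to ``read_length``
    (sequence content is synthetic; alignment is never re-performed).
    """
    if len(abundances) != len(clones):
        raise ValueError("abundances do not match clone count")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cols = ["read_id", "sample_id", "chromosome", "position", "orientation", "mapq"]
    if reads_per_sample == 0:
        return [], pd.DataFrame(columns=cols)

    a = np.asarray(abundances, float)
    counts = rng.multinomial(reads_per_sample, a / a.sum())
    clone_idx = np.repeat(np.arange(len(clones)), counts)
    rng.shuffle(clone_idx)

    pos0 = clones.clones["position"].to_numpy()[clone_idx]
    orient = clones.clones["orientation"].to_numpy()[clone_idx]
    chrom = clones.clones["chromosome"].to_numpy()[clone_idx]
    offsets = rng.integers(0, offset_spread + 1, size=reads_per_sample)
    pos = np.where(orient == "+", pos0 + offsets, pos0 - offsets)
    limits = np.array([genome.chromosomes[c] for c in chrom])
    pos = np.clip(pos, 0, limits - 1)

    low = rng.random(reads_per_sample) >= mapq_high_frac
    mapq = np.full(reads_per_sample, mapq_high, dtype=int)
    mapq[low] = rng.integers(0, 20, size=int(low.sum()))

    read_ids = [f"{sample_id}:r{i:07d}" for i in range(reads_per_sample)]
    alignments = pd.DataFrame(
        {
            "read_id": read_ids,
            "sample_id": sample_id,
            "chromosome": chrom,
            "position": pos.astype(int),
            "orientation": orient,
            "mapq": mapq,
        }
    )

    reads: list[ReadRecord] = []
    if emit_reads:
        flank_len = max(read_length - len(ltr), 0)
        for rid in read_ids:
            seq = (ltr + _random_flank(rng, flank_len) + linker)[:read_length]
            reads.append(ReadRecord(rid, seq, "I" * len(seq)))
    return reads, alignments


def simulate_screen(
    design: ScreenDesign,
    clones: CloneTable,
    genome: GenomeModel,
    rng_seed: int,
    *,
    emit_reads: bool = True,
) -> ScreenSimulation:
    """Run the full screen: one independent selection trajectory and one
    sequencing draw per sample, with replicate labels and truth attached.
    Samples alternate between the 1-month and 2-month harvest timepoints
    (timepoints are pooled downstream, matching the analysis)."""
    seed_seq = np.random.SeedSequence(rng_seed)
    sample_rows = []
    aln_frames = []
    reads: dict[str, list[ReadRecord]] = {}
    abund_cols: dict[str, np.ndarray] = {}

    specs = []
    for arm in design.treatments:
        for replicate in REPLICATES:
            for k in range(arm.n_samples.get(replicate, 0)):
                specs.append((arm, replicate, k))
    children = seed_seq.spawn(len(specs))

    for (arm, replicate, k), child in zip(specs, children):
        rng = np.random.default_rng(child)
        sample_id = f"{arm.name}_{replicate}_s{k + 1:02d}"
        timepoint = 1 if k % 2 == 0 else 2
        abund = evolve_population(
            clones, arm.name, arm.n_passages, design.population_size, rng
        )
        smp_reads, aln = simulate_sample(
            clones,
            abund,
            design.reads_per_sample,
            genome,
            rng,
            sample_id=sample_id,
            offset_spread=design.offset_spread,
            read_length=design.read_length,
            emit_reads=emit_reads,
        )
        sample_rows.append(
            {
                "sample_id": sample_id,
                "treatment": arm.name,
                "biological_replicate": replicate,
                "timepoint_months": timepoint,
            }
        )
        aln_frames.append(aln)
        if emit_reads:
            reads[sample_id] = smp_reads
        abund_cols[sample_id] = abund

    samples = pd.DataFrame(sample_rows)
    alignments = (
        pd.concat(aln_frames, ignore_index=True)
        if aln_frames
        else pd.DataFrame(
            columns=["read_id", "sample_id", "chromosome", "position", "orientation", "mapq"]
        )
    )
    truth_ab = pd.DataFrame(abund_cols, index=clones.clones["clone_id"])
    sums = truth_ab.sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-9), "per-sample abundances must sum to 1"
    return ScreenSimulation(
        samples=samples,
        alignments=alignments,
        reads=reads,
        truth_directions=truth_directions(clones),
        truth_abundances=truth_ab,
        clones=clones,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# Single-cell expression
# ---------------------------------------------------------------------------

def simulate_scrna(
    gene_names: Sequence[str],
    n_parental: int,
    n_resistant: int,
    effect_spec: Mapping[str, tuple[float, float]],
    rng_seed: int,
    *,
    library_median: float = 2_000.0,
    library_sigma: float = 0.4,
    nb_dispersion: float = 2.0,
    mean_rate: float = 1e-3,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Genes × cells count matrix with planted positive-cell probabilities.

    ``effect_spec[gene] = (p_parental, p_resistant)``: the probability that a
    cell of each population expresses the gene at all; unlisted genes default
    to (0.5, 0.5). Expressed counts are 1 + NegBin with mean scaled by a
    log-normal per-cell library factor, so a positive cell always clears any
    CPM threshold ≤ its library's resolution.

    Returns (counts, labels, truth) where truth holds the two planted
    probabilities per gene.
    """
    if n_parental < 1 or n_resistant < 1:
        raise ValueError("both populations must contain at least one cell")
    for gene, (p_par, p_res) in effect_spec.items():
        if not (0 <= p_par <= 1 and 0 <= p_res <= 1):
            raise ValueError(f"probabilities for {gene} outside [0, 1]")
    rng = np.random.default_rng(rng_seed)
    genes = list(gene_names)
    n_cells = n_parental + n_resistant
    labels = pd.Series(
        ["parental"] * n_parental + ["resistant"] * n_resistant,
        index=[f"cell{i:05d}" for i in range(n_cells)],
        name="population",
    )
    lib = library_median * np.exp(rng.normal(0.0, library_sigma, size=n_cells))

    counts = np.zeros((len(genes), n_cells), dtype=np.int64)
    truth_rows = []
    for gi, gene in enumerate(genes):
        p_par, p_res = effect_spec.get(gene, (0.5, 0.5))
        p = np.where(np.arange(n_cells) < n_parental, p_par, p_res)
        expressed = rng.random(n_cells) < p
        mu = lib * mean_rate
        # NB via gamma-Poisson mixture, shifted by 1 (zero-truncated proxy)
        lam = rng.gamma(nb_dispersion, mu / nb_dispersion)
        extra = rng.poisson(lam)
        counts[gi, expressed] = 1 + extra[expressed]
        truth_rows.append({"gene": gene, "p_parental": p_par, "p_resistant": p_res})

    matrix = pd.DataFrame(counts, index=genes, columns=labels.index)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qualities]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_sam(
    alignments: pd.DataFrame,
    genome: GenomeModel,
    path: str | Path,
    *,
    read_length: int = 150,
    sort: bool = True,
) -> None:
    """Write alignment records as a headered SAM file (unmapped-free,
    placeholder 100%-match CIGAR; sequence content is not preserved)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
        "SQ": [
            {"SN": name, "LN": int(length)} for name, length in genome.chromosomes.items()
        ],
    }
    tid = {name: i for i, name in enumerate(genome.chromosomes)}
    df = alignments
    if sort:
        df = df.sort_values(["chromosome", "position"], kind="mergesort")
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in df.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.reference_id = tid[row.chromosome]
            a.reference_start = int(row.position)
            a.mapping_quality = int(row.mapq)
            a.flag = 16 if row.orientation == "-" else 0
            a.cigarstring = f"{read_length}M"
            a.query_sequence = None
            out.write(a)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into the gene-annotation frame used by GenomeModel."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((name, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["name", "chromosome", "start", "end", "strand"])
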