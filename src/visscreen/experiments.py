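"""Reference experiments: planted-truth recovery at study scale.

These functions run the whole pipeline on synthetic screens whose ground
truth is known and report recovery rates, so a change anywhere in the
stack shows up as a drop in sensitivity or a rise in false positives.
They are used by the test suite and by ``scripts/acceptance.py``.

Study-scale defaults mirror the discovery screen: 19 untreated controls,
15 fulvestrant and 7 ribociclib samples split over two biological
replicates; 300 uniquely integrated clones of which 12 carry a fulvestrant
fitness advantage and 6 a ribociclib advantage (per-passage weight 1.6
over 8 passages, population 2x10^4 cells), 5x10^4 junction reads per
sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .pipeline import screen_from_frames
from .scrna import validate_genes
from .synthetic import (
    ScreenDesign,
    TreatmentArm,
    make_genome,
    plant_integrations,
    simulate_screen,
    simulate_scrna,
)

__all__ = ["planted_screen_recovery", "scrna_recovery"]


def discovery_arms_design(
    reads_per_sample: int = 50_000,
    population_size: int = 20_000,
    n_passages: int = 8,
) -> ScreenDesign:
    """Controls + the two discovery arms only (verification arms excluded)."""
    return ScreenDesign(
        treatments=[
            TreatmentArm("NC", {"pLN1": 10, "pLN2": 9}, n_passages),
            TreatmentArm("fulvestrant", {"pLN1": 8, "pLN2": 7}, n_passages),
            TreatmentArm("ribociclib", {"pLN1": 4, "pLN2": 3}, n_passages),
        ],
        reads_per_sample=reads_per_sample,
        population_size=population_size,
    )


def planted_screen_recovery(
    seed: int,
    *,
    n_clones: int = 300,
    n_fulv: int = 12,
    n_ribo: int = 6,
    fitness: float = 1.6,
    reads_per_sample: int = 50_000,
    population_size: int = 20_000,
    n_passages: int = 8,
    config: PipelineConfig | None = None,
) -> dict:
    """Simulate the discovery screen and score candidate recovery.

    Returns sensitivity (fraction of planted resistant clones whose locus
    supports a candidate gene), the neutral false-positive rate, and stage
    counts.  Clones are planted with >= 5 kb spacing so each called locus
    identifies one clone.
    """
    config = config or PipelineConfig()
    genome = make_genome(5, 40_000_000, 400, seed)
    fitness_spec = {
        "fulvestrant": [(i, fitness) for i in range(n_fulv)],
        "ribociclib": [(i, fitness) for i in range(n_fulv, n_fulv + n_ribo)],
    }
    clones = plant_integrations(
        genome, n_clones, fitness_spec, seed + 1, min_spacing=5_000
    )
    design = discovery_arms_design(reads_per_sample, population_size, n_passages)
    sim = simulate_screen(design, clones, genome, seed + 2, emit_reads=False)
    out = screen_from_frames(sim.alignments, sim.samples, genome, config)

    # map candidate-supporting loci back to clones by proximity
    supporting: set[str] = set()
    for loci_str in out.candidates.get("supporting_loci", pd.Series(dtype=str)):
        supporting.update(loci_str.split(","))
    spread = design.offset_spread
    clone_hit = {}
    loci = out.matrix_raw.loci
    for _, clone in clones.clones.iterrows():
        near = loci[
            (loci["chromosome"] == clone["chromosome"])
            & ((loci["representative_position"] - clone["position"]).abs() <= 2 * spread)
        ]
        clone_hit[clone["clone_id"]] = bool(set(near.index) & supporting)

    planted_ids = list(clones.clones["clone_id"].iloc[: n_fulv + n_ribo])
    neutral_ids = list(clones.clones["clone_id"].iloc[n_fulv + n_ribo:])
    sensitivity = float(np.mean([clone_hit[c] for c in planted_ids]))
    neutral_rate = float(np.mean([clone_hit[c] for c in neutral_ids]))
    return {
        "sensitivity": sensitivity,
        "neutral_candidate_rate": neutral_rate,
        "n_planted": len(planted_ids),
        "n_neutral": len(neutral_ids),
        "n_candidates": len(out.candidates),
        "stage_counts": out.stage_counts,
        "output": out,
        "simulation": sim,
    }


def scrna_recovery(
    seed: int,
    *,
    n_seeds: int = 20,
    n_parental: int = 2_000,
    n_resistant: int = 2_000,
    n_planted: int = 6,
    n_neutral: int = 15,
    min_shift: float = 0.15,
) -> dict:
    """Planted fraction-shift recovery in the single-cell validation.

    Over ``n_seeds`` independent matrices: every planted gene (fraction
    shift >= ``min_shift``) must clear Bonferroni at 0.05; neutral genes
    are scored by how often they stay above raw p = 0.05.
    """
    rng = np.random.default_rng(seed)
    planted = [f"hit{i}" for i in range(n_planted)]
    neutral = [f"null{i}" for i in range(n_neutral)]
    planted_ok = []
    neutral_nonsig = []
    for s in range(n_seeds):
        spec = {}
        for g in planted:
            base = rng.uniform(0.15, 0.6)
            spec[g] = (base, base + rng.uniform(min_shift, 0.3))
        for g in neutral:
            base = rng.uniform(0.2, 0.8)
            spec[g] = (base, base)
        counts, labels, _ = simulate_scrna(
            planted + neutral, n_parental, n_resistant, spec,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = validate_genes(counts, labels)
        planted_ok.append(bool((res.loc[planted, "p_bonferroni"] < 0.05).all()))
        neutral_nonsig.extend((res.loc[neutral, "p"] >= 0.05).tolist())
    return {
        "planted_all_significant_rate": float(np.mean(planted_ok)),
        "neutral_nonsignificant_rate": float(np.mean(neutral_nonsig)),
        "n_seeds": n_seeds,
    }
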