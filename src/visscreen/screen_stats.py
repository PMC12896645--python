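"""Filtering cascade and enrichment statistics of the resistance screen.

The cascade removes implausible integration loci before any testing:

1. ``filter_singletons`` — loci detected in exactly one sample overall are
   treated as random integration events;
2. ``filter_replicate_concordance`` — loci must be seen in both biological
   replicates (pLN1 and pLN2) under any condition;
3. ``filter_treatment_concordance`` — loci must be seen in both replicates
   within at least one (non-control) treatment.

Replicate concordance is the screen's surrogate control for multiple
testing: no FDR correction is applied here by design.

Two complementary tests then compare each locus between a treatment group
and the untreated controls (timepoints pooled):

* detection frequency — a two-sided Fisher exact test on the 2×2 table
  (detected / not-detected) × (treated / control), computed by exact
  rational enumeration of the hypergeometric distribution under the
  probability-mass rule;
* read-depth coverage — a two-sample Student t-test on per-sample RPM,
  with undetected samples contributing RPM 0 (configurable).

Each result carries two flags per test: ``significant`` (p < 0.05) and
``exploratory`` (p < 0.10).  Candidate genes are loci reaching at least the
exploratory tier in either test for a discovery treatment, with the
enriched direction required by default; verification categorizes each
candidate by how many of the held-out treatment groups also detect it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig
from .vis_calling import LocusSampleMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_singletons",
    "filter_replicate_concordance",
    "filter_treatment_concordance",
    "fisher_exact_2x2",
    "student_t_test",
    "frequency_tests",
    "coverage_tests",
    "screen_tests",
    "select_candidates",
    "verify_candidates",
    "summarize_partitions",
    "PartitionSummary",
    "volcano_table",
    "scatter_table",
]

REPLICATES = ("pLN1", "pLN2")


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def filter_singletons(matrix: LocusSampleMatrix) -> LocusSampleMatrix:
    """Remove loci detected in exactly one sample overall."""
    n_det = matrix.detected.sum(axis=1)
    keep = matrix.detected.index[n_det != 1]
    removed = len(matrix.detected) - len(keep)
    logger.info("singleton filter removed %d loci", removed)
    out = matrix.subset(keep)
    out.meta["singletons_removed"] = removed
    return out


def _replicate_detection(matrix: LocusSampleMatrix, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Per-locus detection (bool) per biological replicate over given samples."""
    reps = matrix.samples.loc[list(sample_ids), "biological_replicate"]
    if reps.isna().any():
        raise ValueError("samples missing biological replicate labels")
    det = matrix.detected[list(sample_ids)]
    return det.T.groupby(reps).any().T


def filter_replicate_concordance(matrix: LocusSampleMatrix) -> LocusSampleMatrix:
    """Keep loci detected in >= 1 sample of each biological replicate
    (any treatment or control)."""
    missing = [r for r in REPLICATES if r not in set(matrix.samples["biological_replicate"])]
    if missing:
        raise ValueError(f"no samples for biological replicate(s) {missing}")
    by_rep = _replicate_detection(matrix, matrix.samples.index)
    keep = matrix.detected.index[by_rep.reindex(columns=list(REPLICATES)).all(axis=1)]
    removed = len(matrix.detected) - len(keep)
    logger.info("replicate-concordance filter removed %d loci", removed)
    out = matrix.subset(keep)
    out.meta["replicate_discordant_removed"] = removed
    return out


def filter_treatment_concordance(
    matrix: LocusSampleMatrix, control_label: str = "NC"
) -> LocusSampleMatrix:
    """Keep loci detected in both replicates within at least one single
    non-control treatment; control-only concordance does not qualify."""
    keep_mask = pd.Series(False, index=matrix.detected.index)
    for treatment, grp in matrix.samples.groupby("treatment"):
        if treatment == control_label:
            continue
        by_rep = _replicate_detection(matrix, grp.index)
        if not set(REPLICATES) <= set(by_rep.columns):
            continue  # unbalanced arm cannot establish concordance
        keep_mask |= by_rep[list(REPLICATES)].all(axis=1)
    keep = matrix.detected.index[keep_mask]
    removed = len(matrix.detected) - len(keep)
    logger.info("treatment-concordance filter removed %d loci", removed)
    out = matrix.subset(keep)
    out.meta["treatment_discordant_removed"] = removed
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Exact rational enumeration: with margins fixed, sums the hypergeometric
    probabilities of every table whose probability does not exceed that of
    the observed table.  Any zero row or column margin gives p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(min(total, Fraction(1)))


def student_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    welch: bool = False,
) -> tuple[float, float, bool]:
    """Two-sample t-test (pooled variance by default).

    Returns (t, two-sided p, computable).  Groups smaller than 2 are not
    computable; zero pooled variance gives t = 0, p = 1 for equal means and
    p = 0 (degenerate, logged) otherwise.
    """
    x = np.asarray(values_a, float)
    y = np.asarray(values_b, float)
    if len(x) < 2 or len(y) < 2:
        return np.nan, np.nan, False
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if welch:
        se2 = vx / len(x) + vy / len(y)
        if se2 == 0:
            return _degenerate_t(mx, my)
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (
            (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
        )
    else:
        df = len(x) + len(y) - 2
        sp2 = ((len(x) - 1) * vx + (len(y) - 1) * vy) / df
        if sp2 == 0:
            return _degenerate_t(mx, my)
        t = (mx - my) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), True


def _degenerate_t(mx: float, my: float) -> tuple[float, float, bool]:
    if mx == my:
        return 0.0, 1.0, True
    logger.warning("zero-variance groups with unequal means: degenerate t-test")
    return np.inf if mx > my else -np.inf, 0.0, True


def _flag(p: float, config: ScreenConfig) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < config.p_significant:
        return "significant"
    if p < config.p_exploratory:
        return "exploratory"
    return "ns"


def frequency_tests(
    matrix: LocusSampleMatrix,
    treatment: str,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Detection-frequency comparison of one treatment against controls.

    Per locus: Fisher exact test on (detected, undetected) × (treated,
    control), with all timepoints pooled.  Direction comes from the
    detection proportions; loci seen only in one group are flagged
    exclusive.
    """
    config = config or ScreenConfig()
    treated = matrix.samples_for(treatment)
    controls = matrix.samples_for(config.control_label)
    if not treated or not controls:
        raise ValueError(f"need both {treatment} and {config.control_label} samples")
    n_t, n_c = len(treated), len(controls)
    rows = []
    for locus_id in matrix.detected.index:
        a = int(matrix.detected.loc[locus_id, treated].sum())
        b = int(matrix.detected.loc[locus_id, controls].sum())
        p = fisher_exact_2x2(a, n_t - a, b, n_c - b)
        if a > 0 and b == 0:
            direction = "exclusive_treated"
        elif b > 0 and a == 0:
            direction = "exclusive_control"
        elif a / n_t > b / n_c:
            direction = "enriched"
        elif a / n_t < b / n_c:
            direction = "depleted"
        else:
            direction = "none"
        rows.append(
            {
                "locus_id": locus_id,
                "treatment": treatment,
                "a": a,
                "n_t": n_t,
                "b": b,
                "n_c": n_c,
                "fisher_p": p,
                "freq_direction": direction,
                "freq_flag": _flag(p, config),
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def coverage_tests(
    matrix: LocusSampleMatrix,
    treatment: str,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Read-depth (RPM) comparison of one treatment against controls.

    Student t-test per locus on per-sample RPM; undetected samples
    contribute RPM 0 unless ``config.coverage_include_undetected`` is off,
    in which case only detected samples enter (groups below 2 are flagged
    not-computable).
    """
    config = config or ScreenConfig()
    treated = matrix.samples_for(treatment)
    controls = matrix.samples_for(config.control_label)
    if not treated or not controls:
        raise ValueError(f"need both {treatment} and {config.control_label} samples")
    rows = []
    for locus_id in matrix.rpm.index:
        rpm_t = matrix.rpm.loc[locus_id, treated].to_numpy(float)
        rpm_c = matrix.rpm.loc[locus_id, controls].to_numpy(float)
        if not config.coverage_include_undetected:
            det_t = matrix.detected.loc[locus_id, treated].to_numpy(bool)
            det_c = matrix.detected.loc[locus_id, controls].to_numpy(bool)
            rpm_t, rpm_c = rpm_t[det_t], rpm_c[det_c]
        t, p, ok = student_t_test(rpm_t, rpm_c, welch=config.welch)
        mean_t = float(rpm_t.mean()) if len(rpm_t) else 0.0
        mean_c = float(rpm_c.mean()) if len(rpm_c) else 0.0
        if mean_t > mean_c:
            direction = "enriched"
        elif mean_t < mean_c:
            direction = "depleted"
        else:
            direction = "none"
        rows.append(
            {
                "locus_id": locus_id,
                "treatment": treatment,
                "mean_rpm_treated": mean_t,
                "mean_rpm_control": mean_c,
                "t_stat": t,
                "t_p": p,
                "cov_direction": direction,
                "cov_flag": _flag(p, config) if ok else "ns",
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


def screen_tests(
    matrix: LocusSampleMatrix,
    treatment: str,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Combined per-locus ScreenResult table (frequency + coverage fields)
    for one treatment, with an overall direction: the frequency direction
    where informative, else the coverage direction."""
    freq = frequency_tests(matrix, treatment, config)
    cov = coverage_tests(matrix, treatment, config).drop(columns=["treatment"])
    out = freq.join(cov)
    out["direction"] = np.where(
        out["freq_direction"] != "none", out["freq_direction"], out["cov_direction"]
    )
    return out


# ---------------------------------------------------------------------------
# Candidate selection and verification
# ---------------------------------------------------------------------------

_ENRICHED = {"enriched", "exclusive_treated"}


def _locus_qualifies(row: pd.Series, config: ScreenConfig) -> bool:
    freq_hit = row["freq_flag"] in ("significant", "exploratory")
    cov_hit = row["cov_flag"] in ("significant", "exploratory")
    if config.require_enriched:
        freq_hit = freq_hit and row["freq_direction"] in _ENRICHED
        cov_hit = cov_hit and row["cov_direction"] in _ENRICHED
    return freq_hit or cov_hit


def select_candidates(
    results: Mapping[str, pd.DataFrame],
    locus_gene_map: Mapping[str, str | None],
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Collapse qualifying loci into candidate genes.

    A locus qualifies for a treatment when either test reaches at least the
    exploratory tier (and, by default, in the enriched direction).
    Qualifying loci are grouped by nearest gene; unannotated loci keep their
    locus id as gene surrogate.  Returns one row per gene with supporting
    loci and per-treatment evidence.
    """
    config = config or ScreenConfig()
    genes: dict[str, dict] = {}
    for treatment, table in results.items():
        for locus_id, row in table.iterrows():
            if not _locus_qualifies(row, config):
                continue
            gene = locus_gene_map.get(locus_id) or locus_id
            entry = genes.setdefault(gene, {"loci": set(), "evidence": {}})
            entry["loci"].add(locus_id)
            ev = entry["evidence"].setdefault(treatment, set())
            if row["freq_flag"] != "ns":
                ev.add(f"freq_{row['freq_flag']}")
            if row["cov_flag"] != "ns":
                ev.add(f"cov_{row['cov_flag']}")
    rows = []
    for gene in sorted(genes):
        entry = genes[gene]
        treatments = sorted(entry["evidence"])
        rows.append(
            {
                "gene": gene,
                "supporting_loci": ",".join(sorted(entry["loci"])),
                "treatments": ",".join(treatments),
                "n_treatments": len(treatments),
                "evidence": ";".join(
                    f"{t}:{'|'.join(sorted(entry['evidence'][t]))}" for t in treatments
                ),
            }
        )
    cols = ["gene", "supporting_loci", "treatments", "n_treatments", "evidence"]
    return pd.DataFrame(rows, columns=cols)


def verify_candidates(
    candidates: pd.DataFrame,
    matrix: LocusSampleMatrix,
    verification_treatments: Sequence[str],
) -> pd.DataFrame:
    """Categorize candidates by presence in the held-out treatment groups.

    A gene is present in a verification group when any supporting locus is
    detected in >= 1 sample of that group.  Detection in all groups →
    ``all_groups``; in some but not all → ``one_or_two_groups``; in none →
    ``none``.
    """
    candidates = candidates.copy()
    groups = {t: matrix.samples_for(t) for t in verification_treatments}
    missing = [t for t, s in groups.items() if not s]
    if missing:
        raise ValueError(f"verification treatments absent from matrix: {missing}")
    n_groups_detected = []
    detected_in = []
    for _, row in candidates.iterrows():
        loci = [l for l in row["supporting_loci"].split(",") if l in matrix.detected.index]
        hits = []
        for t, sample_ids in groups.items():
            if loci and matrix.detected.loc[loci, sample_ids].to_numpy().any():
                hits.append(t)
        n_groups_detected.append(len(hits))
        detected_in.append(",".join(hits))
    candidates["verification_detected_in"] = detected_in
    candidates["n_verification_groups"] = n_groups_detected
    n_total = len(verification_treatments)
    candidates["verification_category"] = [
        "all_groups" if n == n_total else ("none" if n == 0 else "one_or_two_groups")
        for n in n_groups_detected
    ]
    return candidates


# ---------------------------------------------------------------------------
# Partition bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PartitionSummary:
    """Stage-by-stage bookkeeping of the cascade, with identities asserted
    at construction.  ``table`` has one row per derived quantity."""

    table: pd.DataFrame
    values: dict[str, int] = field(default_factory=dict)


def summarize_partitions(stages: Mapping[str, Mapping]) -> PartitionSummary:
    """Compute and check cascade totals.

    Each stage is a mapping with any of:

    * ``total`` + ``exclusions`` (name → count): retained = total − Σ exclusions;
    * ``categories`` (name → count): total = Σ categories, checked against an
      optional ``expected_total``;
    * ``retained`` to cross-check a computed retention.

    Raises ``ValueError`` naming the failing identity when the numbers do
    not add up.
    """
    rows = []
    values: dict[str, int] = {}
    for stage, spec in stages.items():
        for counts_key in ("exclusions", "categories"):
            counts = spec.get(counts_key, {})
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"{stage}: negative count in {counts_key}")
        if "exclusions" in spec:
            if "total" not in spec:
                raise ValueError(f"{stage}: exclusions given without total")
            retained = spec["total"] - sum(spec["exclusions"].values())
            if retained < 0:
                raise ValueError(
                    f"{stage}: exclusions exceed total "
                    f"({spec['total']} - {sum(spec['exclusions'].values())})"
                )
            if "retained" in spec and spec["retained"] != retained:
                raise ValueError(
                    f"{stage}: retained identity fails: "
                    f"{spec['total']} - Σ exclusions = {retained} != {spec['retained']}"
                )
            values[f"{stage}_retained"] = retained
            rows.append((stage, "retained", retained))
        if "categories" in spec:
            total = sum(spec["categories"].values())
            if "expected_total" in spec and spec["expected_total"] != total:
                raise ValueError(
                    f"{stage}: category sum {total} != expected total {spec['expected_total']}"
                )
            values[f"{stage}_total"] = total
            rows.append((stage, "total", total))
            for name, count in spec["categories"].items():
                rows.append((stage, name, count))
    table = pd.DataFrame(rows, columns=["stage", "quantity", "count"])
    return PartitionSummary(table=table, values=values)


# ---------------------------------------------------------------------------
# Plot source tables (data for scatter / volcano views)
# ---------------------------------------------------------------------------

def scatter_table(freq: pd.DataFrame) -> pd.DataFrame:
    """Detection-fraction scatter source: control vs treated fractions."""
    out = freq.copy()
    out["frac_treated"] = out["a"] / out["n_t"]
    out["frac_control"] = out["b"] / out["n_c"]
    return out[["treatment", "frac_control", "frac_treated", "fisher_p", "freq_flag"]]


def volcano_table(cov: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Volcano source: log2 fold change of mean RPM (pseudocount for zeros)
    against −log10 p of the coverage t-test."""
    out = cov.copy()
    out["log2_fc"] = np.log2(
        (out["mean_rpm_treated"] + pseudocount) / (out["mean_rpm_control"] + pseudocount)
    )
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["t_p"])
    return out[["treatment", "log2_fc", "neg_log10_p", "t_p", "cov_flag"]]
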