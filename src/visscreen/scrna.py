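"""Single-cell fraction-positive validation of candidate genes.

For each candidate gene, the fraction of cells expressing it at >= 1 CPM
(counts per million, per cell) is compared between the parental and the
drug-resistant population with a Pearson chi-squared test on the 2×2
positive/negative × population table (no continuity correction by
default), followed by Bonferroni correction over the genes actually
tested.  Each gene's direction of change is then checked for concordance
with the screen's detection-frequency direction for the designated
treatment.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "cpm_normalize",
    "positive_fractions",
    "chi_squared_2x2",
    "bonferroni_adjust",
    "validate_genes",
    "concordance",
    "read_counts_any",
    "write_mtx",
]

POPULATIONS = ("parental", "resistant")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per cell: cpm(g, c) = 1e6 * count / cell total.

    Cells with zero total counts are excluded with a warning.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("excluding %d zero-count cells", len(zero))
        counts = counts.drop(columns=zero)
        totals = totals.drop(zero)
    return counts * 1e6 / totals


def positive_fractions(
    cpm: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene fraction of CPM-positive cells in each population.

    A cell is positive for a gene iff its CPM is >= ``threshold`` (closed
    boundary).  Returns per gene: n_pos and fraction for both populations.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    labels = labels.reindex(cpm.columns)
    if labels.isna().any():
        raise ValueError("every cell must carry a population label")
    out = {}
    for pop in POPULATIONS:
        cells = labels.index[labels == pop]
        if len(cells) == 0:
            raise ValueError(f"empty population: {pop}")
        pos = (cpm[cells] >= threshold).sum(axis=1)
        out[f"n_pos_{pop}"] = pos.astype(int)
        out[f"n_{pop}"] = len(cells)
        out[f"fraction_{pop}"] = pos / len(cells)
    return pd.DataFrame(out, index=cpm.index)


def chi_squared_2x2(
    pos_a: int, neg_a: int, pos_b: int, neg_b: int, *, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test for a 2×2 table, 1 df.

    Equals the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); a zero margin
    returns (0, 1).  ``yates`` applies the continuity correction.
    """
    a, b, c, d = pos_a, neg_a, pos_b, neg_b
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    stat = n * diff**2 / np.prod([float(m) for m in margins])
    return float(stat), float(stats.chi2.sf(stat, df=1))


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p), order-preserving.

    ``m`` defaults to the number of p-values; it must be >= 1.
    """
    p = np.asarray(p_values, float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)


def validate_genes(
    counts: pd.DataFrame,
    labels: pd.Series,
    genes: Sequence[str] | None = None,
    *,
    threshold: float = 1.0,
    yates: bool = False,
    alias_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full validation of ``genes`` (default: all genes in the matrix).

    Applies CPM normalization, positivity calling, the chi-squared test per
    gene, and Bonferroni correction with m = number of genes tested.  Gene
    matching is case-sensitive after applying ``alias_map`` (candidate name
    → matrix name); genes absent from the matrix are reported and skipped.
    """
    alias_map = dict(alias_map or {})
    if genes is None:
        tested = list(counts.index)
    else:
        tested, missing = [], []
        for g in genes:
            name = alias_map.get(g, g)
            (tested if name in counts.index else missing).append(name)
        if missing:
            logger.warning("genes absent from expression matrix: %s", missing)
    if not tested:
        raise ValueError("no candidate genes overlap the expression matrix")
    cpm = cpm_normalize(counts)
    frac = positive_fractions(cpm, labels, threshold).loc[tested]
    stats_rows = []
    for gene, row in frac.iterrows():
        stat, p = chi_squared_2x2(
            int(row["n_pos_parental"]),
            int(row["n_parental"] - row["n_pos_parental"]),
            int(row["n_pos_resistant"]),
            int(row["n_resistant"] - row["n_pos_resistant"]),
            yates=yates,
        )
        if row["fraction_resistant"] > row["fraction_parental"]:
            direction = "up_in_resistant"
        elif row["fraction_resistant"] < row["fraction_parental"]:
            direction = "down_in_resistant"
        else:
            direction = "none"
        stats_rows.append((gene, stat, p, direction))
    res = pd.DataFrame(
        stats_rows, columns=["gene", "chi2_stat", "p", "direction"]
    ).set_index("gene")
    res["p_bonferroni"] = bonferroni_adjust(res["p"].to_numpy(), m=len(res))
    return frac.join(res)


def concordance(
    validation: pd.DataFrame,
    screen_directions: Mapping[str, str],
) -> pd.DataFrame:
    """Label each validated gene against the screen's direction.

    ``screen_directions`` maps gene → enriched/depleted (detection in the
    designated treatment vs controls).  ``consistent`` when the RNA change
    (resistant vs parental fraction) points the same way, ``opposite`` when
    reversed, ``not_in_screen`` when the gene has no screen direction.
    """
    validation = validation.copy()
    rna_up = {"up_in_resistant": "enriched", "down_in_resistant": "depleted"}
    labels = []
    for gene, row in validation.iterrows():
        screen_dir = screen_directions.get(gene)
        if screen_dir not in ("enriched", "depleted", "exclusive_treated", "exclusive_control"):
            labels.append("not_in_screen")
            continue
        screen_dir = {"exclusive_treated": "enriched", "exclusive_control": "depleted"}.get(
            screen_dir, screen_dir
        )
        rna_dir = rna_up.get(row["direction"])
        if rna_dir is None:
            labels.append("opposite")  # no RNA change cannot confirm
        else:
            labels.append("consistent" if rna_dir == screen_dir else "opposite")
    validation["concordance"] = labels
    return validation


# ---------------------------------------------------------------------------
# I/O: Matrix Market or dense TSV
# ---------------------------------------------------------------------------

def read_counts_any(
    path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a genes × cells count matrix from .mtx (+ genes/barcodes TSVs)
    or from a dense TSV with gene rows and cell columns."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(path)).toarray()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
        return pd.DataFrame(mat, index=genes, columns=cells).astype(int)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(
        prefix.parent / f"{prefix.name}.genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(counts.columns).to_csv(
        prefix.parent / f"{prefix.name}.barcodes.tsv", sep="\t", index=False, header=False
    )
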