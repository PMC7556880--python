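"""Joining differential expression with peak classes and marker gene sets.

DE tables are flat frames of (gene_id, log2fc, p_adj). Filtering applies
the conventional linear-scale cut: |fold change| > 1.5 (i.e. |log2fc| >
log2 1.5) and adjusted p < 0.05, both strict. Set overlap is tested with
the exact upper-tail hypergeometric; direction concordance is reported as
(up_up, down_down, discordant) fractions; and DE genes are counted per
peak class with gene-level deduplication (a gene near several peaks of one
class counts once for that class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals_io import ValidationError

DE_TABLE_COLUMNS = ["gene_id", "log2fc", "p_adj"]


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = set(DE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError("gene_id values must be unique in a DE table")
    if ((df["p_adj"] < 0) | (df["p_adj"] > 1)).any():
        raise ValidationError("p_adj must lie in [0, 1]")
    return df


def de_filter(table: pd.DataFrame, fc_thresh: float = 1.5, p_thresh: float = 0.05
              ) -> dict[str, int]:
    """Genes passing |fold change| > fc_thresh and p_adj < p_thresh (strict).

    Returns gene_id -> sign (+1 up, -1 down).
    """
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ValidationError("thresholds must be positive")
    lfc_cut = np.log2(fc_thresh)
    mask = (table["log2fc"].abs() > lfc_cut) & (table["p_adj"] < p_thresh)
    sub = table.loc[mask]
    return {g: (1 if l > 0 else -1) for g, l in zip(sub["gene_id"], sub["log2fc"])}


@dataclass
class OverlapStat:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_hyper: float
    jaccard: float


def hypergeometric_overlap(a: set, b: set, universe: set) -> OverlapStat:
    """Exact upper-tail hypergeometric test of |a & b| against chance."""
    a, b, universe = set(a), set(b), set(universe)
    if not a <= universe or not b <= universe:
        raise ValidationError("a and b must be subsets of the universe")
    n_overlap = len(a & b)
    n_union = len(a | b)
    p = float(stats.hypergeom.sf(n_overlap - 1, len(universe), len(a), len(b)))
    return OverlapStat(
        n_universe=len(universe),
        n_a=len(a),
        n_b=len(b),
        n_overlap=n_overlap,
        p_hyper=p,
        jaccard=n_overlap / n_union if n_union else 0.0,
    )


def direction_concordance(a: pd.DataFrame, b: pd.DataFrame, genes: set
                          ) -> dict[str, float]:
    """Sign agreement of log2fc for a shared gene set across two DE tables."""
    sign_a = dict(zip(a["gene_id"], np.sign(a["log2fc"])))
    sign_b = dict(zip(b["gene_id"], np.sign(b["log2fc"])))
    genes = sorted(genes)
    if not genes:
        raise ValidationError("empty shared gene set")
    for g in genes:
        if g not in sign_a or g not in sign_b:
            raise ValidationError(f"gene {g!r} missing from a DE table")
    up_up = sum(1 for g in genes if sign_a[g] > 0 and sign_b[g] > 0)
    down_down = sum(1 for g in genes if sign_a[g] < 0 and sign_b[g] < 0)
    n = len(genes)
    return {
        "up_up": up_up / n,
        "down_down": down_down / n,
        "discordant": (n - up_up - down_down) / n,
    }


def de_counts_by_peak_class(de_genes: set, peak_to_genes: dict[str, set],
                            peak_classes: dict[str, str]
                            ) -> tuple[dict[str, int], dict[str, set]]:
    """DE genes associated with each peak class, deduplicated at gene level.

    ``peak_to_genes`` maps peak id -> nearby gene ids (e.g. nearest up- and
    downstream genes); ``peak_classes`` maps peak id -> class label. A DE
    gene near multiple peaks of one class counts once for that class but
    may count in several classes.
    """
    gene_lists: dict[str, set] = {}
    for peak_id, genes in peak_to_genes.items():
        if peak_id not in peak_classes:
            continue
        cls = peak_classes[peak_id]
        gene_lists.setdefault(cls, set()).update(g for g in genes if g in de_genes)
    counts = {cls: len(genes) for cls, genes in gene_lists.items()}
    return counts, gene_lists
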