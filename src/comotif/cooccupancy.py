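"""Permutation-based enrichment tests for peak co-occupancy and gene proximity.

Both tests share one result schema (:class:`EnrichResult`). The co-occupancy
test counts how many intervals of set ``a`` touch the union of set ``b``
(>= 1 bp) and compares against a null in which every a-interval is
relocated uniformly at random on its own chromosome, preserving its length.
The gene-set test counts the intersection of a query gene set with the
genes proximal to a peak class and compares against random same-size gene
sets drawn from the universe without replacement (whose intersection count
is exactly hypergeometric, which is how the null is sampled).

Two p-values are reported: the empirical (1 + #null >= obs)/(1 + n_perm),
bounded below by the Monte-Carlo floor, and the upper normal-tail p at the
null z-score, which can express extreme significance beyond the floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .intervals_io import ChromTable, PeakSet, ValidationError, merge_spans


@dataclass
class EnrichResult:
    observed: int
    null_mean: float
    null_sd: float
    fold: float
    z: float
    p_empirical: float
    p_normal: float
    n_perm: int
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _summarize(observed: int, null_counts: np.ndarray, n_perm: int, seed: int
               ) -> EnrichResult:
    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=0))
    if null_mean > 0:
        fold = observed / null_mean
    else:
        fold = 0.0 if observed == 0 else float("inf")
    z = (observed - null_mean) / null_sd if null_sd > 0 else (
        0.0 if observed == null_mean else float("inf") * np.sign(observed - null_mean)
    )
    p_emp = (1 + int((null_counts >= observed).sum())) / (1 + n_perm)
    p_norm = float(stats.norm.sf(z)) if np.isfinite(z) else (0.0 if z > 0 else 1.0)
    return EnrichResult(
        observed=int(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        fold=float(fold),
        z=float(z),
        p_empirical=float(p_emp),
        p_normal=p_norm,
        n_perm=int(n_perm),
        seed=int(seed),
    )


def count_overlapping(starts: np.ndarray, ends: np.ndarray,
                      b_starts: np.ndarray, b_ends: np.ndarray) -> np.ndarray:
    """Boolean mask: does each [start, end) touch the disjoint sorted b-spans?"""
    if len(b_starts) == 0:
        return np.zeros(starts.shape, dtype=bool)
    idx = np.searchsorted(b_starts, ends, side="left")
    hit = idx > 0
    prev = np.maximum(idx - 1, 0)
    return hit & (b_ends[prev] > starts)


def permutation_overlap_test(a: PeakSet, b: PeakSet, chroms: ChromTable,
                             n_perm: int = 1000, seed: int = 0) -> EnrichResult:
    """RELI-style co-occupancy enrichment of a-peaks in b-peaks.

    Observed statistic: number of a-peaks overlapping the union of b by
    >= 1 bp. Null: each a-peak relocated uniformly on its own chromosome,
    length preserved, independently per permutation.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if len(a) == 0:
        raise ValidationError("peak set a is empty")
    for iv in a:
        if iv.chrom not in chroms:
            raise ValidationError(f"a-peak chromosome {iv.chrom!r} absent from ChromTable")
    rng = np.random.default_rng(seed)
    b_spans = merge_spans(b) if len(b) else {}

    observed = 0
    null_counts = np.zeros(n_perm, dtype=np.int64)
    for chrom, ivs in a.by_chrom().items():
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        lens = np.array([len(iv) for iv in ivs], dtype=np.int64)
        L = chroms[chrom]
        if chrom in b_spans:
            bs, be = b_spans[chrom]
        else:
            bs = be = np.empty(0, dtype=np.int64)
        observed += int(count_overlapping(starts, starts + lens, bs, be).sum())
        # relocated starts: uniform in [0, L - len] per peak, per permutation
        u = rng.random((n_perm, len(ivs)))
        null_starts = (u * (L - lens + 1)).astype(np.int64)
        if len(bs):
            hits = count_overlapping(
                null_starts.ravel(),
                (null_starts + lens).ravel(),
                bs,
                be,
            ).reshape(n_perm, len(ivs))
            null_counts += hits.sum(axis=1)
    return _summarize(observed, null_counts, n_perm, seed)


def geneset_proximity_enrichment(gene_set: set, proximal_genes: set, universe: set,
                                 n_perm: int = 1000, seed: int = 0) -> EnrichResult:
    """Enrichment of a gene set among genes proximal to a peak class.

    Observed statistic: |gene_set & proximal_genes|. Null: random gene sets
    of the same size drawn from the universe without replacement; the null
    intersection count is hypergeometric and is sampled as such.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    gene_set, proximal_genes, universe = set(gene_set), set(proximal_genes), set(universe)
    if not gene_set <= universe or not proximal_genes <= universe:
        raise ValidationError("gene_set and proximal_genes must be subsets of the universe")
    if len(gene_set) > len(universe):
        raise ValidationError("gene_set larger than universe")
    rng = np.random.default_rng(seed)
    observed = len(gene_set & proximal_genes)
    n_good = len(proximal_genes)
    n_bad = len(universe) - n_good
    null_counts = rng.hypergeometric(n_good, n_bad, len(gene_set), size=n_perm)
    return _summarize(observed, null_counts.astype(np.int64), n_perm, seed)
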