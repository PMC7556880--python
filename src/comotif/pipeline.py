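"""End-to-end orchestration: simulate inputs, run every stage, write outputs.

``write_inputs`` materializes a synthetic study (genome FASTA, chromosome
sizes, peak BEDs, gene annotation, DE tables, reporter wells, ground-truth
ledger) under an output directory; ``run_pipeline`` runs the full analysis
over those inputs and writes a deterministic ``results.json`` plus
per-stage tables. All randomness derives from ``SimConfig.seed``, so two
runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .cooccupancy import geneset_proximity_enrichment, permutation_overlap_test
from .expression_integration import (
    de_counts_by_peak_class,
    de_filter,
    direction_concordance,
    hypergeometric_overlap,
    read_de_table,
)
from .intervals_io import (
    ChromTable,
    GeneAnnot,
    PeakSet,
    SequenceStore,
    assign_nearest_genes,
    extract_sequences,
    intersect,
    read_bed,
    write_bed,
)
from .motifs import (
    CGBM_8MER,
    DGBM_8MER,
    bundled_pwm_path,
    classify_peakset,
    count_kmers,
    enumerate_canonical_kmers,
    kmer_peak_fraction,
    rank_kmer,
    read_pwm,
)
from .reporter_synergy import normalize_reporter, read_reporter_table, synergy_test
from .spacing_orientation import (
    composite_sites,
    config_enrichment_test,
    max_config_fraction,
    spacing_grid,
)

_TAG_MARKERS = 8


def _plant_peak_classes(cfg: sd.SimConfig, store: SequenceStore, peaks_a: PeakSet,
                        truth: pd.DataFrame, pwm) -> pd.DataFrame:
    """Write class-defining sequences into the genome at a-peak locations.

    Peaks planted to co-occur with factor B receive classes per
    ``class_fracs_overlap`` (dGBM peaks also get an E-box so the spacing
    stage has pairs to tabulate); A-only peaks receive the canonical 8-mer
    at the planned incidence and plain background otherwise.
    """
    rng = np.random.default_rng([int(cfg.seed), _TAG_MARKERS, 1])
    planted = dict(zip(truth["peak_id"], truth["planted_overlap"]))
    overlap_ids = [iv.name for iv in peaks_a if planted[iv.name]]
    only_ids = [iv.name for iv in peaks_a if not planted[iv.name]]
    by_name = {iv.name: iv for iv in peaks_a}

    n_ov = len(overlap_ids)
    n_c = int(round(cfg.class_fracs_overlap[0] * n_ov))
    n_d = int(round(cfg.class_fracs_overlap[1] * n_ov))
    labels = ["cGBM"] * n_c + ["dGBM"] * n_d + ["neither"] * (n_ov - n_c - n_d)
    rng.shuffle(labels)
    rows = []
    for pid, label in zip(overlap_ids, labels):
        iv = by_name[pid]
        seq = sd.plant_class_sequence(
            label, len(iv), cfg.gc, pwm, rng, with_ebox=(label == "dGBM")
        )
        store.set_slice(iv.chrom, iv.start, seq)
        rows.append({"peak_id": pid, "category": "overlap", "planted_class": label})
    n_cgbm_only = int(round(cfg.cgbm_frac_a_only * len(only_ids)))
    for j, pid in enumerate(only_ids):
        iv = by_name[pid]
        if j < n_cgbm_only:
            seq = sd.plant_class_sequence("cGBM", len(iv), cfg.gc, pwm, rng)
            store.set_slice(iv.chrom, iv.start, seq)
            rows.append({"peak_id": pid, "category": "a_only", "planted_class": "cGBM"})
        else:
            rows.append({"peak_id": pid, "category": "a_only", "planted_class": "background"})
    return pd.DataFrame(rows)


def write_inputs(cfg: sd.SimConfig, outdir) -> dict:
    """Simulate the full study and write its input files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pwm = read_pwm(bundled_pwm_path())
    chroms, store = sd.simulate_genome(cfg)
    peaks_a, peaks_b, overlap_truth = sd.simulate_peak_sets(cfg, chroms)
    class_truth = _plant_peak_classes(cfg, store, peaks_a, overlap_truth, pwm)
    genes = sd.simulate_gene_annotation(cfg, chroms)
    de_a, de_b, de_truth = sd.simulate_de_tables(cfg, genes)
    reporter = sd.simulate_reporter_data(cfg)

    paths = {
        "config": outdir / "config.yaml",
        "genome": outdir / "genome.fa",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "peaks_a": outdir / "peaks_a.bed",
        "peaks_b": outdir / "peaks_b.bed",
        "genes": outdir / "genes.tsv",
        "de_a": outdir / "de_condition_a.tsv",
        "de_b": outdir / "de_condition_b.tsv",
        "reporter": outdir / "reporter.tsv",
        "truth": outdir / "truth.json",
    }
    cfg.to_yaml(paths["config"])
    store.write_fasta(paths["genome"])
    chroms.write(paths["chrom_sizes"])
    write_bed(peaks_a, paths["peaks_a"])
    write_bed(peaks_b, paths["peaks_b"])
    genes.write_tsv(paths["genes"])
    de_a.to_csv(paths["de_a"], sep="\t", index=False)
    de_b.to_csv(paths["de_b"], sep="\t", index=False)
    reporter.to_csv(paths["reporter"], sep="\t", index=False)
    truth = {
        "seed": cfg.seed,
        "overlap": overlap_truth.to_dict(orient="list"),
        "classes": class_truth.to_dict(orient="list"),
        "de": de_truth.to_dict(orient="list"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def run_pipeline(cfg: sd.SimConfig, outdir, n_perm: int = 1000,
                 spacing_threshold: float = 0.75) -> dict:
    """Simulate, analyze, and write results; returns the results dict.

    ``spacing_threshold`` is the PWM cutoff for the composite-site scan; it
    sits below the 0.8 classification cutoff so that low-affinity divergent
    GBM sites also contribute GBM/E-box pairs to the spacing grid.
    """
    outdir = Path(outdir)
    paths = write_inputs(cfg, outdir)
    pwm = read_pwm(bundled_pwm_path())
    seed = int(cfg.seed)

    chroms = ChromTable.read(paths["chrom_sizes"])
    store = SequenceStore.read_fasta(paths["genome"], chroms)
    peaks_a = read_bed(paths["peaks_a"], chroms, label="factor_a")
    peaks_b = read_bed(paths["peaks_b"], chroms, label="factor_b")
    genes = GeneAnnot.read_tsv(paths["genes"])
    de_a = read_de_table(paths["de_a"])
    de_b = read_de_table(paths["de_b"])
    reporter = read_reporter_table(paths["reporter"])

    # --- co-occupancy
    overlap_set, frac_a = intersect(peaks_a, peaks_b)
    enrich = permutation_overlap_test(peaks_a, peaks_b, chroms, n_perm=n_perm, seed=seed)
    overlap_ids = {iv.name for iv in overlap_set}
    only_set = PeakSet("a_only", [iv for iv in peaks_a if iv.name not in overlap_ids])

    # --- motif classification and 8-mer census
    seqs_overlap = extract_sequences(overlap_set, store)
    seqs_only = extract_sequences(only_set, store)
    class_fracs, class_table = classify_peakset(seqs_overlap, pwm)
    census_only = count_kmers(seqs_only.values(), k=8)
    census_overlap = count_kmers(seqs_overlap.values(), k=8)

    # --- spacing / orientation on co-occupied peaks
    pairs, n_peaks_with_pair = composite_sites(
        seqs_overlap, pwm, threshold=spacing_threshold, window=100
    )
    grid = spacing_grid(pairs, window=100)
    grid_df = config_enrichment_test(grid, n_perm=n_perm, seed=seed)
    top_orient, top_gap, top_frac = max_config_fraction(grid)

    # --- expression integration
    de_set_a = de_filter(de_a)
    de_set_b = de_filter(de_b)
    universe = set(de_a["gene_id"]) & set(de_b["gene_id"])
    ostat = hypergeometric_overlap(set(de_set_a), set(de_set_b), universe)
    shared = set(de_set_a) & set(de_set_b)
    concord = direction_concordance(de_a, de_b, shared) if shared else None
    nearest = assign_nearest_genes(peaks_a, genes)
    peak_to_genes = {
        pid: {g for g in (ng.upstream, ng.downstream) if g is not None}
        for pid, ng in nearest.items()
    }
    peak_category = {iv.name: ("overlap" if iv.name in overlap_ids else "a_only")
                     for iv in peaks_a}
    cat_counts, _ = de_counts_by_peak_class(set(de_set_a), peak_to_genes, peak_category)
    class_map = dict(zip(class_table["peak_id"], class_table["class"]))
    cls_counts, _ = de_counts_by_peak_class(set(de_set_a), peak_to_genes, class_map)

    # --- marker-set proximity enrichment (markers drawn near co-occupied peaks)
    rng = np.random.default_rng([seed, _TAG_MARKERS, 2])
    proximal = sorted({g for pid in overlap_ids for g in peak_to_genes.get(pid, set())})
    marker_size = min(100, max(10, len(proximal) // 2))
    n_prox = int(round(0.8 * marker_size))
    others = sorted(set(genes.gene_ids()) - set(proximal))
    markers = set(rng.choice(proximal, size=min(n_prox, len(proximal)), replace=False))
    markers |= set(rng.choice(others, size=marker_size - len(markers), replace=False))
    prox_enrich = geneset_proximity_enrichment(
        markers, set(proximal), set(genes.gene_ids()), n_perm=n_perm, seed=seed
    )

    # --- reporter synergy
    normalized = normalize_reporter(reporter)
    synergy = synergy_test(normalized, method="delta")

    results = {
        "seed": seed,
        "n_canonical_8mers": enumerate_canonical_kmers(8),
        "cooccupancy": {
            "n_peaks_a": len(peaks_a),
            "n_peaks_b": len(peaks_b),
            "n_overlap": len(overlap_set),
            "frac_a_overlap": frac_a,
            "enrichment": asdict(enrich),
        },
        "classification": {
            "fractions_overlap_peaks": class_fracs,
            "cgbm_peak_fraction_a_only": kmer_peak_fraction(
                list(seqs_only.values()), CGBM_8MER
            ),
            "cgbm_peak_fraction_overlap": kmer_peak_fraction(
                list(seqs_overlap.values()), CGBM_8MER
            ),
            "cgbm_rank_a_only": rank_kmer(census_only, CGBM_8MER),
            "cgbm_rank_overlap": rank_kmer(census_overlap, CGBM_8MER),
            "dgbm_rank_overlap": rank_kmer(census_overlap, DGBM_8MER),
        },
        "spacing": {
            "n_pairs": len(pairs),
            "n_peaks_with_pair": n_peaks_with_pair,
            "top_orientation": top_orient,
            "top_gap": top_gap,
            "top_fraction": top_frac,
            "n_cells_flagged": int((grid_df["p_adj"] < 0.05).sum()),
        },
        "expression": {
            "n_de_a": len(de_set_a),
            "n_de_b": len(de_set_b),
            "n_shared": ostat.n_overlap,
            "shared_frac_of_a": ostat.n_overlap / max(1, len(de_set_a)),
            "p_hyper": ostat.p_hyper,
            "jaccard": ostat.jaccard,
            "concordance": concord,
            "de_counts_by_category": cat_counts,
            "de_counts_by_class": cls_counts,
            "marker_proximity": asdict(prox_enrich),
        },
        "reporter": [
            {
                "construct": s.construct,
                "means": s.means,
                "expected_additive": s.expected_additive,
                "excess": s.excess,
                "p_synergy": s.p_synergy,
            }
            for s in synergy
        ],
    }

    class_table.to_csv(outdir / "peak_classes.tsv", sep="\t", index=False)
    grid_df.to_csv(outdir / "spacing_grid.tsv", sep="\t", index=False)
    census_overlap.to_frame().head(100).to_csv(
        outdir / "kmer_census_overlap_top100.tsv", sep="\t", index=False
    )
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
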