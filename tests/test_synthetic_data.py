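"""Determinism and planted-parameter recovery of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from comotif.intervals_io import ValidationError, extract_sequences, intersect
from comotif.motifs import CGBM_8MER, DGBM_8MER, classify_peak, find_core, find_ebox
from comotif.expression_integration import de_filter
from comotif.synthetic_data import (
    DEPlan,
    MotifPlan,
    ReporterPlan,
    SimConfig,
    embed_motifs,
    plant_class_sequence,
    simulate_classified_peaks,
    simulate_de_tables,
    simulate_gene_annotation,
    simulate_genome,
    simulate_peak_sets,
    simulate_reporter_data,
)


def small_cfg(**kw):
    defaults = dict(
        seed=5,
        n_chrom=2,
        chrom_len=200_000,
        n_peaks_a=60,
        n_peaks_b=60,
        n_genes=40,
        de=DEPlan(n_de=20),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        _, s1 = simulate_genome(cfg)
        _, s2 = simulate_genome(cfg)
        assert s1["chr1"] == s2["chr1"]

    def test_gc_zero_yields_at_only(self):
        cfg = small_cfg(gc=0.0, chrom_len=10_000, n_chrom=1)
        _, store = simulate_genome(cfg)
        assert set(store["chr1"]) <= {"A", "T"}

    def test_gc_within_binomial_tolerance(self):
        n = 1_000_000
        cfg = small_cfg(gc=0.5, chrom_len=n, n_chrom=1)
        _, store = simulate_genome(cfg)
        gc = sum(store["chr1"].count(b) for b in "GC") / n
        sd = np.sqrt(0.25 / n)
        assert abs(gc - 0.5) < 3 * sd

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValidationError):
            small_cfg(gc=1.5)


class TestPeakSets:
    @pytest.mark.parametrize("frac,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_extreme_overlap_fractions(self, frac, expected):
        cfg = small_cfg(overlap_frac=frac)
        chroms, _ = simulate_genome(cfg)
        a, b, truth = simulate_peak_sets(cfg, chroms)
        _, realized = intersect(a, b)
        assert realized == expected

    def test_planted_fraction_recovered_exactly(self):
        cfg = small_cfg(overlap_frac=0.6, n_peaks_a=100)
        chroms, _ = simulate_genome(cfg)
        a, b, truth = simulate_peak_sets(cfg, chroms)
        _, realized = intersect(a, b)
        assert realized == pytest.approx(0.6)
        assert truth["planted_overlap"].sum() == 60

    def test_infeasible_density_rejected(self):
        cfg = small_cfg(chrom_len=2_000, n_chrom=1, n_peaks_a=50, n_peaks_b=50, n_genes=0)
        with pytest.raises(ValidationError):
            simulate_peak_sets(cfg, simulate_genome(cfg)[0])


def _grid_peaks(chroms, n=50, length=300, step=2000):
    """Non-overlapping peaks on a regular grid (embedding tests need disjoint
    peaks so one peak's insertions cannot overwrite another's)."""
    from comotif.intervals_io import Interval, PeakSet

    return PeakSet(
        "grid",
        [Interval("chr1", i * step, i * step + length, name=f"p{i}") for i in range(n)],
        chroms,
    )


class TestEmbedMotifs:
    def test_independent_placements_recorded_and_written(self):
        cfg = small_cfg()
        cfg.motif_plan = MotifPlan(p_dgbm=1.0, p_ebox=1.0)
        chroms, store = simulate_genome(cfg)
        peaks = _grid_peaks(chroms)
        out, ledger = embed_motifs(peaks, store, cfg)
        seqs = extract_sequences(peaks, out)
        for pid, sub in ledger.groupby("peak_id"):
            seq = seqs[pid]
            for row in sub.itertuples():
                if row.kind == "dgbm":
                    ins = DGBM_8MER
                    expected = ins if row.strand != "-" else None
                    window = seq[row.offset:row.offset + 8]
                    from comotif.motifs import revcomp
                    assert window in (ins, revcomp(ins))
                elif row.kind == "ebox":
                    assert find_ebox(seq[row.offset:row.offset + 6]) != []

    def test_ebox_on_minus_strand_still_matches_pattern(self):
        # CANNTG reverse-complemented is again CANNTG-shaped
        from comotif.motifs import revcomp
        from comotif.synthetic_data import EBOX_REALIZATIONS

        for e in EBOX_REALIZATIONS:
            assert find_ebox(revcomp(e)) == [(0, revcomp(e))]

    def test_composite_layout_reproduces_gaps(self):
        # promoter-proximal geometry: E-box, 22 bp, GBM 8-mer, 2 bp, E-box
        cfg = small_cfg()
        cfg.motif_plan = MotifPlan(
            p_layout=1.0, layout=[("ebox", 0), ("dgbm", 22), ("ebox", 2)]
        )
        chroms, store = simulate_genome(cfg)
        peaks = _grid_peaks(chroms)
        out, ledger = embed_motifs(peaks, store, cfg)
        seqs = extract_sequences(peaks, out)
        for pid, sub in ledger.groupby("peak_id"):
            sub = sub.sort_values("offset").reset_index(drop=True)
            assert list(sub["kind"]) == ["ebox", "dgbm", "ebox"]
            e1, g, e2 = sub["offset"]
            assert g - (e1 + 6) == 22
            assert e2 - (g + 8) == 2
            assert seqs[pid][g:g + 8] == DGBM_8MER
            assert find_ebox(seqs[pid][e1:e1 + 6]) and find_ebox(seqs[pid][e2:e2 + 6])

    def test_collision_error_names_peak(self):
        cfg = small_cfg()
        cfg.motif_plan = MotifPlan(
            p_layout=1.0, layout=[("ebox", 0), ("dgbm", 80), ("ebox", 2)]
        )
        chroms, store = simulate_genome(cfg)
        peaks = _grid_peaks(chroms, n=5, length=50)
        with pytest.raises(ValidationError, match="too short"):
            embed_motifs(peaks, store, cfg)


class TestClassPlanting:
    def test_planted_classes_verified_by_classifier(self, pwm, rng):
        for target in ("cGBM", "dGBM", "neither"):
            seq = plant_class_sequence(target, 300, 0.42, pwm, rng)
            assert classify_peak(seq, pwm).label == target

    def test_exact_class_counts(self, pwm):
        seqs, truth = simulate_classified_peaks(
            60, (0.2, 0.5, 0.3), 250, 0.42, pwm, seed=3
        )
        counts = truth["planted_class"].value_counts()
        assert counts["cGBM"] == 12 and counts["dGBM"] == 30 and counts["neither"] == 18
        for pid, seq in seqs.items():
            planted = truth.set_index("peak_id").loc[pid, "planted_class"]
            assert classify_peak(seq, pwm).label == planted


class TestGeneAnnotation:
    def test_deterministic(self):
        cfg = small_cfg()
        chroms, _ = simulate_genome(cfg)
        a1 = simulate_gene_annotation(cfg, chroms)
        a2 = simulate_gene_annotation(cfg, chroms)
        assert [(r.gene_id, r.tss) for r in a1] == [(r.gene_id, r.tss) for r in a2]

    def test_bodies_non_overlapping(self):
        cfg = small_cfg(n_genes=60)
        chroms, _ = simulate_genome(cfg)
        annot = simulate_gene_annotation(cfg, chroms)
        by_chrom = {}
        for r in annot:
            by_chrom.setdefault(r.chrom, []).append((r.body.start, r.body.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_requested_count_placed(self):
        cfg = small_cfg(n_genes=37)
        chroms, _ = simulate_genome(cfg)
        assert len(simulate_gene_annotation(cfg, chroms)) == 37

    def test_mean_tss_gap_near_uniform_expectation(self):
        cfg = small_cfg(n_chrom=1, chrom_len=2_000_000, n_genes=200)
        chroms, _ = simulate_genome(cfg)
        annot = simulate_gene_annotation(cfg, chroms)
        tss = np.sort([r.tss for r in annot])
        gaps = np.diff(tss)
        # ~200 uniform bodies on 2 Mb: mean inter-TSS gap near 10 kb
        assert gaps.mean() == pytest.approx(2_000_000 / 200, rel=0.2)

    def test_infeasible_density_rejected(self):
        cfg = small_cfg(n_chrom=1, chrom_len=50_000, n_genes=100)
        chroms, _ = simulate_genome(cfg)
        with pytest.raises(ValidationError):
            simulate_gene_annotation(cfg, chroms)


class TestDETables:
    def test_full_sharing_full_concordance(self):
        cfg = small_cfg(de=DEPlan(n_de=20, shared_frac=1.0, concordant_frac=1.0))
        chroms, _ = simulate_genome(cfg)
        genes = simulate_gene_annotation(cfg, chroms)
        a, b, _ = simulate_de_tables(cfg, genes)
        sa, sb = de_filter(a), de_filter(b)
        assert set(sa) == set(sb)
        assert all(sa[g] == sb[g] for g in sa)

    def test_zero_sharing(self):
        cfg = small_cfg(de=DEPlan(n_de=15, shared_frac=0.0))
        chroms, _ = simulate_genome(cfg)
        genes = simulate_gene_annotation(cfg, chroms)
        a, b, _ = simulate_de_tables(cfg, genes)
        assert set(de_filter(a)) & set(de_filter(b)) == set()

    def test_filter_recovers_planted_sets_exactly(self):
        cfg = small_cfg(chrom_len=500_000, n_genes=200, de=DEPlan(n_de=50, shared_frac=0.5))
        chroms, _ = simulate_genome(cfg)
        genes = simulate_gene_annotation(cfg, chroms)
        a, b, truth = simulate_de_tables(cfg, genes)
        truth = truth.set_index("gene_id")
        assert set(de_filter(a)) == set(truth.index[truth["de_a"]])
        assert set(de_filter(b)) == set(truth.index[truth["de_b"]])
        assert len(de_filter(a)) == 50

    def test_planted_concordance_fraction(self):
        cfg = small_cfg(
            chrom_len=1_000_000,
            n_genes=400,
            de=DEPlan(n_de=100, shared_frac=0.8, concordant_frac=0.75),
        )
        chroms, _ = simulate_genome(cfg)
        genes = simulate_gene_annotation(cfg, chroms)
        a, b, _ = simulate_de_tables(cfg, genes)
        sa, sb = de_filter(a), de_filter(b)
        shared = set(sa) & set(sb)
        assert len(shared) == 80
        concordant = sum(1 for g in shared if sa[g] == sb[g])
        assert concordant == 60  # 0.75 * 80


class TestReporter:
    def test_noiseless_additive(self):
        cfg = small_cfg()
        cfg.reporter = ReporterPlan(constructs={"X": 1.0}, cv=0.0, renilla_cv=0.0)
        tab = simulate_reporter_data(cfg)
        from comotif.reporter_synergy import normalize_reporter

        norm = normalize_reporter(tab)
        ab = norm.loc[norm["condition"] == "AB", "relative"]
        assert np.allclose(ab, cfg.reporter.effect_a + cfg.reporter.effect_b - 1.0)

    def test_noiseless_interaction_two(self):
        cfg = small_cfg()
        cfg.reporter = ReporterPlan(
            constructs={"X": 2.0}, effect_a=2.0, effect_b=2.0, cv=0.0
        )
        tab = simulate_reporter_data(cfg)
        from comotif.reporter_synergy import normalize_reporter

        norm = normalize_reporter(tab)
        ab = norm.loc[norm["condition"] == "AB", "relative"]
        assert np.allclose(ab, 6.0)  # (2 + 2 - 1) * 2

    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        t1 = simulate_reporter_data(cfg)
        t2 = simulate_reporter_data(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValidationError):
            ReporterPlan(effect_a=-1.0)
        with pytest.raises(ValidationError):
            ReporterPlan(n_rep=1)
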