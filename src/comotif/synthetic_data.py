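"""Synthetic inputs with planted, recoverable structure.

Every generator is deterministic under ``SimConfig.seed``: each draws from a
``numpy`` Generator seeded by (seed, stage-tag) so outputs do not depend on
call order. Planted quantities (overlap fraction, motif content, shared DE
fraction, reporter interaction) are recorded in truth tables so that the
downstream analysis stages can be tested as parameter-recovery problems.

The defaults emulate the structure of the mouse mandibular-prominence
ChIP-seq study the pipeline was designed around: two peak sets with ~62% of
the first factor's peaks co-occupied by the second; co-occupied peaks
dominated by the divergent low-affinity Gli motif (GACCTCCC / CCTCC core,
85%) with a small canonical (GACCACCC, 9%) and residual (6%) class;
factor-A-only peaks carrying the canonical 8-mer in ~16% of peaks; two
differential-expression tables sharing ~50% of their DE genes; and
dual-luciferase reporters in which the divergent-motif construct responds
super-additively (interaction 2) and the canonical construct additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .intervals_io import (
    ChromTable,
    GeneAnnot,
    GeneRecord,
    Interval,
    PeakSet,
    SequenceStore,
    ValidationError,
)
from . import motifs as _motifs
from .motifs import CGBM_8MER, DGBM_8MER, DGBM_CORE, PWMatrix, classify_peak, revcomp

# stage tags for seed derivation (stable across releases)
_TAG_GENOME = 1
_TAG_PEAKS = 2
_TAG_EMBED = 3
_TAG_GENES = 4
_TAG_DE = 5
_TAG_REPORTER = 6
_TAG_CLASSES = 7

EBOX_REALIZATIONS = tuple(
    "CA" + n1 + n2 + "TG" for n1 in "ACGT" for n2 in "ACGT"
)

_MOTIF_SEQS = {"cgbm": CGBM_8MER, "dgbm": DGBM_8MER}


@dataclass
class MotifPlan:
    """Per-peak embedding probabilities and optional composite layout.

    ``layout`` is a list of (kind, gap_before) elements placed left to right
    with the stated edge-to-edge gaps, e.g. the promoter-proximal geometry
    [("ebox", 0), ("dgbm", 22), ("ebox", 2)]. When a layout is given it is
    embedded as a unit (per-peak with probability ``p_layout``) instead of
    independent placements.
    """

    p_cgbm: float = 0.0
    p_dgbm: float = 0.0
    p_ebox: float = 0.0
    p_layout: float = 0.0
    layout: Optional[list] = None

    def __post_init__(self):
        for p in (self.p_cgbm, self.p_dgbm, self.p_ebox, self.p_layout):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("embedding probabilities must lie in [0, 1]")


@dataclass
class DEPlan:
    n_de: int = 400
    shared_frac: float = 0.5
    concordant_frac: float = 1.0
    lfc_scale: float = 0.8  # exponential scale of |log2fc| above the 1.5-fold cut

    def __post_init__(self):
        if not 0.0 <= self.shared_frac <= 1.0 or not 0.0 <= self.concordant_frac <= 1.0:
            raise ValidationError("fractions must lie in [0, 1]")


@dataclass
class ReporterPlan:
    """Expected relative outputs: control 1, A, B, and AB = (A+B-1)*interaction."""

    baseline: float = 1.0  # raw firefly/renilla ratio of the control condition
    effect_a: float = 2.0
    effect_b: float = 2.0
    constructs: dict = field(
        default_factory=lambda: {"cGBM_Ebox": 1.0, "dGBM_Ebox": 2.0}
    )  # construct -> interaction multiplier
    cv: float = 0.1  # multiplicative (log-normal) CV of the firefly/renilla ratio
    renilla_mean: float = 1000.0
    renilla_cv: float = 0.2
    n_rep: int = 6

    def __post_init__(self):
        if self.baseline <= 0 or self.effect_a <= 0 or self.effect_b <= 0:
            raise ValidationError("baseline and effects must be positive")
        if self.cv < 0 or self.renilla_cv < 0:
            raise ValidationError("CV must be >= 0")
        if self.n_rep < 2:
            raise ValidationError("need >= 2 replicates per condition")


@dataclass
class SimConfig:
    seed: int = 0
    # genome
    n_chrom: int = 2
    chrom_len: int = 5_000_000
    gc: float = 0.42
    # peaks
    n_peaks_a: int = 1000
    n_peaks_b: int = 1000
    overlap_frac: float = 0.62
    peak_len_mean: float = 300.0
    peak_len_sd: float = 50.0
    # motif content per peak category (fractions of peaks in each class)
    class_fracs_overlap: tuple = (0.09, 0.85, 0.06)  # (cGBM, dGBM, neither)
    cgbm_frac_a_only: float = 0.16
    motif_plan: MotifPlan = field(default_factory=MotifPlan)
    # genes / expression
    n_genes: int = 2000
    gene_len_range: tuple = (2_000, 4_000)
    de: DEPlan = field(default_factory=DEPlan)
    # reporter assay
    reporter: ReporterPlan = field(default_factory=ReporterPlan)

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError("gc must lie in [0, 1]")
        if not 0.0 <= self.overlap_frac <= 1.0:
            raise ValidationError("overlap_frac must lie in [0, 1]")
        if self.n_chrom < 1 or self.chrom_len < 1000:
            raise ValidationError("need >= 1 chromosome of >= 1 kb")
        if abs(sum(self.class_fracs_overlap) - 1.0) > 1e-9:
            raise ValidationError("class_fracs_overlap must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("motif_plan", MotifPlan), ("de", DEPlan), ("reporter", ReporterPlan)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("class_fracs_overlap", "gene_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["class_fracs_overlap"] = list(self.class_fracs_overlap)
        data["gene_len_range"] = list(self.gene_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _rng(cfg_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed), tag])


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


# ---------------------------------------------------------------------------
# genome and peaks


def simulate_genome(cfg: SimConfig) -> tuple[ChromTable, SequenceStore]:
    """I.i.d. bases with P(G)=P(C)=gc/2 on n_chrom chromosomes."""
    rng = _rng(cfg.seed, _TAG_GENOME)
    seqs = {
        f"chr{i + 1}": random_dna(cfg.chrom_len, cfg.gc, rng) for i in range(cfg.n_chrom)
    }
    store = SequenceStore(seqs)
    return store.chrom_table(), store


def _draw_lengths(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lens = rng.normal(cfg.peak_len_mean, cfg.peak_len_sd, size=n)
    return np.maximum(50, np.round(lens)).astype(np.int64)


def simulate_peak_sets(cfg: SimConfig, chroms: ChromTable
                       ) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Two peak sets with a planted co-occupancy fraction.

    B-peaks are placed uniformly; round(overlap_frac * n_peaks_a) a-peaks are
    placed to overlap a random b-peak by >= 1 bp, and the remaining a-peaks
    are placed uniformly while avoiding any overlap with b (rejection
    sampling), so the realized a-in-b fraction equals the plan exactly.
    The truth table records each a-peak's planted status.
    """
    rng = _rng(cfg.seed, _TAG_PEAKS)
    names = chroms.names
    total_bp = sum(length for _, length in chroms)
    need = (cfg.n_peaks_a + cfg.n_peaks_b) * cfg.peak_len_mean
    if need > total_bp:
        raise ValidationError("total peak bp exceeds genome size")

    b_lens = _draw_lengths(cfg.n_peaks_b, cfg, rng)
    b_intervals = []
    for i in range(cfg.n_peaks_b):
        chrom = names[rng.integers(len(names))]
        start = int(rng.integers(0, chroms[chrom] - b_lens[i]))
        b_intervals.append(Interval(chrom, start, start + int(b_lens[i]), name=f"b{i}"))
    peaks_b = PeakSet("factor_b", b_intervals, chroms)

    n_planted = int(round(cfg.overlap_frac * cfg.n_peaks_a))
    a_lens = _draw_lengths(cfg.n_peaks_a, cfg, rng)
    a_intervals = []
    truth = []
    for i in range(cfg.n_peaks_a):
        length = int(a_lens[i])
        if i < n_planted:
            anchor = b_intervals[int(rng.integers(len(b_intervals)))]
            lo = max(0, anchor.start - length + 1)
            hi = min(chroms[anchor.chrom] - length, anchor.end - 1)
            start = int(rng.integers(lo, hi + 1))
            iv = Interval(anchor.chrom, start, start + length, name=f"a{i}")
            planted = True
        else:
            for _ in range(1000):
                chrom = names[rng.integers(len(names))]
                start = int(rng.integers(0, chroms[chrom] - length))
                iv = Interval(chrom, start, start + length, name=f"a{i}")
                if not any(iv.overlaps(bv) for bv in b_intervals if bv.chrom == iv.chrom):
                    break
            else:
                raise ValidationError("could not place non-overlapping a-peak (density too high)")
            planted = False
        a_intervals.append(iv)
        truth.append({"peak_id": iv.name, "planted_overlap": planted})
    peaks_a = PeakSet("factor_a", a_intervals, chroms)
    return peaks_a, peaks_b, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# motif embedding


def _place_block(occupied: list[tuple[int, int]], length: int, peak_len: int,
                 rng: np.random.Generator, attempts: int = 100) -> int:
    if peak_len < length:
        raise ValidationError("peak shorter than planned insertion")
    for _ in range(attempts):
        off = int(rng.integers(0, peak_len - length + 1))
        if all(off + length <= s or off >= e for s, e in occupied):
            occupied.append((off, off + length))
            return off
    raise ValidationError("could not place motif without collision after 100 attempts")


def embed_motifs(peaks: PeakSet, store: SequenceStore, cfg: SimConfig,
                 plan: Optional[MotifPlan] = None
                 ) -> tuple[SequenceStore, pd.DataFrame]:
    """Write planned motif instances into peak sequences.

    Each peak independently receives a cGBM consensus, dGBM 8-mer, and/or an
    E-box (drawn uniformly from the 16 CANNTG realizations) per the plan's
    probabilities, at random non-colliding offsets and random strands
    (reverse-complemented when on the minus strand). When a composite
    ``layout`` is planned, its elements are written left-to-right with the
    stated edge-to-edge gaps. The returned ledger lists one row per
    placement: (peak_id, kind, offset, strand, gap_before).
    """
    plan = plan or cfg.motif_plan
    rng = _rng(cfg.seed, _TAG_EMBED)
    out = store.copy()
    rows = []
    for iv in peaks:
        peak_len = len(iv)
        occupied: list[tuple[int, int]] = []
        # each placement: (kind, offset, strand, gap_before, realized sequence)
        placements: list[tuple[str, int, str, Optional[int], str]] = []
        if plan.layout is not None and rng.random() < plan.p_layout:
            total = sum(
                len(_MOTIF_SEQS.get(kind, "CANNTG")) + gap for kind, gap in plan.layout
            )
            if peak_len < total:
                raise ValidationError(f"peak {iv.key} too short for composite layout")
            cursor = int(rng.integers(0, peak_len - total + 1))
            for kind, gap in plan.layout:
                cursor += gap
                ins = _MOTIF_SEQS.get(kind) or str(rng.choice(EBOX_REALIZATIONS))
                occupied.append((cursor, cursor + len(ins)))
                placements.append((kind, cursor, "+", gap, ins))
                cursor += len(ins)
        for kind, p in (("cgbm", plan.p_cgbm), ("dgbm", plan.p_dgbm), ("ebox", plan.p_ebox)):
            if rng.random() >= p:
                continue
            ins = _MOTIF_SEQS.get(kind) or str(rng.choice(EBOX_REALIZATIONS))
            off = _place_block(occupied, len(ins), peak_len, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((kind, off, strand, None, ins))
        for kind, off, strand, gap, ins in placements:
            out.set_slice(iv.chrom, iv.start + off, revcomp(ins) if strand == "-" else ins)
            rows.append(
                {
                    "peak_id": iv.key,
                    "kind": kind,
                    "offset": off,
                    "strand": strand,
                    "gap_before": gap,
                }
            )
    ledger = pd.DataFrame(rows, columns=["peak_id", "kind", "offset", "strand", "gap_before"])
    return out, ledger


def plant_class_sequence(target: str, length: int, gc: float, pwm: PWMatrix,
                         rng: np.random.Generator, threshold: float = 0.8,
                         core: str = DGBM_CORE, with_ebox: bool = False,
                         max_attempts: int = 200) -> str:
    """A random sequence whose three-way classification is ``target``.

    Background is drawn i.i.d. and the class-defining 8-mer inserted at a
    random offset; the draw is rejected and retried until the classifier
    confirms the target label (accidental canonical hits or CCTCC cores in
    the background would otherwise contaminate the planted class).
    """
    if target not in ("cGBM", "dGBM", "neither"):
        raise ValidationError(f"unknown class {target!r}")
    for _ in range(max_attempts):
        seq = random_dna(length, gc, rng)
        gbm_span = None
        if target in ("cGBM", "dGBM"):
            ins = CGBM_8MER if target == "cGBM" else DGBM_8MER
            off = int(rng.integers(0, length - len(ins) + 1))
            seq = seq[:off] + ins + seq[off + len(ins):]
            gbm_span = (off, off + len(ins))
        if with_ebox:
            ebox = str(rng.choice(EBOX_REALIZATIONS))
            # the E-box footprint must not touch the planted GBM
            for _ in range(50):
                off2 = int(rng.integers(0, length - len(ebox) + 1))
                if gbm_span is None or off2 + len(ebox) <= gbm_span[0] or off2 >= gbm_span[1]:
                    break
            seq = seq[:off2] + ebox + seq[off2 + len(ebox):]
        if classify_peak(seq, pwm, threshold, core).label == target:
            return seq
    raise ValidationError(f"could not plant class {target} in {max_attempts} attempts")


def simulate_classified_peaks(n: int, class_fracs: tuple, length: int, gc: float,
                              pwm: PWMatrix, seed: int, threshold: float = 0.8,
                              with_ebox: bool = False
                              ) -> tuple[dict[str, str], pd.DataFrame]:
    """n peak sequences with exact planted class counts (cGBM, dGBM, neither)."""
    if abs(sum(class_fracs) - 1.0) > 1e-9:
        raise ValidationError("class fractions must sum to 1")
    rng = _rng(seed, _TAG_CLASSES)
    n_c = int(round(class_fracs[0] * n))
    n_d = int(round(class_fracs[1] * n))
    labels = ["cGBM"] * n_c + ["dGBM"] * n_d + ["neither"] * (n - n_c - n_d)
    rng.shuffle(labels)
    seqs, rows = {}, []
    for i, label in enumerate(labels):
        pid = f"peak{i}"
        seqs[pid] = plant_class_sequence(label, length, gc, pwm, rng,
                                         threshold=threshold, with_ebox=with_ebox)
        rows.append({"peak_id": pid, "planted_class": label})
    return seqs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation and expression


def simulate_gene_annotation(cfg: SimConfig, chroms: ChromTable) -> GeneAnnot:
    """Non-overlapping gene bodies with uniformly distributed positions.

    Genes are apportioned to chromosomes proportionally to length; within a
    chromosome the free (non-genic) space is split into multinomial gaps
    between consecutive bodies, which places the bodies uniformly at random
    subject to non-overlap and is feasible whenever the bodies fit. Strands
    are random; the TSS sits at the 5' end of the body.
    """
    rng = _rng(cfg.seed, _TAG_GENES)
    lo, hi = cfg.gene_len_range
    total = sum(length for _, length in chroms)
    records = []
    gene_idx = 0
    remaining = cfg.n_genes
    names = chroms.names
    for ci, chrom in enumerate(names):
        L = chroms[chrom]
        n_c = remaining if ci == len(names) - 1 else int(round(cfg.n_genes * L / total))
        n_c = min(n_c, remaining)
        remaining -= n_c
        if n_c == 0:
            continue
        body_lens = rng.integers(lo, hi + 1, size=n_c)
        free = L - int(body_lens.sum())
        if free < 0:
            raise ValidationError(
                f"cannot place {n_c} gene bodies on {chrom} (length {L})"
            )
        gaps = rng.multinomial(free, np.full(n_c + 1, 1.0 / (n_c + 1)))
        start = 0
        for j in range(n_c):
            start += int(gaps[j])
            end = start + int(body_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            records.append(
                GeneRecord(
                    f"gene{gene_idx:05d}", chrom, strand, tss, Interval(chrom, start, end)
                )
            )
            gene_idx += 1
            start = end
    return GeneAnnot(records)


def simulate_de_tables(cfg: SimConfig, genes: GeneAnnot
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two DE tables (gene_id, log2fc, p_adj) with planted sharing structure.

    Each table marks ``n_de`` genes as differentially expressed
    (|log2fc| > log2 1.5 and p_adj < 0.05); a planted fraction of the DE
    genes is common to both tables, and among the shared genes a planted
    fraction agrees in sign. Non-DE genes fail both thresholds. Returns the
    two tables plus a truth table of planted calls.
    """
    plan = cfg.de
    universe = genes.gene_ids()
    if plan.n_de > len(universe):
        raise ValidationError("n_de exceeds number of genes")
    rng = _rng(cfg.seed, _TAG_DE)
    n_shared = int(round(plan.shared_frac * plan.n_de))
    perm = rng.permutation(len(universe))
    de_a = [universe[j] for j in perm[:plan.n_de]]
    shared = de_a[:n_shared]
    rest = [universe[j] for j in perm[plan.n_de:]]
    if plan.n_de - n_shared > len(rest):
        raise ValidationError("not enough genes for disjoint DE calls")
    de_b = shared + rest[: plan.n_de - n_shared]

    lfc_cut = np.log2(1.5)
    sign_a = {g: (1 if rng.random() < 0.5 else -1) for g in de_a}
    n_conc = int(round(plan.concordant_frac * n_shared))
    sign_b = {}
    for j, g in enumerate(shared):
        sign_b[g] = sign_a[g] if j < n_conc else -sign_a[g]
    for g in de_b[n_shared:]:
        sign_b[g] = 1 if rng.random() < 0.5 else -1

    def build(de_set, signs):
        rows = []
        for g in universe:
            if g in signs:
                mag = lfc_cut + 1e-6 + rng.exponential(plan.lfc_scale)
                rows.append((g, signs[g] * mag, rng.uniform(1e-8, 0.049)))
            else:
                lfc = float(np.clip(rng.normal(0.0, 0.15), -lfc_cut + 1e-6, lfc_cut - 1e-6))
                rows.append((g, lfc, rng.uniform(0.051, 1.0)))
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_adj"])

    table_a = build(de_a, sign_a)
    table_b = build(de_b, sign_b)
    truth = pd.DataFrame(
        {
            "gene_id": universe,
            "de_a": [g in sign_a for g in universe],
            "de_b": [g in sign_b for g in universe],
        }
    )
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# reporter assay


def _lognormal_unit_mean(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative noise with mean 1 and the stated coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def simulate_reporter_data(cfg: SimConfig) -> pd.DataFrame:
    """Dual-luciferase wells with a planted additive or super-additive effect.

    Expected relative outputs per construct are control=1, A=effect_a,
    B=effect_b, AB=(effect_a+effect_b-1)*interaction; the firefly/renilla
    ratio carries multiplicative log-normal noise with the planned CV, and
    renilla is drawn per well, so firefly = relative * baseline * renilla.
    """
    plan = cfg.reporter
    rng = _rng(cfg.seed, _TAG_REPORTER)
    rows = []
    for construct, interaction in plan.constructs.items():
        expected = {
            "control": 1.0,
            "A": plan.effect_a,
            "B": plan.effect_b,
            "AB": (plan.effect_a + plan.effect_b - 1.0) * interaction,
        }
        for condition, rel in expected.items():
            noise = _lognormal_unit_mean(plan.cv, plan.n_rep, rng)
            renilla = plan.renilla_mean * _lognormal_unit_mean(plan.renilla_cv, plan.n_rep, rng)
            ratio = rel * plan.baseline * noise
            for r in range(plan.n_rep):
                rows.append(
                    {
                        "construct": construct,
                        "condition": condition,
                        "replicate": r + 1,
                        "firefly": float(ratio[r] * renilla[r]),
                        "renilla": float(renilla[r]),
                    }
                )
    return pd.DataFrame(rows)
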