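"""PWM scanning, motif-core detection, peak classification, and k-mer census.

Scoring model
-------------
A position-probability matrix is pseudocounted, renormalized, and converted
to per-column log-odds against a uniform background. A window's score is the
sum of its per-column log-odds; it is min-max normalized by the matrix's
minimal and maximal achievable sums, so ``norm_score`` lies in [0, 1] and a
"fraction of max" threshold (default 0.8) is scale-free. The bundled matrix
``gbm_synthetic.pwm`` is a synthetic Gli-binding-motif stand-in with
consensus GACCACCC and a highly constrained 5th position, so that the
divergent variant GACCTCCC (an A->T change at position 5) falls below the
0.8 threshold while single substitutions at less constrained positions do
not.

Peak classes
------------
A peak is ``cGBM`` when it carries at least one PWM hit at or above the
threshold; otherwise ``dGBM`` when it carries the CCTCC core (either
strand); otherwise ``neither``. Classes are exhaustive and mutually
exclusive by construction.

K-mer census
------------
Each window position contributes one count to its canonical k-mer (the
lexicographic minimum of the k-mer and its reverse complement), so a
palindromic window is counted once rather than twice. For k=8 there are
(4^8 - 4^4)/2 + 4^4 = 32,896 canonical 8-mers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals_io import ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CGBM_8MER = "GACCACCC"
DGBM_8MER = "GACCTCCC"
DGBM_CORE = "CCTCC"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def bundled_pwm_path() -> str:
    """Path to the bundled synthetic canonical-GBM position matrix."""
    return str(importlib.resources.files("comotif.data") / "gbm_synthetic.pwm")


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWMatrix:
    """Position-probability matrix with derived log-odds score range."""

    motif_id: str
    probs: np.ndarray  # (L, 4), pseudocounted and renormalized
    pseudocount: float
    log_odds: np.ndarray = field(init=False)  # (L, 4)
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValidationError("PWM probabilities must be an (L, 4) array")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("PWM columns must each sum to 1 after renormalization")
        self.log_odds = np.log(self.probs / 0.25)
        self.s_min = float(self.log_odds.min(axis=1).sum())
        self.s_max = float(self.log_odds.max(axis=1).sum())

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def score(self, kmer: str) -> float:
        """Raw log-odds sum of one window (forward strand)."""
        if len(kmer) != len(self):
            raise ValidationError(f"window length {len(kmer)} != motif length {len(self)}")
        idx = [_BASE_INDEX[b] for b in kmer.upper()]
        return float(self.log_odds[np.arange(len(self)), idx].sum())

    def norm_score(self, kmer: str) -> float:
        """Min-max normalized score in [0, 1]; 1.0 everywhere if degenerate."""
        if self.s_max == self.s_min:
            return 1.0
        return (self.score(kmer) - self.s_min) / (self.s_max - self.s_min)


def read_pwm(path, pseudocount: float = 1e-3) -> PWMatrix:
    """Read a position-probability matrix from text.

    Two dialects are accepted: ``>motif_id`` followed by L lines of four
    whitespace-separated probabilities (A C G T order), or a Cis-BP-style
    table with a header line ``Pos A C G T`` and a leading position column.
    Rows must sum to ~1 before pseudocounting.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty PWM file")
    motif_id = "pwm"
    rows = []
    if lines[0].startswith(">"):
        motif_id = lines[0][1:].strip() or "pwm"
        body = lines[1:]
        for ln in body:
            rows.append([float(x) for x in ln.split()])
    else:
        header = lines[0].split()
        if [h.upper() for h in header[-4:]] == ["A", "C", "G", "T"]:
            motif_id = "pwm"
            for ln in lines[1:]:
                parts = ln.split()
                rows.append([float(x) for x in parts[-4:]])
        else:
            for ln in lines:
                rows.append([float(x) for x in ln.split()])
    mat = np.array(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValidationError(f"{path}: expected 4 probability columns")
    if mat.shape[0] < 4:
        raise ValidationError(f"{path}: motif length {mat.shape[0]} < 4")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-3):
        raise ValidationError(f"{path}: probability rows must sum to ~1")
    mat = (mat + pseudocount) / (1.0 + 4 * pseudocount)
    mat = mat / mat.sum(axis=1, keepdims=True)
    return PWMatrix(motif_id=motif_id, probs=mat, pseudocount=pseudocount)


@dataclass(frozen=True)
class MotifHit:
    offset: int  # 0-based within the scanned sequence
    strand: str  # '+' or '-'
    raw: float
    norm_score: float
    peak_id: Optional[str] = None


def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_pwm(seq: str, pwm: PWMatrix, threshold: float = 0.8,
             peak_id: Optional[str] = None) -> list[MotifHit]:
    """Score every window on both strands; return hits with norm >= threshold.

    Windows containing non-ACGT characters are skipped. The minus-strand
    score at an offset is the forward score of the window's reverse
    complement; both strands can hit at the same offset.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    L = len(pwm)
    n = len(seq) - L + 1
    if n <= 0:
        return []
    codes = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    pos_idx = np.arange(L)
    safe = np.where(windows >= 0, windows, 0)
    fwd = pwm.log_odds[pos_idx, safe].sum(axis=1)
    # reverse complement: complement base c = 3 - b, read right-to-left
    rev = pwm.log_odds[pos_idx, (3 - safe)[:, ::-1]].sum(axis=1)
    rng = pwm.s_max - pwm.s_min
    if rng == 0.0:
        fwd_norm = np.ones(n)
        rev_norm = np.ones(n)
    else:
        fwd_norm = (fwd - pwm.s_min) / rng
        rev_norm = (rev - pwm.s_min) / rng
    hits = []
    for off in np.nonzero(valid & (fwd_norm >= threshold))[0]:
        hits.append(MotifHit(int(off), "+", float(fwd[off]), float(fwd_norm[off]), peak_id))
    for off in np.nonzero(valid & (rev_norm >= threshold))[0]:
        hits.append(MotifHit(int(off), "-", float(rev[off]), float(rev_norm[off]), peak_id))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# fixed patterns


def find_ebox(seq: str) -> list[tuple[int, str]]:
    """All offsets matching the E-box CANNTG (its own reverse-complement).

    Because the pattern is strand-symmetric each offset is reported once,
    with the matched 6-mer; no strand is attached.
    """
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 5):
        w = seq[i:i + 6]
        if w[0] == "C" and w[1] == "A" and w[4] == "T" and w[5] == "G" \
                and all(b in BASES for b in w[2:4]):
            out.append((i, w))
    return out


def find_core(seq: str, core: str = DGBM_CORE) -> list[tuple[int, str]]:
    """All forward matches of ``core`` and of its reverse complement.

    Overlapping matches are all reported. Returns (offset, strand) pairs.
    """
    if not core:
        raise ValidationError("core must be non-empty")
    seq = seq.upper()
    rc = revcomp(core)
    out = []
    for i in range(len(seq) - len(core) + 1):
        w = seq[i:i + len(core)]
        if w == core:
            out.append((i, "+"))
        if w == rc and rc != core:
            out.append((i, "-"))
    out.sort()
    return out


# ---------------------------------------------------------------------------
# classification


@dataclass
class PeakClass:
    label: str  # 'cGBM' | 'dGBM' | 'neither'
    pwm_hits: list[MotifHit]
    core_hits: list[tuple[int, str]]


def classify_peak(seq: str, pwm: PWMatrix, threshold: float = 0.8,
                  core: str = DGBM_CORE) -> PeakClass:
    """Three-way classification: cGBM beats dGBM beats neither."""
    pwm_hits = scan_pwm(seq, pwm, threshold)
    core_hits = find_core(seq, core)
    if pwm_hits:
        label = "cGBM"
    elif core_hits:
        label = "dGBM"
    else:
        label = "neither"
    return PeakClass(label, pwm_hits, core_hits)


def classify_peakset(seqs: dict[str, str], pwm: PWMatrix, threshold: float = 0.8,
                     core: str = DGBM_CORE) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-class fractions plus a per-peak classification table."""
    if not seqs:
        raise ValidationError("classify_peakset requires at least one peak")
    rows = []
    for peak_id, seq in seqs.items():
        pc = classify_peak(seq, pwm, threshold, core)
        rows.append(
            {
                "peak_id": peak_id,
                "class": pc.label,
                "n_pwm_hits": len(pc.pwm_hits),
                "n_core_hits": len(pc.core_hits),
                "best_norm_score": max((h.norm_score for h in pc.pwm_hits), default=np.nan),
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    fractions = {
        label: float((table["class"] == label).sum()) / n
        for label in ("cGBM", "dGBM", "neither")
    }
    return fractions, table


# ---------------------------------------------------------------------------
# k-mer census


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    kmer = kmer.upper()
    if any(b not in BASES for b in kmer):
        raise ValidationError(f"ambiguous base in k-mer {kmer!r}")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def enumerate_canonical_kmers(k: int, as_list: bool = False):
    """Number of canonical k-mers: (4^k - P)/2 + P, P = # palindromes.

    P is 0 for odd k and 4^(k/2) for even k (a reverse-complement palindrome
    is determined by its first half). For k=8 the count is 32,896.
    """
    if not 1 <= k <= 12:
        raise ValidationError("k must lie in [1, 12]")
    palindromes = 0 if k % 2 else 4 ** (k // 2)
    count = (4 ** k - palindromes) // 2 + palindromes
    if not as_list:
        return count
    kmers = sorted({canonical_kmer("".join(p)) for p in product(BASES, repeat=k)})
    assert len(kmers) == count
    return kmers


@dataclass
class KmerCensus:
    k: int
    counts: dict[str, int]
    total_positions: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["kmer", "count"],
        )
        df["rank"] = range(1, len(df) + 1)
        return df


def count_kmers(seqs: Iterable[str], k: int = 8) -> KmerCensus:
    """Canonical k-mer occurrence census over a collection of sequences.

    Every window position contributes exactly one count to its canonical
    k-mer, so palindromic windows are counted once; windows containing
    non-ACGT characters are skipped but still enter ``total_positions``.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        seq = seq.upper()
        n = len(seq) - k + 1
        if n <= 0:
            continue
        total += n
        for i in range(n):
            w = seq[i:i + k]
            if "N" in w:
                continue
            rc = revcomp(w)
            key = w if w <= rc else rc
            counts[key] = counts.get(key, 0) + 1
    return KmerCensus(k=k, counts=counts, total_positions=total)


def rank_kmer(census: KmerCensus, kmer: str) -> int:
    """1-based competition rank by descending count, lexicographic tie-break.

    A k-mer absent from the census ranks just after all present ones.
    """
    key = canonical_kmer(kmer)
    if key not in census.counts:
        return len(census.counts) + 1
    c = census.counts[key]
    rank = 1
    for other, n in census.counts.items():
        if n > c or (n == c and other < key):
            rank += 1
    return rank


def kmer_peak_fraction(peak_seqs: Sequence[str], kmer: str) -> float:
    """Fraction of peaks containing >=1 occurrence of the k-mer (either strand)."""
    if not peak_seqs:
        raise ValidationError("kmer_peak_fraction requires at least one peak")
    kmer = kmer.upper()
    rc = revcomp(kmer)
    hits = sum(1 for s in peak_seqs if kmer in s.upper() or rc in s.upper())
    return hits / len(peak_seqs)
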