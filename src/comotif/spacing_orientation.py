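"""Spacing and relative orientation of GBM/E-box pairs within peaks.

For every (PWM hit, E-box) pair with non-overlapping footprints
co-occurring within a window (default 100 bp edge-to-edge) one
:class:`MotifPair` is recorded. The gap is signed: positive when the E-box
starts after the GBM ends, negative when the E-box ends before the GBM
starts; pairs whose footprints overlap are excluded.
Because the E-box pattern CANNTG is its own reverse complement it carries
no strand, so orientation has two states (GBM+ / GBM-), not four.

The pair counts are tabulated on an (orientation x gap) grid; a
fixed-grammar composite site would concentrate mass in one cell, while a
flexible architecture spreads it thinly. Cell-level excess is tested
against a uniform multinomial null conditioned on the total pair count,
with Benjamini-Hochberg adjustment across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intervals_io import ValidationError
from .motifs import MotifHit, PWMatrix, find_ebox, scan_pwm

ORIENTATIONS = ("GBM+", "GBM-")
EBOX_LEN = 6


@dataclass(frozen=True)
class MotifPair:
    peak_id: str
    gbm_offset: int
    gbm_strand: str
    ebox_offset: int
    gap: int  # signed, edge-to-edge
    orientation: str  # 'GBM+' | 'GBM-'


@dataclass
class PairGrid:
    window: int
    counts: np.ndarray  # (2, 2*window + 1), rows follow ORIENTATIONS
    total: int

    @property
    def gaps(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    @property
    def fractions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for oi, orient in enumerate(ORIENTATIONS):
            for gi, gap in enumerate(self.gaps):
                rows.append(
                    {
                        "orientation": orient,
                        "gap": int(gap),
                        "count": int(self.counts[oi, gi]),
                        "fraction": float(self.fractions[oi, gi]),
                    }
                )
        return pd.DataFrame(rows)


def _signed_gap(gbm_start: int, gbm_end: int, ebox_start: int, ebox_end: int):
    """Edge-to-edge signed gap, or None when the footprints overlap.

    Overlapping footprints are not a composite-site spacing (the same bases
    cannot be bound by both factors at once; GBM and E-box words also share
    a CACC core, so permissive PWM hits routinely straddle E-boxes) and are
    excluded from pairing.
    """
    if ebox_start >= gbm_end:
        return ebox_start - gbm_end
    if ebox_end <= gbm_start:
        return ebox_end - gbm_start  # negative
    return None


def composite_sites(peak_seqs: dict[str, str], pwm: PWMatrix, threshold: float = 0.8,
                    window: int = 100) -> tuple[list[MotifPair], int]:
    """All GBM/E-box pairs with |gap| <= window, plus the peak-level tally.

    A peak may yield several pairs (every hit x every E-box within range);
    the second return value counts peaks contributing at least one pair.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    pairs: list[MotifPair] = []
    peaks_with_pair = 0
    for peak_id, seq in peak_seqs.items():
        gbm_hits = scan_pwm(seq, pwm, threshold, peak_id=peak_id)
        eboxes = find_ebox(seq)
        found = False
        for hit in gbm_hits:
            for ebox_off, _ in eboxes:
                gap = _signed_gap(hit.offset, hit.offset + len(pwm),
                                  ebox_off, ebox_off + EBOX_LEN)
                if gap is not None and abs(gap) <= window:
                    pairs.append(
                        MotifPair(
                            peak_id=peak_id,
                            gbm_offset=hit.offset,
                            gbm_strand=hit.strand,
                            ebox_offset=ebox_off,
                            gap=gap,
                            orientation="GBM+" if hit.strand == "+" else "GBM-",
                        )
                    )
                    found = True
        if found:
            peaks_with_pair += 1
    return pairs, peaks_with_pair


def spacing_grid(pairs: list[MotifPair], window: int = 100) -> PairGrid:
    """Exact tabulation of pairs on the (orientation, gap) grid."""
    counts = np.zeros((2, 2 * window + 1), dtype=np.int64)
    for p in pairs:
        if abs(p.gap) > window:
            raise ValidationError(f"pair gap {p.gap} outside window {window}")
        counts[ORIENTATIONS.index(p.orientation), p.gap + window] += 1
    return PairGrid(window=window, counts=counts, total=len(pairs))


def max_config_fraction(grid: PairGrid) -> tuple[str, int, float]:
    """The most frequent (orientation, gap) cell and its fraction.

    Ties are broken by orientation order (GBM+ first), then smaller |gap|,
    then the negative gap before the positive.
    """
    if grid.total == 0:
        raise ValidationError("empty grid")
    best = None
    for oi, orient in enumerate(ORIENTATIONS):
        for gi, gap in enumerate(grid.gaps):
            c = grid.counts[oi, gi]
            key = (-c, oi, abs(int(gap)), int(gap))
            if best is None or key < best[0]:
                best = (key, orient, int(gap), float(grid.fractions[oi, gi]))
    return best[1], best[2], best[3]


def config_enrichment_test(grid: PairGrid, n_perm: int = 1000, seed: int = 0
                           ) -> pd.DataFrame:
    """Per-cell upper-tail empirical p-values under a uniform multinomial null.

    Draws ``n_perm`` multinomials of the grid's total over all cells with
    equal probabilities; each cell's p is (1 + #{null count >= observed})
    / (1 + n_perm), adjusted across cells by Benjamini-Hochberg.
    """
    if grid.total < 1:
        raise ValidationError("grid total must be >= 1")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n_cells = grid.counts.size
    obs = grid.counts.ravel()
    null = rng.multinomial(grid.total, np.full(n_cells, 1.0 / n_cells), size=n_perm)
    exceed = (null >= obs[None, :]).sum(axis=0)
    p = (1 + exceed) / (1 + n_perm)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    df = grid.to_frame()
    df["p"] = p
    df["p_adj"] = p_adj
    return df
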