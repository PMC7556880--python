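"""Dual-luciferase normalization and the super-additivity (synergy) test.

Each well's firefly reading is normalized by its renilla control, and the
ratio scaled by the mean control ratio of its construct, so the control
condition has mean relative output 1. On that scale an additive model for
two co-transfected activators predicts

    E[AB] = A + B - 1

(the shared baseline is subtracted once). Synergy is a statistically
significant positive excess of the AB condition over this expectation.

The default test works on the raw-ratio scale, where the excess statistic

    D = mean(AB) - mean(A) - mean(B) + mean(control)

is a linear combination of independent condition means; its variance is the
sum of the four squared standard errors and the degrees of freedom follow
Welch-Satterthwaite. Dividing D by the mean control ratio gives the excess
on the relative scale without changing the t statistic, so the test is
invariant to rescaling all firefly readings of a construct. A stratified
bootstrap (resampling replicates within each condition) is available as an
alternative p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals_io import ValidationError

logger = logging.getLogger("comotif")

CONDITIONS = ("control", "A", "B", "AB")
REPORTER_COLUMNS = ["construct", "condition", "replicate", "firefly", "renilla"]

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def read_reporter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"construct": str, "condition": str})
    missing = set(REPORTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"reporter table missing columns: {sorted(missing)}")
    return df


def normalize_reporter(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well firefly/renilla ratio, scaled to the construct's control mean.

    Adds ``ratio`` and ``relative`` columns; requires a control condition
    per construct and strictly positive renilla readings.
    """
    if (table["renilla"] <= 0).any():
        raise ValidationError("renilla readings must be positive")
    out = table.copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    relatives = []
    for construct, sub in out.groupby("construct", sort=False):
        ctrl = sub.loc[sub["condition"] == "control", "ratio"]
        if ctrl.empty:
            raise ValidationError(f"construct {construct!r} lacks a control condition")
        relatives.append(sub["ratio"] / ctrl.mean())
    out["relative"] = pd.concat(relatives)
    return out


@dataclass
class SynergyStat:
    construct: str
    means: dict[str, float]  # relative mean per condition
    expected_additive: float  # mean(A) + mean(B) - 1
    excess: float  # mean(AB) - expected_additive
    t: float
    df: float
    p_synergy: float  # one-sided, excess > 0
    method: str
    pairwise: pd.DataFrame = field(repr=False, default=None)


def _condition_ratios(sub: pd.DataFrame) -> dict[str, np.ndarray]:
    groups = {}
    for cond in CONDITIONS:
        vals = sub.loc[sub["condition"] == cond, "ratio"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValidationError(f"condition {cond!r} needs >= 2 replicates")
        groups[cond] = vals
    return groups


def _welch_excess(groups: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """t, df, one-sided p for D = AB - A - B + control on the ratio scale."""
    means = {c: v.mean() for c, v in groups.items()}
    d = means["AB"] - means["A"] - means["B"] + means["control"]
    var_terms = {c: v.var(ddof=1) / len(v) for c, v in groups.items()}
    v = sum(var_terms.values())
    if v == 0:
        logger.warning("zero variance in all conditions; reporting boundary p")
        return (np.inf if d > 0 else -np.inf if d < 0 else 0.0), np.inf, (
            0.0 if d > 0 else 1.0
        )
    df = v ** 2 / sum(
        t ** 2 / (len(groups[c]) - 1) for c, t in var_terms.items()
    )
    t = d / np.sqrt(v)
    return float(t), float(df), float(stats.t.sf(t, df))


def synergy_test(normalized: pd.DataFrame, method: str = "delta",
                 n_boot: int = 10_000, seed: int = 0) -> list[SynergyStat]:
    """Per-construct test of super-additive activation.

    ``method='delta'`` uses the Welch-type statistic on condition means;
    ``method='bootstrap'`` resamples replicates within conditions (>= 10,000
    stratified resamples, seeded) and reports the fraction of resamples with
    non-positive excess as the one-sided p.
    """
    if method not in ("delta", "bootstrap"):
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    results = []
    for construct, sub in normalized.groupby("construct", sort=False):
        groups = _condition_ratios(sub)
        ctrl_mean = groups["control"].mean()
        rel_means = {c: v.mean() / ctrl_mean for c, v in groups.items()}
        expected = rel_means["A"] + rel_means["B"] - 1.0
        excess = rel_means["AB"] - expected
        t, df, p_delta = _welch_excess(groups)
        if method == "bootstrap":
            boot_d = np.zeros(n_boot)
            for c, sign in (("AB", 1.0), ("A", -1.0), ("B", -1.0), ("control", 1.0)):
                vals = groups[c]
                idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
                boot_d += sign * vals[idx].mean(axis=1)
            p = (1 + int((boot_d <= 0).sum())) / (1 + n_boot)
        else:
            p = p_delta
        results.append(
            SynergyStat(
                construct=construct,
                means=rel_means,
                expected_additive=float(expected),
                excess=float(excess),
                t=t,
                df=df,
                p_synergy=float(p),
                method=method,
                pairwise=condition_comparisons(sub),
            )
        )
    return results


def _tier(p: float) -> str:
    for cut, stars in SIGNIFICANCE_TIERS:
        if p < cut:
            return stars
    return "ns"


def condition_comparisons(normalized: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Welch tests: each condition vs control, AB vs A, AB vs B.

    Significance tiers use strict thresholds 0.05 / 0.01 / 0.001. A
    zero-variance degenerate pair is reported at the exact 0/1 boundary
    with a warning.
    """
    groups = _condition_ratios(normalized)
    pairs = [("A", "control"), ("B", "control"), ("AB", "control"), ("AB", "A"), ("AB", "B")]
    rows = []
    for x, y in pairs:
        gx, gy = groups[x], groups[y]
        if gx.var(ddof=1) == 0 and gy.var(ddof=1) == 0:
            p = 1.0 if gx.mean() == gy.mean() else 0.0
            logger.warning("zero-variance comparison %s vs %s; boundary p=%g", x, y, p)
        else:
            p = float(stats.ttest_ind(gx, gy, equal_var=False).pvalue)
        rows.append({"group1": x, "group2": y, "p": p, "tier": _tier(p)})
    return pd.DataFrame(rows)
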