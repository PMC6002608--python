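"""Quadrant gating of two-channel phagocytosis assays and assay statistics.

Events carry two intensities: a pH-insensitive bead dye (YG) reporting
cargo uptake, and a pH-sensitive dye (pHrodo) whose signal rises as the
phagosome acidifies. Quadrants map to biology as: double-negative =
PhagoNeg (no cargo); YG-positive only = PhagoEarly (cargo bound or
internalized, not acidified); double-positive = PhagoLate (internalized
and acidified). The YG-negative / pHrodo-positive quadrant has no uptake
marker, so those events are counted as PhagoNeg and reported separately
as a diagnostic.

Statistics used on the gated fractions elsewhere in the pipeline —
Welch's unequal-variance t test with 95% confidence intervals and the
Wilcoxon-Mann-Whitney test — live here too, together with the
gentamicin-protection survival percentage.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateThresholds",
    "GateFractions",
    "GatingError",
    "fit_thresholds",
    "classify_events",
    "quadrant_counts",
    "gate_fractions",
    "WelchResult",
    "welch_t_test",
    "mann_whitney_test",
    "survival_percentage",
]

LABELS = ("PhagoNeg", "PhagoEarly", "PhagoLate")


class GatingError(ValueError):
    """Raised on invalid events or thresholds."""


@dataclasses.dataclass(frozen=True)
class GateThresholds:
    yg_cut: float
    phrodo_cut: float

    def __post_init__(self) -> None:
        if not (self.yg_cut > 0 and self.phrodo_cut > 0):
            raise GatingError("gate thresholds must be positive")


@dataclasses.dataclass(frozen=True)
class GateFractions:
    phago_neg: float
    phago_early: float
    phago_late: float
    n_events: int

    def __post_init__(self) -> None:
        total = self.phago_neg + self.phago_early + self.phago_late
        if abs(total - 1.0) > 1e-12:
            raise GatingError(f"fractions must sum to 1, got {total}")


def _event_arrays(events) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(events, pd.DataFrame):
        yg = events["yg"].to_numpy(dtype=float)
        phrodo = events["phrodo"].to_numpy(dtype=float)
    else:
        arr = np.asarray(events, dtype=float)
        yg, phrodo = arr[:, 0], arr[:, 1]
    if not (np.isfinite(yg).all() and np.isfinite(phrodo).all()):
        raise GatingError("intensities must be finite")
    if (yg <= 0).any() or (phrodo <= 0).any():
        raise GatingError("intensities must be positive")
    return yg, phrodo


def fit_thresholds(control_events, quantile: float = 0.995) -> GateThresholds:
    """Per-channel cuts at the given quantile of a negative-control
    population (a reproducible surrogate for manual gate placement)."""
    yg, phrodo = _event_arrays(control_events)
    if yg.size < 100:
        raise GatingError(f"need >= 100 control events to place gates, got {yg.size}")
    if not 0.0 < quantile < 1.0:
        raise GatingError("quantile must be in (0, 1)")
    return GateThresholds(
        yg_cut=float(np.quantile(yg, quantile)),
        phrodo_cut=float(np.quantile(phrodo, quantile)),
    )


def classify_events(events, thresholds: GateThresholds) -> np.ndarray:
    """Quadrant labels per event: YG <= cut -> PhagoNeg; YG > cut with
    pHrodo <= cut -> PhagoEarly; both above -> PhagoLate."""
    yg, phrodo = _event_arrays(events)
    labels = np.where(
        yg <= thresholds.yg_cut,
        "PhagoNeg",
        np.where(phrodo <= thresholds.phrodo_cut, "PhagoEarly", "PhagoLate"),
    )
    return labels


def quadrant_counts(events, thresholds: GateThresholds) -> dict[str, int]:
    """Raw quadrant occupancy, including the anomalous YG-/pHrodo+ corner
    (folded into PhagoNeg by :func:`classify_events`)."""
    yg, phrodo = _event_arrays(events)
    yg_pos = yg > thresholds.yg_cut
    ph_pos = phrodo > thresholds.phrodo_cut
    return {
        "PhagoNeg": int((~yg_pos & ~ph_pos).sum()),
        "PhagoEarly": int((yg_pos & ~ph_pos).sum()),
        "PhagoLate": int((yg_pos & ph_pos).sum()),
        "yg_neg_phrodo_pos": int((~yg_pos & ph_pos).sum()),
    }


def gate_fractions(labels: Sequence[str]) -> GateFractions:
    """Empirical population fractions from per-event labels."""
    labels = np.asarray(labels)
    n = labels.size
    if n == 0:
        raise GatingError("no events to summarize")
    bad = set(np.unique(labels)) - set(LABELS)
    if bad:
        raise GatingError(f"unknown label(s): {sorted(bad)}")
    return GateFractions(
        phago_neg=float((labels == "PhagoNeg").sum() / n),
        phago_early=float((labels == "PhagoEarly").sum() / n),
        phago_late=float((labels == "PhagoLate").sum() / n),
        n_events=int(n),
    )


@dataclasses.dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    mean_diff: float
    ci_low: float
    ci_high: float
    degenerate: bool = False  # zero variance in both groups


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite degrees of
    freedom and a 95% confidence interval on the mean difference.

    Degenerate inputs (zero variance in both groups) give p = 1 for equal
    means and p = 0 (flagged) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GatingError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if va == 0.0 and vb == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        t = 0.0 if diff == 0.0 else np.copysign(np.inf, diff)
        return WelchResult(t, float(a.size + b.size - 2), p, diff, diff, diff, True)
    sa, sb = va / a.size, vb / b.size
    se = np.sqrt(sa + sb)
    t = diff / se
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * se
    return WelchResult(float(t), float(df), float(p), diff, diff - half, diff + half)


def mann_whitney_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney U (for group A) and two-sided p-value.

    Exact distribution when the combined sample is <= 12 without ties,
    tie-corrected normal approximation otherwise. All values identical
    gives p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise GatingError("each group needs >= 3 values")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def survival_percentage(cfu_t: float, cfu_0: float) -> float:
    """Surviving intracellular bacteria at time t as a percentage of time
    zero; may exceed 100 when bacteria replicate intracellularly."""
    if cfu_0 <= 0:
        raise GatingError("cfu at time zero must be positive")
    if cfu_t < 0:
        raise GatingError("cfu must be non-negative")
    return 100.0 * cfu_t / cfu_0
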