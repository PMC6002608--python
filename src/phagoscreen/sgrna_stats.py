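"""Per-sgRNA differential abundance between sorted populations.

First step of the two-step screen analysis: a negative-binomial Wald test
on guide counts between the PhagoLate and PhagoNeg gates, with
median-of-ratios normalization, method-of-moments dispersion estimation
shrunk toward a 1/mu + const trend, and Benjamini-Hochberg adjustment.

The model family follows standard RNA-seq count testing (NB with
Var = mu + alpha * mu^2, Wald z on the log2 fold change), deliberately
simplified to a closed-form two-group fit: group means of normalized
counts instead of an IRLS GLM, log-space shrinkage toward a fitted
mean-dispersion trend instead of an empirical-Bayes prior, no LFC
shrinkage, no outlier handling. Exact numerical parity with DESeq2-class
tools is not a goal; the inferential structure is the same.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .read_counting import CountMatrix

__all__ = [
    "DispersionModel",
    "StatsError",
    "size_factors",
    "estimate_dispersions",
    "wald_test",
    "bh_adjust",
    "sgrna_stats",
    "DISPERSION_FLOOR",
]

DISPERSION_FLOOR = 1e-8


class StatsError(ValueError):
    """Raised on inputs the count model cannot handle."""


def _counts_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(
    counts: CountMatrix | pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors.

    The reference profile is the per-guide geometric mean across samples
    (guides with a zero in any sample are excluded); each sample's factor
    is the median of its counts over the reference. With
    ``pseudo_reference=True`` the geometric mean is computed on counts + 0.5
    over all guides instead, for matrices where no guide is nonzero
    everywhere.
    """
    K = _counts_frame(counts).to_numpy(dtype=float)
    if pseudo_reference:
        logk = np.log(K + 0.5)
        logref = logk.mean(axis=1)
        usable = np.ones(K.shape[0], dtype=bool)
    else:
        usable = (K > 0).all(axis=1)
        if not usable.any():
            raise StatsError(
                "no guide has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to use a pseudo-count reference"
            )
        logk = np.where(K > 0, np.log(np.where(K > 0, K, 1.0)), np.nan)
        logref = logk[usable].mean(axis=1)
    ratios = np.exp(logk[usable] - logref[:, None])
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=_counts_frame(counts).columns, name="size_factor")


@dataclasses.dataclass
class DispersionModel:
    """Raw, trend, and final (shrunk) NB dispersions per guide."""

    alpha_raw: pd.Series
    trend_a0: float  # asymptotic dispersion
    trend_a1: float  # 1/mu coefficient
    alpha_trend: pd.Series
    alpha_final: pd.Series
    base_mean: pd.Series

    def trend(self, mu: np.ndarray) -> np.ndarray:
        mu = np.clip(np.asarray(mu, float), 1e-12, None)
        return np.maximum(self.trend_a1 / mu + self.trend_a0, DISPERSION_FLOOR)


def _group_arrays(
    counts: CountMatrix | pd.DataFrame,
    design: pd.Series | None,
    contrast: tuple[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized-count column masks for the two populations."""
    frame = _counts_frame(counts)
    if design is None:
        if not isinstance(counts, CountMatrix):
            raise StatsError("a design series is required for a bare DataFrame")
        design = counts.sample_meta["population"]
    design = design.loc[frame.columns]
    if contrast is None:
        levels = [l for l in pd.unique(design) if l != "Initial"]
        if len(levels) != 2:
            raise StatsError(f"expected exactly two populations, got {list(levels)}")
        contrast = (str(levels[0]), str(levels[1]))
    a = (design == contrast[0]).to_numpy()
    b = (design == contrast[1]).to_numpy()
    if a.sum() < 2 or b.sum() < 2:
        raise StatsError(
            f"need >= 2 replicates per population to estimate dispersion; got "
            f"{contrast[0]}: {int(a.sum())}, {contrast[1]}: {int(b.sum())}"
        )
    return frame.to_numpy(dtype=float), a, b


def estimate_dispersions(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    design: pd.Series | None = None,
    contrast: tuple[str, str] | None = None,
    shrinkage_weight: float = 1.0,
) -> DispersionModel:
    """Method-of-moments NB dispersions with trend shrinkage.

    Per guide, the raw dispersion is max(0, (pooled within-group variance
    - mean) / mean^2) on size-factor-normalized counts. A trend
    alpha(mu) = a1/mu + a0 is fitted over guides with positive raw
    dispersion (least squares with one round of gross-outlier trimming),
    and the final dispersion is a log-space weighted average of the raw
    value and the trend (``shrinkage_weight`` toward the trend), floored
    at 1e-8.

    The default weight of 1.0 uses the trend alone for testing: with two
    or three replicates per gate a per-guide dispersion carries only a few
    degrees of freedom, and mixing it in understates the standard error of
    guides whose raw estimate is low by chance, inflating the type-I
    error. The raw values remain available for diagnostics.
    """
    K, a, b = _group_arrays(counts, design, contrast)
    frame = _counts_frame(counts)
    Q = K / factors.loc[frame.columns].to_numpy()[None, :]

    means, variances, dofs = [], [], []
    for mask in (a, b):
        g = Q[:, mask]
        means.append(g.mean(axis=1))
        variances.append(g.var(axis=1, ddof=1))
        dofs.append(mask.sum() - 1)
    mu = np.mean(means, axis=0)  # mean of group means
    var_w = (dofs[0] * variances[0] + dofs[1] * variances[1]) / (dofs[0] + dofs[1])

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, (var_w - mu) / mu**2, 0.0)
    alpha_raw = np.maximum(alpha_raw, 0.0)

    pos = (alpha_raw > 0) & (mu > 0)
    a0, a1 = _fit_trend(mu[pos], alpha_raw[pos])
    alpha_trend = np.maximum(a1 / np.clip(mu, 1e-12, None) + a0, DISPERSION_FLOOR)

    w = shrinkage_weight
    log_final = (1.0 - w) * np.log(np.maximum(alpha_raw, DISPERSION_FLOOR)) + w * np.log(
        alpha_trend
    )
    alpha_final = np.maximum(np.exp(log_final), DISPERSION_FLOOR)

    idx = frame.index
    return DispersionModel(
        alpha_raw=pd.Series(alpha_raw, index=idx, name="alpha_raw"),
        trend_a0=float(a0),
        trend_a1=float(a1),
        alpha_trend=pd.Series(alpha_trend, index=idx, name="alpha_trend"),
        alpha_final=pd.Series(alpha_final, index=idx, name="alpha_final"),
        base_mean=pd.Series(Q.mean(axis=1), index=idx, name="base_mean"),
    )


def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a1/mu + a0, coefficients clipped at 0.

    Least squares targets the mean of the raw dispersions (the quantity
    the NB variance model needs); one trimming round discards gross
    outliers (> 10x the first fit) so single aberrant guides cannot drag
    the trend. A median-targeting robust loss would sit below the mean of
    the right-skewed raw-dispersion distribution and understate the trend.
    """
    if mu.size < 10:
        med = float(np.median(alpha)) if alpha.size else DISPERSION_FLOOR
        return max(med, DISPERSION_FLOOR), 0.0
    X = sm.add_constant(1.0 / mu)
    beta = np.linalg.lstsq(X, alpha, rcond=None)[0]
    keep = alpha < 10.0 * np.maximum(X @ beta, DISPERSION_FLOOR)
    if keep.sum() >= 10:
        beta = np.linalg.lstsq(X[keep], alpha[keep], rcond=None)[0]
    return max(float(beta[0]), 0.0), max(float(beta[1]), 0.0)


def wald_test(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    dispersions: DispersionModel,
    contrast: tuple[str, str] = ("PhagoLate", "PhagoNeg"),
    design: pd.Series | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """NB Wald test of each guide between the two populations.

    Group means of normalized counts give LFC = log2(mu_A / mu_B), with the
    pseudo-count applied only to zero group means so nonzero cases are
    unbiased. The standard error comes from the NB information,
    SE = sqrt(sum_g (1/mu_g + alpha) / n_g) / ln 2, and the two-sided
    p-value from the standard normal on z = LFC / SE.

    Guides with zero counts everywhere get an undefined (NaN) result and
    are flagged; they are excluded from ranking downstream.
    """
    K, a, b = _group_arrays(counts, design, contrast)
    frame = _counts_frame(counts)
    Q = K / factors.loc[frame.columns].to_numpy()[None, :]
    alpha = dispersions.alpha_final.loc[frame.index].to_numpy()

    mu_a = Q[:, a].mean(axis=1)
    mu_b = Q[:, b].mean(axis=1)
    undefined = (mu_a == 0) & (mu_b == 0)
    mu_a_adj = np.where(mu_a == 0, pseudo_count, mu_a)
    mu_b_adj = np.where(mu_b == 0, pseudo_count, mu_b)

    lfc = np.log2(mu_a_adj / mu_b_adj)
    var_log = (1.0 / mu_a_adj + alpha) / a.sum() + (1.0 / mu_b_adj + alpha) / b.sum()
    se = np.sqrt(var_log) / np.log(2.0)
    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame(
        {
            "gene": _genes_for(counts, frame.index),
            "base_mean": Q.mean(axis=1),
            "log2_fold_change": lfc,
            "standard_error": se,
            "wald_z": z,
            "p_value": p,
            "undefined": undefined,
        },
        index=frame.index,
    )
    out.loc[undefined, ["log2_fold_change", "standard_error", "wald_z", "p_value"]] = np.nan
    defined = ~undefined
    p_adj = np.full(len(out), np.nan)
    p_adj[defined] = bh_adjust(out.loc[defined, "p_value"].to_numpy())
    out["p_adj"] = p_adj
    return out


def _genes_for(counts, idx: pd.Index) -> pd.Series | str:
    gene_map = getattr(counts, "gene_map", None)
    if gene_map is not None:
        return pd.Series(gene_map, index=idx)
    return ""


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{k >= i} p_(k) * m / k over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def sgrna_stats(
    counts: CountMatrix,
    contrast: tuple[str, str] = ("PhagoLate", "PhagoNeg"),
    index=None,
    shrinkage_weight: float = 1.0,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Convenience wrapper: size factors -> dispersions -> Wald test.

    If a :class:`~phagoscreen.library_index.LibraryIndex` is given, the
    output carries each guide's gene symbol (needed for aggregation).
    """
    s = size_factors(counts, pseudo_reference=pseudo_reference)
    disp = estimate_dispersions(counts, s, contrast=contrast, shrinkage_weight=shrinkage_weight)
    res = wald_test(counts, s, disp, contrast=contrast)
    if index is not None:
        res["gene"] = [index.record(i).gene for i in res.index]
        res["category"] = [index.record(i).category for i in res.index]
    return res
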