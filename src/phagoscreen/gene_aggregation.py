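"""Aggregation of guide-level statistics to genes.

Second step of the two-step screen analysis: guides are ranked by a signed
significance metric, each gene's guides are located in the ranked list
with a weighted Kolmogorov-Smirnov running sum (the classic gene-set
enrichment statistic), and significance comes from a permutation null of
random same-size guide sets. Depletion from the PhagoLate gate shows up as
a negative enrichment score with the gene's guides concentrated at the
bottom of the list.

Non-targeting guides carry no gene identity: they take part in ranking
(they inform the null ordering) but never form a gene set.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .library_index import LibraryIndex
from .sgrna_stats import bh_adjust

__all__ = [
    "RankedList",
    "AggregationError",
    "rank_sgrnas",
    "enrichment_score",
    "permutation_pvalue",
    "aggregate_genes",
    "volcano_table_columns",
]

#: guards log10 of exact-zero adjusted p-values
_EPS = 1e-300

volcano_table_columns = (
    "gene", "n_sgrnas", "mean_lfc", "es", "p_perm", "p_adj", "n_sig_sgrnas", "direction",
)


class AggregationError(ValueError):
    """Raised on invalid ranked lists or gene sets."""


@dataclasses.dataclass
class RankedList:
    """Guides ordered by a signed ranking metric (descending)."""

    sgrna_ids: list[str]
    metric: np.ndarray  # signed, aligned with sgrna_ids

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.sgrna_ids) != self.metric.size:
            raise AggregationError("ids and metric lengths differ")
        self._pos = {sid: i for i, sid in enumerate(self.sgrna_ids)}

    def __len__(self) -> int:
        return len(self.sgrna_ids)

    def positions(self, member_ids) -> np.ndarray:
        try:
            return np.sort([self._pos[m] for m in member_ids])
        except KeyError as exc:
            raise AggregationError(f"member {exc.args[0]!r} not in ranked list") from exc


def rank_sgrnas(stats: pd.DataFrame, metric: str = "signed") -> RankedList:
    """Rank guides by sign(LFC) x -log10(p_adj) (descending).

    ``metric='padj_only'`` uses the unsigned -log10(p_adj) instead. Guides
    with undefined statistics (all-zero counts) are excluded. Ties are
    broken by |LFC| descending, then sgrna_id lexicographically, so the
    order is deterministic.
    """
    if stats.empty:
        raise AggregationError("no guide statistics to rank")
    df = stats.loc[stats["p_adj"].notna() & stats["log2_fold_change"].notna()].copy()
    if df.empty:
        raise AggregationError("all guide statistics are undefined")
    neglog = -np.log10(df["p_adj"].to_numpy() + _EPS)
    if metric == "signed":
        r = np.sign(df["log2_fold_change"].to_numpy()) * neglog
    elif metric == "padj_only":
        r = neglog
    else:
        raise AggregationError(f"unknown ranking metric {metric!r}")
    df = df.assign(_r=r, _abs_lfc=df["log2_fold_change"].abs(), _id=df.index)
    df = df.sort_values(
        ["_r", "_abs_lfc", "_id"], ascending=[False, False, True], kind="mergesort"
    )
    return RankedList(sgrna_ids=list(df.index), metric=df["_r"].to_numpy())


def _es_from_positions(
    absr_q: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Enrichment scores for one or many sorted member-position sets.

    ``positions`` is (m,) or (P, m) of sorted 0-based ranks. The running
    sum increments by the normalized |r|^q weight at each hit and
    decrements by 1/(N-m) at each miss; extrema only occur immediately
    after a hit (maxima) or immediately before one or at the very end
    (minima), so the extremum over all N positions is computed from the m
    hit positions alone.
    """
    pos = np.atleast_2d(positions)
    m = pos.shape[1]
    w = absr_q[pos]
    denom = w.sum(axis=1, keepdims=True)
    w = np.where(denom > 0, w / np.where(denom > 0, denom, 1.0), 1.0 / m)
    miss = 1.0 / (n - m)
    j = np.arange(m)[None, :]
    after = np.cumsum(w, axis=1) - (pos - j) * miss
    before = after - w
    mx = np.maximum(after.max(axis=1), 0.0)
    mn = np.minimum(before.min(axis=1), 0.0)
    es = np.where(np.abs(mx) >= np.abs(mn), mx, mn)
    return es if positions.ndim == 2 else es[0]


def enrichment_score(
    ranked: RankedList, member_ids, weight_exponent: float = 1.0
) -> float:
    """Weighted KS enrichment score of a guide set within the ranked list.

    Hits increment the running sum by |r_i|^q normalized over the set
    (uniform if all member metrics are zero); misses decrement by
    1/(N - m). The score is the extremum of the running sum: +1 when all
    members sit at the very top, -1 at the very bottom.
    """
    if weight_exponent < 0:
        raise AggregationError("weight_exponent must be >= 0")
    member_ids = list(member_ids)
    n = len(ranked)
    if not member_ids:
        raise AggregationError("member set is empty")
    if len(set(member_ids)) >= n:
        raise AggregationError("member set must be a proper subset of the ranked list")
    pos = ranked.positions(member_ids)
    absr_q = np.abs(ranked.metric) ** weight_exponent
    return float(_es_from_positions(absr_q, pos, n))


def _null_es(
    ranked: RankedList,
    set_size: int,
    weight_exponent: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null enrichment scores of uniformly drawn same-size guide sets."""
    n = len(ranked)
    absr_q = np.abs(ranked.metric) ** weight_exponent
    draws = rng.integers(0, n, size=(n_perm, set_size))
    # reject rows with repeated positions (sampling without replacement)
    bad = np.flatnonzero((np.sort(draws, axis=1)[:, 1:] == np.sort(draws, axis=1)[:, :-1]).any(axis=1))
    while bad.size:
        draws[bad] = rng.integers(0, n, size=(bad.size, set_size))
        srt = np.sort(draws[bad], axis=1)
        bad = bad[(srt[:, 1:] == srt[:, :-1]).any(axis=1)]
    return _es_from_positions(absr_q, np.sort(draws, axis=1), n)


def _perm_p(es_obs: float, null: np.ndarray) -> float:
    """Sign-matched permutation p-value with the +1 continuity floor."""
    if es_obs == 0.0:
        return 1.0
    match = np.sign(null) == np.sign(es_obs)
    hits = int(np.sum(match & (np.abs(null) >= abs(es_obs))))
    return (1 + hits) / (1 + int(match.sum()))


def permutation_pvalue(
    ranked: RankedList,
    member_ids,
    weight_exponent: float = 1.0,
    n_perm: int = 20_000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Permutation p-value of the set's enrichment score.

    The null is the enrichment score of ``n_perm`` uniformly drawn guide
    sets of the same size; the p-value compares |ES| within the nulls of
    matching sign, with a +1 floor so it is never exactly zero.
    Deterministic for a given seed.
    """
    if n_perm < 100:
        raise AggregationError("n_perm must be >= 100")
    es_obs = enrichment_score(ranked, member_ids, weight_exponent)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked, len(set(member_ids)), weight_exponent, n_perm, rng)
    p = _perm_p(es_obs, null)
    summary = {
        "es_obs": es_obs,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std()),
        "n_perm": n_perm,
    }
    return p, summary


def aggregate_genes(
    stats: pd.DataFrame,
    index: LibraryIndex,
    weight_exponent: float = 1.0,
    n_perm: int = 20_000,
    seed: int = 0,
    sig_threshold: float = 0.05,
    metric: str = "signed",
) -> pd.DataFrame:
    """Build the per-gene volcano table from guide-level statistics.

    For every SLC and essential-control gene: mean LFC over its guides,
    enrichment score, permutation p-value, BH-adjusted p-value, and the
    number of its guides individually significant at ``sig_threshold``
    (the volcano dot size). Non-targeting guides are never aggregated.
    Null distributions are shared across genes of the same set size, so a
    fixed seed gives a fully deterministic table.
    """
    ranked = rank_sgrnas(stats, metric=metric)
    rng = np.random.default_rng(seed)
    in_list = set(ranked.sgrna_ids)
    absr_q = np.abs(ranked.metric) ** weight_exponent
    n = len(ranked)

    genes = index.genes("SLC") + index.genes("EssentialControl")
    members_of: dict[str, list[str]] = {}
    for gene in genes:
        members = [r.sgrna_id for r in index.sgrnas_for_gene(gene) if r.sgrna_id in in_list]
        if not members:
            warnings.warn(f"gene {gene!r} has no ranked guides and was dropped")
            continue
        members_of[gene] = members

    null_by_size = {
        size: _null_es(ranked, size, weight_exponent, n_perm, rng)
        for size in sorted({len(m) for m in members_of.values()})
    }

    rows = []
    for gene, members in members_of.items():
        pos = ranked.positions(members)
        es = float(_es_from_positions(absr_q, pos, n))
        p_perm = _perm_p(es, null_by_size[len(members)])
        sub = stats.loc[members]
        rows.append(
            {
                "gene": gene,
                "n_sgrnas": len(members),
                "mean_lfc": float(sub["log2_fold_change"].mean()),
                "es": es,
                "p_perm": p_perm,
                "n_sig_sgrnas": int((sub["p_adj"] < sig_threshold).sum()),
                "direction": "depleted" if es < 0 else "enriched",
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_perm"].to_numpy())
    out = out[list(volcano_table_columns)]
    return out.sort_values(["p_adj", "p_perm", "gene"], kind="mergesort").reset_index(drop=True)


def volcano_plot(gene_results: pd.DataFrame, path=None, ax=None):
    """Volcano plot: mean LFC vs -log10 adjusted p, dot size = number of
    individually significant guides."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    y = -np.log10(gene_results["p_adj"].to_numpy() + _EPS)
    sizes = 10 + 25 * gene_results["n_sig_sgrnas"].to_numpy()
    ax.scatter(gene_results["mean_lfc"], y, s=sizes, alpha=0.6, edgecolor="none")
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, color="grey")
    ax.set_xlabel("mean LFC (PhagoLate vs PhagoNeg)")
    ax.set_ylabel(r"$-\log_{10}(p_{adj})$")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
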