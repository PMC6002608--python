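import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagoscreen.sgrna_stats import (
    StatsError,
    bh_adjust,
    estimate_dispersions,
    sgrna_stats,
    size_factors,
    wald_test,
)

from .conftest import make_count_matrix


def brute_force_size_factors(K):
    """Independent median-of-ratios oracle: explicit loops, no vectorization."""
    import math

    n, m = K.shape
    usable = [i for i in range(n) if all(K[i, j] > 0 for j in range(m))]
    refs = {i: math.exp(sum(math.log(K[i, j]) for j in range(m)) / m) for i in usable}
    out = []
    for j in range(m):
        ratios = sorted(K[i, j] / refs[i] for i in usable)
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else (ratios[k // 2 - 1] + ratios[k // 2]) / 2
        out.append(med)
    return np.array(out)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_count_matrix(np.tile([[10], [20], [30]], (1, 4)))
        assert size_factors(cm).to_numpy() == pytest.approx(np.ones(4))

    def test_doubled_column_splits_symmetrically(self):
        a = np.array([[10, 20], [50, 100], [7, 14]])
        cm = make_count_matrix(a)
        s = size_factors(cm).to_numpy()
        assert s == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        K = rng.integers(1, 2000, size=(200, 6))
        cm = make_count_matrix(K)
        assert size_factors(cm).to_numpy() == pytest.approx(
            brute_force_size_factors(K), rel=1e-12
        )

    def test_no_all_nonzero_row_advises_fallback(self):
        K = np.array([[0, 5, 5, 5], [5, 0, 5, 5], [5, 5, 0, 5]])
        cm = make_count_matrix(K)
        with pytest.raises(StatsError, match="pseudo_reference"):
            size_factors(cm)
        s = size_factors(cm, pseudo_reference=True)
        assert (s > 0).all()


class TestDispersions:
    def test_constant_counts_have_zero_raw_dispersion(self):
        cm = make_count_matrix(np.full((50, 6), 500))
        d = estimate_dispersions(cm, size_factors(cm))
        assert (d.alpha_raw == 0).all()

    def test_poisson_counts_yield_near_zero_final_dispersion(self):
        rng = np.random.default_rng(3)
        cm = make_count_matrix(rng.poisson(500, size=(5000, 6)))
        d = estimate_dispersions(cm, size_factors(cm))
        assert d.alpha_final.median() <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        lam = rng.gamma(1 / 0.1, 0.1 * 500, size=(5000, 6))
        cm = make_count_matrix(rng.poisson(lam))
        d = estimate_dispersions(cm, size_factors(cm))
        assert 0.05 <= d.alpha_final.median() <= 0.2

    def test_single_replicate_per_group_rejected(self):
        cm = make_count_matrix(np.array([[5, 6], [7, 8]]))
        with pytest.raises(StatsError, match="2 replicates"):
            estimate_dispersions(cm, size_factors(cm))


class TestWaldTest:
    def _fit(self, cm):
        s = size_factors(cm)
        d = estimate_dispersions(cm, s)
        return wald_test(cm, s, d)

    def test_identical_groups_give_null_result(self):
        block = np.array([[100, 110, 90], [40, 50, 60]])
        cm = make_count_matrix(np.hstack([block, block]))
        res = self._fit(cm)
        assert res["log2_fold_change"].to_numpy() == pytest.approx(0.0)
        assert res["wald_z"].to_numpy() == pytest.approx(0.0)
        assert res["p_value"].to_numpy() == pytest.approx(1.0)

    def test_planted_fourfold_depletion_recovered(self):
        """A true 4x depletion planted in a small guide subset is estimated
        near LFC -2 on average over seeds."""
        rng = np.random.default_rng(5)
        est = []
        for _ in range(20):
            mean_late = np.full(400, 500.0)
            mean_late[:20] = 125.0  # the planted 4x depletion
            late = rng.poisson(np.tile(mean_late[:, None], 3))
            neg = rng.poisson(500.0, size=(400, 3))
            cm = make_count_matrix(np.hstack([late, neg]))
            s = size_factors(cm)
            d = estimate_dispersions(cm, s)
            res = wald_test(cm, s, d)
            est.append(res["log2_fold_change"].iloc[:20].mean())
        assert np.mean(est) == pytest.approx(-2.0, abs=0.3)

    def test_all_zero_guide_flagged_and_excluded(self):
        K = np.array([[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]])
        cm = make_count_matrix(K)
        s = size_factors(cm, pseudo_reference=True)
        d = estimate_dispersions(cm, s)
        res = wald_test(cm, s, d)
        assert bool(res["undefined"].iloc[0])
        assert np.isnan(res["p_value"].iloc[0])
        assert not res["undefined"].iloc[1]

    def test_normalization_invariance_under_global_scaling(self):
        """Rescaling every column by c (a sequencing-depth change) is
        absorbed by the row reference: size factors and fold changes are
        exactly unchanged, and p-values move only through the Poisson
        1/mu term of the standard error (vanishing at high depth)."""
        rng = np.random.default_rng(6)
        K = rng.poisson(300, size=(400, 6))
        cm1 = make_count_matrix(K)
        cm2 = make_count_matrix(K * 3)
        r1, r2 = self._fit(cm1), self._fit(cm2)
        s1, s2 = size_factors(cm1), size_factors(cm2)
        assert (s2 / s1).to_numpy() == pytest.approx(np.ones(6), rel=1e-9)
        assert r2["log2_fold_change"].to_numpy() == pytest.approx(
            r1["log2_fold_change"].to_numpy(), rel=1e-9, abs=1e-12
        )
        assert np.abs(r2["p_value"] - r1["p_value"]).max() < 0.05

    def test_single_column_scaling_cancels_in_lfc(self):
        """Scaling one column is absorbed by its size factor up to the
        row-reference renormalization, which rescales all normalized counts
        by a common constant: fold changes are unaffected."""
        rng = np.random.default_rng(6)
        K = rng.poisson(300, size=(400, 6))
        K2 = K.copy()
        K2[:, 0] *= 3
        cm1, cm2 = make_count_matrix(K), make_count_matrix(K2)
        r1, r2 = self._fit(cm1), self._fit(cm2)
        s1, s2 = size_factors(cm1), size_factors(cm2)
        # the scaled column's factor carries the scale modulo the common
        # reference shift 3**(1/6) shared by every sample
        shift = 3 ** (1 / 6)
        assert s2.iloc[0] / s1.iloc[0] == pytest.approx(3.0 / shift, rel=1e-9)
        assert (s2.iloc[1:] / s1.iloc[1:]).to_numpy() == pytest.approx(
            np.full(5, 1 / shift), rel=1e-9
        )
        assert r2["log2_fold_change"].to_numpy() == pytest.approx(
            r1["log2_fold_change"].to_numpy(), rel=1e-9, abs=1e-12
        )

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(7)
        cm = make_count_matrix(rng.poisson(200, size=(300, 6)))
        s = size_factors(cm)
        d = estimate_dispersions(cm, s)
        fwd = wald_test(cm, s, d, contrast=("PhagoLate", "PhagoNeg"))
        rev = wald_test(cm, s, d, contrast=("PhagoNeg", "PhagoLate"))
        assert rev["log2_fold_change"].to_numpy() == pytest.approx(
            -fwd["log2_fold_change"].to_numpy()
        )
        assert rev["wald_z"].to_numpy() == pytest.approx(-fwd["wald_z"].to_numpy())
        assert rev["p_value"].to_numpy() == pytest.approx(fwd["p_value"].to_numpy())


def brute_force_bh(p):
    """Independent double-loop BH oracle."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank, i in enumerate(order, start=1):
        best = min(
            p[order[r - 1]] * m / r for r in range(rank, m + 1)
        )
        q[i] = min(best, 1.0)
    return q


class TestBhAdjust:
    def test_monotone_chain_collapses(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=1000)
        assert bh_adjust(p) == pytest.approx(brute_force_bh(list(p)), rel=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(StatsError):
            bh_adjust([0.5, -0.1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    def test_adjustment_preserves_p_order(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


def test_agrees_with_reference_nb_implementation():
    """Cross-check against an independent NB differential-abundance tool
    (pyDESeq2): for a two-group design the GLM maximum-likelihood fold
    change is the dispersion-weighted analogue of the group mean of
    normalized counts, so LFCs must agree closely; significance calls on a
    clear planted effect must coincide."""
    import warnings

    rng = np.random.default_rng(13)
    mean = np.full(300, 400.0)
    mean[:10] = 100.0  # planted 4x depletion in PhagoLate
    late = rng.poisson(np.tile(mean[:, None], 3))
    neg = rng.poisson(400.0, size=(300, 3))
    cm = make_count_matrix(np.hstack([late, neg]))
    ours = sgrna_stats(cm)

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = cm.sample_meta.rename(columns={"population": "condition"})[["condition"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=cm.counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "PhagoLate", "PhagoNeg"],
                        quiet=True)
        ds.summary()
    ref = ds.results_df
    assert ours["log2_fold_change"].to_numpy() == pytest.approx(
        ref["log2FoldChange"].to_numpy(), abs=0.01
    )
    ours_sig = set(ours.index[ours["p_adj"] < 0.05])
    ref_sig = set(ref.index[ref["padj"] < 0.05])
    assert ours_sig == ref_sig == set(cm.counts.index[:10])


def test_wrapper_attaches_gene_annotations(small_index):
    from phagoscreen.screen_sim import ScreenSimConfig, simulate_screen

    cfg = ScreenSimConfig(index=small_index, seed=1, coverage=100,
                          sort_depth=1000, read_depth=50)
    counts, _ = simulate_screen(cfg)
    res = sgrna_stats(counts, index=small_index)
    assert res.loc["SLC001_sg1", "gene"] == "SLC001"
    assert res.loc["NT_001", "category"] == "NonTargeting"
    assert (res["p_adj"].dropna() >= res["p_value"].dropna() - 1e-15).all()
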