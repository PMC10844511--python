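import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gonodyn import de_engine
from gonodyn.de_engine import (
    DEResult,
    apply_deg_filter,
    benjamini_hochberg,
    cooks_outlier_flags,
    estimate_size_factors,
    fit_variance_prior,
    independent_filtering,
    moderated_t_core,
    moderated_t_test,
    nb_wald_core,
    nb_wald_test,
)
from gonodyn.exceptions import ValidationError


def brute_force_bh(pvalues):
    """Independent step-up oracle: literal definition of the BH adjustment."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(p[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


class TestSizeFactors:
    def test_hand_example(self):
        # median-of-ratios by hand on [[10,20],[100,200],[4,8]]
        factors = estimate_size_factors([[10, 20], [100, 200], [4, 8]])
        np.testing.assert_allclose(factors, [1 / math.sqrt(2), math.sqrt(2)])

    def test_identical_columns(self):
        factors = estimate_size_factors([[5, 5, 5], [9, 9, 9]])
        np.testing.assert_allclose(factors, [1, 1, 1])

    def test_single_sample(self):
        np.testing.assert_allclose(estimate_size_factors([[7], [3]]), [1.0])

    def test_no_zero_free_rows(self):
        with pytest.raises(ValidationError, match="zero-free"):
            estimate_size_factors([[0, 5], [3, 0]])

    @given(
        c=st.floats(min_value=0.1, max_value=50),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(100, (20, 4)) + 1
        base = estimate_size_factors(counts)
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= c
        new = estimate_size_factors(scaled)
        # multiplying one column by c multiplies its factor by c, modulo the
        # renormalization of the geometric-mean reference
        np.testing.assert_allclose(new[2] / base[2], c * (new[0] / base[0]), rtol=1e-9)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.002, 0.01, 0.03, 0.04]),
            [0.008, 0.02, 0.04, 0.04],
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.42]), [0.42])

    def test_ties(self):
        np.testing.assert_allclose(benjamini_hochberg([0.05] * 10), [0.05] * 10)

    def test_nan_passthrough(self):
        out = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-12)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=30)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestModeratedT:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=[f"s{i}" for i in range(len(rows[0]))]
        )

    def test_d0_zero_equals_pooled_t(self):
        m = self._frame([[1, 2, 3, 3, 4, 5]])
        table = moderated_t_core(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], prior_df=0)
        assert table["tstat"].iloc[0] == pytest.approx(2.449489742783178, abs=1e-10)
        t_ref = stats.ttest_ind([3, 4, 5], [1, 2, 3]).statistic
        assert table["tstat"].iloc[0] == pytest.approx(t_ref, abs=1e-10)

    def test_zero_difference_gives_p_one(self):
        m = self._frame([[1, 2, 3, 1, 2, 3]])
        for prior in (0, 5, None):
            table = moderated_t_core(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], prior_df=prior)
            assert table["tstat"].iloc[0] == pytest.approx(0.0)
            assert table["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_infinite_prior_uses_common_variance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(0, 1, (200, 6)), columns=[f"s{i}" for i in range(6)])
        table = moderated_t_core(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], prior_df=math.inf)
        s0sq = table.attrs["prior_var"]
        expected = m[["s3", "s4", "s5"]].mean(axis=1) - m[["s0", "s1", "s2"]].mean(axis=1)
        expected = expected / math.sqrt(s0sq * (2 / 3))
        np.testing.assert_allclose(table["tstat"], expected, rtol=1e-10)

    def test_large_prior_approaches_common_variance_denominator(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(0, 1, (100, 8)), columns=[f"s{i}" for i in range(8)])
        ref, alt = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        big = moderated_t_core(m, ref, alt, prior_df=1e9)
        inf = moderated_t_core(m, ref, alt, prior_df=math.inf)
        np.testing.assert_allclose(big["tstat"], inf["tstat"], rtol=1e-4)

    def test_constant_matrix_untested_with_zero_prior(self):
        m = self._frame([[2, 2, 2, 5, 5, 5]])
        table = moderated_t_core(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"], prior_df=0)
        assert table["status"].iloc[0] == de_engine.STATUS_UNTESTED
        assert np.isnan(table["pvalue"].iloc[0])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(
            rng.normal(5, 1, (5000, 8)), columns=[f"s{i}" for i in range(8)]
        )
        table = moderated_t_core(m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        ks = stats.kstest(table["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_prior_fit_recovers_known_hyperparameters(self):
        # variances drawn from a scaled inverse-chi-square prior: d0=4, s0^2=2
        rng = np.random.default_rng(5)
        d0, s0sq, df = 4.0, 2.0, 10
        true_var = d0 * s0sq / rng.chisquare(d0, 20000)
        s2 = true_var * rng.chisquare(df, 20000) / df
        d0_hat, s0sq_hat = fit_variance_prior(s2, df)
        assert d0_hat == pytest.approx(d0, rel=0.1)
        assert s0sq_hat == pytest.approx(s0sq, rel=0.1)

    def test_dataset_level_wrapper(self, tiny_intensity_dataset):
        result = moderated_t_test(tiny_intensity_dataset, sex="F")
        assert result.platform == "intensity"
        assert set(result.table.columns) >= {"log2fc", "pvalue", "padj", "status", "is_deg"}
        assert (result.table["padj"].dropna() >= result.table["pvalue"].dropna() - 1e-12).all()

    def test_wrong_platform_rejected(self, tiny_counts_dataset):
        with pytest.raises(ValidationError, match="intensity"):
            moderated_t_test(tiny_counts_dataset, sex="F")


def nb_matrix(rng, mu, alpha, n_genes, reps):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), (n_genes, reps))


class TestNBWald:
    def test_equal_means_null_behavior(self):
        rng = np.random.default_rng(2)
        y = nb_matrix(rng, 200.0, 0.02, 500, 12)
        m = pd.DataFrame(y, columns=[f"s{i}" for i in range(12)])
        table = nb_wald_core(
            m, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)],
            cooks_cutoff=None, if_alpha=None,
        )
        assert abs(np.nanmedian(table["log2fc"])) < 0.05
        assert np.nanmean(table["pvalue"]) > 0.4

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(3)
        y1 = nb_matrix(rng, 500.0, 0.01, 200, 6)
        y2 = nb_matrix(rng, 2000.0, 0.01, 200, 6)
        m = pd.DataFrame(np.hstack([y1, y2]), columns=[f"s{i}" for i in range(12)])
        table = nb_wald_core(
            m, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)],
            cooks_cutoff=None, if_alpha=None, size_factors=np.ones(12),
        )
        assert np.nanmedian(table["log2fc"]) == pytest.approx(2.0, abs=0.1)

    def test_common_scaling_absorbed_by_size_factors(self):
        rng = np.random.default_rng(4)
        base = nb_matrix(rng, 100.0, 0.05, 300, 12) + 1
        cols = [f"s{i}" for i in range(12)]
        ref, alt = cols[:6], cols[6:]
        t1 = nb_wald_core(pd.DataFrame(base, columns=cols), ref, alt,
                          cooks_cutoff=None, if_alpha=None)
        t2 = nb_wald_core(pd.DataFrame(base * 4, columns=cols), ref, alt,
                          cooks_cutoff=None, if_alpha=None)
        # invariance holds up to the dispersion re-estimation on the new scale
        np.testing.assert_allclose(t1["log2fc"], t2["log2fc"], atol=0.02)

    def test_all_zero_gene_untested(self):
        rng = np.random.default_rng(5)
        y = nb_matrix(rng, 50.0, 0.05, 20, 8)
        y[0, :] = 0
        m = pd.DataFrame(y, columns=[f"s{i}" for i in range(8)])
        table = nb_wald_core(m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
                             cooks_cutoff=None, if_alpha=None, min_total_count=0)
        assert table["status"].iloc[0] == de_engine.STATUS_UNTESTED
        assert np.isnan(table["pvalue"].iloc[0])

    def test_zero_group_untested(self):
        rng = np.random.default_rng(6)
        y = nb_matrix(rng, 50.0, 0.05, 20, 8)
        y[3, :4] = 0
        m = pd.DataFrame(y, columns=[f"s{i}" for i in range(8)])
        table = nb_wald_core(m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
                             cooks_cutoff=None, if_alpha=None, min_total_count=0)
        assert table["status"].iloc[3] == de_engine.STATUS_UNTESTED

    def test_low_total_count_filtered(self):
        rng = np.random.default_rng(7)
        y = nb_matrix(rng, 50.0, 0.05, 20, 8)
        y[2, :] = [1, 0, 1, 0, 1, 0, 1, 0]
        m = pd.DataFrame(y, columns=[f"s{i}" for i in range(8)])
        table = nb_wald_core(m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
                             cooks_cutoff=None, if_alpha=None, min_total_count=10)
        assert table["status"].iloc[2] == de_engine.STATUS_LOW_EXPR

    def test_dataset_level_wrapper(self, tiny_counts_dataset):
        result = nb_wald_test(tiny_counts_dataset, sex="M")
        assert result.platform == "counts"
        assert result.table.shape[0] == tiny_counts_dataset.n_genes


class TestCooks:
    def test_identical_counts_no_flag(self):
        counts = np.tile([[10, 10, 10, 40, 40, 40]], (5, 1))
        flags = cooks_outlier_flags(
            counts, ["a", "a", "a", "b", "b", "b"], size_factors=np.ones(6)
        )
        assert not flags.any()

    def test_two_replicate_groups_never_flagged(self):
        counts = np.array([[10, 10000, 12, 11]])
        flags = cooks_outlier_flags(
            counts, ["a", "a", "b", "b"], size_factors=np.ones(4)
        )
        assert not flags.any()

    def test_extreme_sample_flag_matches_brute_force(self):
        counts = np.array([[10, 10, 10000, 50, 55, 60]], dtype=float)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        sf = np.ones(6)
        alpha = np.array([0.05])
        flags = cooks_outlier_flags(counts, groups, size_factors=sf, dispersion=alpha)

        # independent oracle: direct Cook's formula on the group-mean NB fit
        from gonodyn.de_engine import _fit_group_log_mean

        def brute_force_max_d(y, idx):
            eta, _ = _fit_group_log_mean(counts[:, idx], sf[idx], alpha)
            mu = math.exp(eta[0])
            ds = []
            for j in idx:
                w = np.array([mu / (1 + alpha[0] * mu)] * len(idx))
                h = w[0] / w.sum()
                r = (counts[0, j] - mu) / math.sqrt(mu * (1 + alpha[0] * mu))
                ds.append(r**2 * h / (2 * (1 - h) ** 2))
            return max(ds)

        d_a = brute_force_max_d(counts, np.array([0, 1, 2]))
        d_b = brute_force_max_d(counts, np.array([3, 4, 5]))
        assert flags[0] == (max(d_a, d_b) > 19.17)
        assert flags[0]  # the constructed outlier must exceed the cutoff

    def test_flagged_gene_gets_missing_p(self):
        rng = np.random.default_rng(8)
        y = nb_matrix(rng, 100.0, 0.02, 50, 6)
        y[10, 0] = 100000
        m = pd.DataFrame(np.hstack([y, nb_matrix(rng, 100.0, 0.02, 50, 6)]),
                         columns=[f"s{i}" for i in range(12)])
        table = nb_wald_core(m, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)],
                             if_alpha=None)
        assert table["status"].iloc[10] == de_engine.STATUS_COOKS
        assert np.isnan(table["pvalue"].iloc[10])
        assert np.isnan(table["padj"].iloc[10])


class TestIndependentFiltering:
    def _table(self, base_mean, pvalue):
        n = len(base_mean)
        return pd.DataFrame(
            {
                "log2fc": np.zeros(n),
                "pvalue": pvalue,
                "padj": np.nan,
                "base_mean": base_mean,
                "status": de_engine.STATUS_TESTED,
                "is_deg": False,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_shared_base_mean_filters_nothing(self):
        table = self._table([5.0] * 50, np.linspace(0.001, 1, 50))
        out = independent_filtering(table)
        assert out.attrs["if_theta_quantile"] == 0.0
        assert (out["status"] == de_engine.STATUS_TESTED).all()

    def test_low_mean_nulls_filtered_increases_rejections(self):
        # grid-search oracle on a constructed table: 200 low-mean nulls and
        # 50 high-mean signals; filtering all nulls maximizes rejections
        # signals are marginal (p=0.02): with the 200 nulls in m they miss the
        # 0.1 FDR cut, after filtering the low-mean nulls they all pass
        rng = np.random.default_rng(9)
        base = np.concatenate([np.full(200, 1.0), np.full(50, 100.0)])
        pval = np.concatenate([rng.uniform(0.5, 1.0, 200), np.full(50, 0.02)])
        table = self._table(base, pval)
        out = independent_filtering(table, if_alpha=0.1)
        assert out.attrs["if_threshold"] > 1.0
        rejections_unfiltered = (benjamini_hochberg(pval) < 0.1).sum()
        assert out.attrs["if_rejections"] >= rejections_unfiltered
        assert (out.loc[out["base_mean"] < 100, "status"] == de_engine.STATUS_LOW_EXPR).all()

    def test_no_tested_genes_rejected(self):
        table = self._table([1.0], [0.5])
        table["status"] = de_engine.STATUS_UNTESTED
        with pytest.raises(ValidationError, match="no tested genes"):
            independent_filtering(table)


class TestDEGFilter:
    def _result(self, log2fc, padj, status="tested"):
        table = pd.DataFrame(
            {
                "log2fc": [log2fc],
                "pvalue": [padj],
                "padj": [padj],
                "base_mean": [10.0],
                "status": [status],
                "is_deg": [False],
            },
            index=["g"],
        )
        return DEResult(table=table, contrast=("T1", "T2"))

    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (2.0, 0.01, True),
            (-1.7, 0.04, True),   # down-changes count symmetrically
            (1.2, 0.001, False),  # below the FC threshold
            (2.0, 0.06, False),
            (1.5, 0.049, True),   # boundary: |FC| >= threshold
        ],
    )
    def test_flag_rule(self, log2fc, padj, expected):
        result = apply_deg_filter(self._result(log2fc, padj))
        assert bool(result.table["is_deg"].iloc[0]) is expected

    def test_untested_never_deg(self):
        result = apply_deg_filter(self._result(3.0, 0.001, status="cooks_outlier"))
        assert not result.table["is_deg"].any()

    def test_linear_scale_reinterprets_threshold(self):
        result = apply_deg_filter(self._result(1.0, 0.01), fc_threshold=1.5, fc_scale="linear")
        assert result.table["is_deg"].iloc[0]  # log2(1.5) ~ 0.585 <= 1.0

    def test_bad_scale_rejected(self):
        with pytest.raises(ValidationError, match="fc_scale"):
            apply_deg_filter(self._result(1.0, 0.01), fc_scale="log10")
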