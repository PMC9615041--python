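import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacdyn import (
    bh_adjust,
    consecutive_comparisons,
    estimate_dispersions,
    nb_wald_test,
    size_factors_median_of_ratios,
    summarize_wave,
    compare_day_pair,
)
from atacdyn.simulate import nb_draw


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = np.array([[10, 10], [40, 40], [7, 7]])
        assert np.allclose(size_factors_median_of_ratios(c), [1.0, 1.0])

    def test_hand_computed_example(self):
        c = np.array([[10, 20], [30, 60], [50, 100]])
        s = size_factors_median_of_ratios(c)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-4)

    def test_single_sample_is_unit(self):
        assert np.allclose(size_factors_median_of_ratios(np.array([[5], [9]])), [1.0])

    def test_error_when_no_all_positive_peak(self):
        with pytest.raises(ValueError, match="pseudo-count"):
            size_factors_median_of_ratios(np.array([[0, 5], [3, 0]]))


class TestDispersions:
    def test_poisson_counts_give_small_estimates(self):
        rng = np.random.default_rng(0)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 300))
        c = rng.poisson(np.tile(mu[:, None], (1, 200)))
        a = estimate_dispersions(c, np.ones(200))
        assert np.nanmedian(a) <= 0.05

    def test_truncation_when_variance_below_mean(self):
        # strongly underdispersed counts: raw moment estimate is 0, so the
        # trend (itself tiny here) is returned
        c = np.tile(np.array([[100, 101, 100, 99, 100, 100]]), (50, 1))
        a = estimate_dispersions(c, np.ones(6))
        assert np.nanmax(a) < 1e-3

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(3)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 300))
        c = nb_draw(np.tile(mu[:, None], (1, 200)), 0.2, rng)
        a = estimate_dispersions(c, np.ones(200))
        assert 0.1 <= np.nanmedian(a) <= 0.4

    def test_all_zero_peak_flagged_nan(self):
        c = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        a = estimate_dispersions(c, np.ones(4))
        assert np.isnan(a[0]) and np.isfinite(a[1])


class TestBH:
    def test_step_up_hand_computation(self):
        assert np.allclose(bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.013])[0] == pytest.approx(0.013)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestWald:
    def test_identical_groups_give_zero_lfc_and_p_one(self):
        c = np.array([[10, 20, 10, 20], [5, 5, 5, 5]], dtype=float)
        res = nb_wald_test(c, np.array([0, 0, 1, 1]), np.ones(4), np.array([0.1, 0.1]))
        assert res["log2FC"].abs().max() < 1e-8
        assert np.allclose(res["wald_p"], 1.0)

    def test_normalization_invariance(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(100, size=(50, 4)).astype(float)
        g = np.array([0, 0, 1, 1])
        a = np.full(50, 0.05)
        base = nb_wald_test(c, g, np.ones(4), a)
        doubled = c.copy()
        doubled[:, 2:] *= 2
        res = nb_wald_test(doubled, g, np.array([1, 1, 2, 2.0]), a)
        assert np.allclose(res["log2FC"], base["log2FC"], atol=1e-8)

    def test_antisymmetry_in_group_swap(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(80, size=(40, 4)).astype(float)
        c[:20, 2:] *= 3
        g = np.array([0, 0, 1, 1])
        a = np.full(40, 0.05)
        fwd = nb_wald_test(c, g, np.ones(4), a)
        rev = nb_wald_test(c, 1 - g, np.ones(4), a)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-6)
        assert np.allclose(fwd["wald_p"], rev["wald_p"], atol=1e-8)

    def test_matches_profile_likelihood_grid_oracle(self):
        """MLE and curvature agree with a dense-grid profile likelihood."""
        rng = np.random.default_rng(5)
        n_peaks = 50
        mu = np.exp(rng.uniform(np.log(50), np.log(300), n_peaks))
        fc = 2.0 ** rng.normal(0, 0.7, n_peaks)
        m = np.column_stack([mu, mu, mu * fc, mu * fc])
        c = nb_draw(m, 0.1, rng).astype(float)
        c = np.maximum(c, 1)  # keep groups away from the zero boundary
        g = np.array([0, 0, 1, 1])
        alpha = np.full(n_peaks, 0.1)
        res = nb_wald_test(c, g, np.ones(4), alpha)

        a = 0.1
        r = 1.0 / a
        for i in range(n_peaks):
            y = c[i]
            b1_grid = np.linspace(res["log2FC"][i] * np.log(2) - 0.3,
                                  res["log2FC"][i] * np.log(2) + 0.3, 2001)
            # profile out the intercept with vectorized Newton iterations
            b0 = np.full_like(b1_grid, np.log(max(y.mean(), 1.0)))
            for _ in range(50):
                m = np.exp(b0[:, None] + b1_grid[:, None] * g[None, :])
                score = ((y[None, :] - m) / (1 + a * m)).sum(axis=1)
                info = (m * (1 + a * y[None, :]) / (1 + a * m) ** 2).sum(axis=1)
                b0 = b0 + score / info
            m = np.exp(b0[:, None] + b1_grid[:, None] * g[None, :])
            prof = stats.nbinom.logpmf(y[None, :], r, r / (r + m)).sum(axis=1)
            jbest = prof.argmax()
            b1_hat = b1_grid[jbest]
            assert abs(b1_hat - res["log2FC"][i] * np.log(2)) < 1e-3
            # curvature-based se from the central second difference
            h = b1_grid[1] - b1_grid[0]
            curv = (prof[jbest - 1] - 2 * prof[jbest] + prof[jbest + 1]) / h**2
            se_oracle = np.sqrt(-1.0 / curv) / np.log(2)
            assert abs(se_oracle - res["se"][i]) < 1e-3 + 0.01 * se_oracle


class TestPairwiseWorkflow:
    def test_identical_replicates_across_days_give_no_calls(self, two_day_samples, make_cm):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, size=200)
        c = np.tile(col[:, None], (1, 4))
        cm = make_cm(c, two_day_samples)
        res = compare_day_pair(cm, 0, 3)
        assert int(res["significant"].sum()) == 0

    def test_missing_day_lists_available(self, two_day_samples, make_cm):
        cm = make_cm(np.ones((5, 4), dtype=int) * 10, two_day_samples)
        with pytest.raises(ValueError, match="available"):
            compare_day_pair(cm, 0, 7)

    def test_global_null_fdr_control(self, two_day_samples, make_cm):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 1000))
        c = nb_draw(np.tile(mu[:, None], (1, 4)), 0.05, rng)
        cm = make_cm(c, two_day_samples)
        res = compare_day_pair(cm, 0, 3)
        assert int(res["significant"].sum()) <= 1.5 * 0.05 * 1000

    def test_wave_summary_conserves_counts(self):
        tab = pd.DataFrame(
            {"direction": ["up_later", "up_earlier", "ns", "up_later"]}
        )
        out = summarize_wave({(0.0, 3.0): tab})
        row = out.iloc[0]
        assert row["n_sig"] == row["n_up"] + row["n_down"] == 3

    def test_consecutive_pairs_inferred_from_sheet(self, make_cm):
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "day": [0, 0, 3, 3, 7, 7],
                "replicate": [1, 2, 1, 2, 1, 2],
            }
        )
        rng = np.random.default_rng(0)
        cm = make_cm(rng.poisson(50, size=(30, 6)), samples)
        res = consecutive_comparisons(cm)
        assert set(res) == {(0, 3), (3, 7)}


class TestReferenceCrossCheck:
    def test_agrees_with_pydeseq2_on_mixed_effects(self):
        """Size factors match the reference median-of-ratios implementation
        exactly and unshrunk log2 fold changes agree closely."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(7)
        n = 150
        mu = np.exp(rng.uniform(np.log(30), np.log(400), n))
        fc = np.ones(n)
        fc[:50] = 2.0 ** rng.normal(0, 1, 50)
        m = np.column_stack([mu, mu, mu * fc, mu * fc])
        counts = nb_draw(m, 0.05, rng)
        g = np.array([0, 0, 1, 1])
        sf = size_factors_median_of_ratios(counts)
        alpha = estimate_dispersions(counts, sf, groups=g)
        ours = nb_wald_test(counts, g, sf, alpha)

        cdf = pd.DataFrame(
            counts.T, index=["s1", "s2", "s3", "s4"],
            columns=[f"p{i}" for i in range(n)],
        )
        meta = pd.DataFrame({"condition": ["A", "A", "B", "B"]}, index=cdf.index)
        dds = DeseqDataSet(counts=cdf, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        st.summary()
        ref = st.results_df

        assert np.allclose(sf, np.asarray(dds.obs["size_factors"], dtype=float))
        ref_lfc = ref["log2FoldChange"].to_numpy()
        assert np.nanmax(np.abs(ours["log2FC"].to_numpy() - ref_lfc)) < 0.05
        sig = (ref["padj"] < 0.01).to_numpy()
        assert (np.sign(ours["log2FC"].to_numpy()[sig]) == np.sign(ref_lfc[sig])).all()
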