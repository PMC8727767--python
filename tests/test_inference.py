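"""Median-split coding, logistic fits, AICc ranking and model averaging."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sibskit.inference import (
    aicc,
    average_parameters,
    chi_squared_2x2,
    conditional_average,
    enumerate_models,
    fit_logistic,
    median_split,
    pearson_r,
)
from sibskit.simulate import SimParams, simulate_cohort


class TestMedianSplit:
    def test_discharge_counts(self, fixture_cohort):
        y = median_split(fixture_cohort.df["gose_discharge"], "discharge")
        assert (int(y.sum()), int((1 - y).sum())) == (20, 12)

    def test_chronic_counts_after_dropping_missing(self, fixture_cohort):
        y = median_split(fixture_cohort.df["gose_chronic"], "chronic")
        assert len(y) == 30
        assert (int(y.sum()), int((1 - y).sum())) == (15, 15)

    def test_degenerate_split_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            median_split([3, 3, 4], "discharge")

    def test_invalid_timepoint_rejected(self):
        with pytest.raises(ValueError):
            median_split([1, 5], "admission")


class TestFitLogistic:
    def test_intercept_only_closed_form(self, fixture_cohort):
        y = median_split(fixture_cohort.df["gose_discharge"], "discharge")
        fit = fit_logistic(pd.DataFrame(index=y.index), y.to_numpy())
        assert fit.params["const"] == pytest.approx(np.log(20 / 12), abs=1e-6)
        expected_llf = 20 * np.log(20 / 32) + 12 * np.log(12 / 32)
        assert fit.llf == pytest.approx(expected_llf, abs=1e-9)

    def test_fixture_discharge_bsr_gcs_model(self, fixture_cohort):
        df = fixture_cohort.df
        y = median_split(df["gose_discharge"], "discharge")
        fit = fit_logistic(df[["max_bsr", "max_gcs"]], y.to_numpy())
        assert fit.params["max_bsr"] == pytest.approx(13.866, abs=0.005)
        assert fit.params["max_gcs"] == pytest.approx(1.572, abs=0.005)
        assert fit.llf == pytest.approx(-5.366, abs=0.005)

    def test_constant_outcome_flagged_as_separation(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        fit = fit_logistic(X, np.zeros(20))
        assert fit.separation

    def test_matches_grid_search_oracle(self):
        # coarse 2-d likelihood grid on a 10-point one-predictor problem
        x = np.array([-2.1, -1.4, -0.7, -0.2, 0.1, 0.4, 0.9, 1.3, 1.8, 2.2])
        y = np.array([0, 0, 0, 1, 0, 1, 0, 1, 1, 1])

        def loglik(b0, b1):
            p = 1 / (1 + np.exp(-(b0 + b1 * x)))
            return np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        grid = np.arange(-4, 4.0001, 0.01)
        best = max(((b0, b1) for b0 in grid for b1 in grid),
                   key=lambda ab: loglik(*ab))
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.params["const"] == pytest.approx(best[0], abs=0.01)
        assert fit.params["x"] == pytest.approx(best[1], abs=0.01)


class TestAICc:
    @pytest.mark.parametrize("llf,k,n,expected", [
        (-5.366, 3, 32, 17.589),
        (-15.907, 2, 32, 36.228),
    ])
    def test_printed_examples(self, llf, k, n, expected):
        assert aicc(llf, k, n) == pytest.approx(expected, abs=0.005)

    def test_zero_parameter_edge(self):
        assert aicc(-10.0, 0, 5) == 20.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 4, 5)

    def test_converges_to_aic_for_large_n(self):
        k, llf = 3, -10.0
        gaps = [aicc(llf, k, n) - (-2 * llf + 2 * k) for n in (10, 100, 1000, 10000)]
        assert all(a > b > 0 for a, b in zip(gaps, gaps[1:]))


class TestEnumerateModels:
    def test_sixteen_models_and_weight_normalization(self, fixture_cohort):
        ms = enumerate_models(fixture_cohort, "discharge")
        assert len(ms.fits) == 16
        assert ms.weight[ms.delta <= 5].sum() == pytest.approx(1.0, abs=1e-12)
        assert (ms.weight[ms.delta > 5] == 0).all()
        assert np.sum(ms.delta == 0.0) == 1

    def test_discharge_window_models_all_contain_bsr_and_gcs(self, fixture_cohort):
        ms = enumerate_models(fixture_cohort, "discharge")
        window_terms = [set(f.terms) for f in ms.window]
        assert len(window_terms) == 4
        assert all({"max_bsr", "max_gcs"} <= t for t in window_terms)

    def test_chronic_uses_complete_cases(self, fixture_cohort):
        ms = enumerate_models(fixture_cohort, "chronic")
        assert ms.n == 30

    def test_weights_from_printed_deltas(self):
        # Akaike weights over a published delta<=5 confidence window
        deltas = np.array([0.0, 0.567, 2.826, 3.047])
        w = np.exp(-deltas / 2) / np.exp(-deltas / 2).sum()
        np.testing.assert_allclose(np.round(w, 3), [0.452, 0.340, 0.110, 0.098])

    def test_null_cohort_keeps_intercept_only_in_window(self):
        hits = 0
        for rep in range(20):
            params = SimParams(n_patients=500, intercept=0.0, beta_bsr=0.0,
                               beta_gcs=0.0, seed=3000 + rep)
            ms = enumerate_models(simulate_cohort(params).cohort, "chronic")
            hits += any(f.terms == () for f in ms.window)
        assert hits >= 16  # >= 80% of replicates


class TestAveraging:
    def test_printed_chronic_bsr_average(self):
        betas = [8.083, 7.917, 8.444, 8.340]
        weights = [0.422, 0.284, 0.146, 0.146]
        assert conditional_average(betas, weights) == pytest.approx(8.13, abs=0.005)

    def test_printed_chronic_sex_average_confirms_conditional_scheme(self):
        assert conditional_average([-5.818, -6.289], [0.422, 0.146]) == pytest.approx(
            -5.94, abs=0.005)

    def test_average_lies_within_window_beta_range(self, fixture_cohort):
        ms = enumerate_models(fixture_cohort, "chronic")
        table = average_parameters(ms)
        for term in ("max_bsr", "max_gcs"):
            betas = [f.params[term] for f in ms.window if term in f.params.index]
            assert min(betas) <= table.loc[term, "beta_avg"] <= max(betas)

    def test_window_of_one_model_returns_model_estimates(self, fixture_cohort):
        ms = enumerate_models(fixture_cohort, "chronic", window_delta=0.5)
        assert len(ms.window) == 1
        table = average_parameters(ms)
        fit = ms.window[0]
        for term in fit.terms:
            assert table.loc[term, "beta_avg"] == pytest.approx(fit.params[term])
            assert table.loc[term, "se"] == pytest.approx(fit.se[term])

    def test_adjusted_se_exceeds_se(self, fixture_cohort):
        table = average_parameters(enumerate_models(fixture_cohort, "chronic"))
        assert (table["adj_se"] >= table["se"]).all()
        np.testing.assert_allclose(table["odds_ratio"], np.exp(table["beta_avg"]))


class TestAssociations:
    def test_fixture_discharge_gose_days_correlation(self, fixture_cohort):
        r, p = pearson_r(fixture_cohort.df["gose_discharge"],
                         fixture_cohort.df["days_discharge"])
        assert r == pytest.approx(-0.24, abs=0.005)
        assert p == pytest.approx(0.18, abs=0.01)

    @pytest.mark.parametrize("flip,expected", [(1.0, 1.0), (-1.0, -1.0)])
    def test_perfect_correlation(self, flip, expected):
        x = np.arange(10.0)
        assert pearson_r(x, flip * x)[0] == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("table,expected", [
        ([[20, 12], [6, 2]], 0.44),
        ([[15, 15], [4, 4]], 0.0),
        ([[10, 10], [10, 10]], 0.0),
    ])
    def test_chi_squared_examples(self, table, expected):
        chi2, _ = chi_squared_2x2(table)
        assert chi2 == pytest.approx(expected, abs=0.005)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2([[0, 0], [3, 4]])
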