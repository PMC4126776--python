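"""Transfer-function oracles: hand-computed WA, naive jackknife, MAT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wacalib as w
from wacalib.transfer import apparent_r2


def naive_wa_optima(Y: pd.DataFrame, x: pd.Series):
    """Brute-force per-taxon optima and tolerances by explicit loops."""
    optima, tols = {}, {}
    for taxon in Y.columns:
        num = den = 0.0
        for s in Y.index:
            num += Y.loc[s, taxon] * x[s]
            den += Y.loc[s, taxon]
        u = num / den
        sq = 0.0
        for s in Y.index:
            sq += Y.loc[s, taxon] * (x[s] - u) ** 2
        optima[taxon] = u
        tols[taxon] = np.sqrt(sq / den)
    return optima, tols


def naive_initial_estimates(Y, optima, tols, floor):
    """Tolerance-downweighted sample estimates by explicit loops."""
    out = {}
    for s in Y.index:
        num = den = 0.0
        for taxon in Y.columns:
            t_eff = max(tols[taxon], floor)
            weight = Y.loc[s, taxon] / t_eff**2
            num += weight * optima[taxon]
            den += weight
        out[s] = num / den
    return pd.Series(out)


class TestFitWA:
    def test_optima_match_hand_computation(self, toy_abundance, toy_gradient):
        model = w.fit_wa(toy_abundance, toy_gradient)
        optima, tols = naive_wa_optima(toy_abundance.data, toy_gradient)
        for taxon in toy_abundance.taxa:
            assert model.optima[taxon] == pytest.approx(optima[taxon], abs=1e-12)
            assert model.tolerances[taxon] == pytest.approx(tols[taxon], abs=1e-12)

    def test_deshrink_is_ols_of_observed_on_initial(self, toy_abundance, toy_gradient):
        model = w.fit_wa(toy_abundance, toy_gradient)
        optima, tols = naive_wa_optima(toy_abundance.data, toy_gradient)
        xhat0 = naive_initial_estimates(
            toy_abundance.data, optima, tols, model.tolerance_floor
        )
        b1, b0 = np.polyfit(xhat0.to_numpy(), toy_gradient.to_numpy(), 1)
        assert model.deshrink_intercept == pytest.approx(b0, abs=1e-12)
        assert model.deshrink_slope == pytest.approx(b1, abs=1e-12)

    def test_tolerance_floor_is_tenth_of_gradient_sd(self, toy_abundance, toy_gradient):
        model = w.fit_wa(toy_abundance, toy_gradient)
        assert model.tolerance_floor == pytest.approx(
            toy_gradient.std(ddof=1) / 10.0
        )

    def test_no_downweighting_uses_plain_weighted_mean(
        self, toy_abundance, toy_gradient
    ):
        model = w.fit_wa(toy_abundance, toy_gradient, tolerance_dw=False)
        pred = w.predict(model, toy_abundance.data)
        for s in toy_abundance.samples:
            num = den = 0.0
            for taxon in toy_abundance.taxa:
                num += toy_abundance.data.loc[s, taxon] * model.optima[taxon]
                den += toy_abundance.data.loc[s, taxon]
            assert pred.raw[s] == pytest.approx(num / den, abs=1e-12)

    def test_counts_basis_rejected(self, toy_gradient):
        counts = w.AbundanceMatrix(
            pd.DataFrame(
                np.ones((5, 2)), index=toy_gradient.index, columns=["a", "b"]
            ),
            basis="density",
        )
        with pytest.raises(ValueError, match="relative"):
            w.fit_wa(counts, toy_gradient)

    def test_zero_total_taxon_dropped_with_warning(self, toy_gradient):
        data = pd.DataFrame(
            {"a": [1.0] * 5, "b": [0.0] * 5}, index=toy_gradient.index
        )
        matrix = w.AbundanceMatrix(data, "rel_density")
        with pytest.warns(UserWarning, match="zero total abundance"):
            model = w.fit_wa(matrix, toy_gradient, tolerance_dw=False, deshrink="none")
        assert list(model.taxa) == ["a"]

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_optima_invariant_to_count_scaling(self, scale):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(12, 4)).astype(float),
            index=[f"s{i}" for i in range(12)],
            columns=list("abcd"),
        )
        x = pd.Series(rng.normal(size=12), index=counts.index)
        base = w.fit_wa(w.AbundanceMatrix(counts, "density").to_relative(), x)
        scaled = w.fit_wa(
            w.AbundanceMatrix(counts * scale, "density").to_relative(), x
        )
        assert np.allclose(base.optima, scaled.optima, atol=1e-10)
        assert np.allclose(base.tolerances, scaled.tolerances, atol=1e-10)


class TestPredict:
    def test_coverage_and_no_overlap(self, toy_abundance, toy_gradient):
        model = w.fit_wa(toy_abundance, toy_gradient)
        fossil = pd.DataFrame(
            {"a": [0.3, 0.0], "unknown": [0.7, 1.0]},
            index=["f1", "f2"],
        )
        pred = w.predict(model, fossil)
        assert pred.coverage["f1"] == pytest.approx(0.3)
        assert pred.coverage["f2"] == pytest.approx(0.0)
        assert "f2" in pred.no_overlap
        assert np.isnan(pred.values["f2"])
        assert np.isfinite(pred.values["f1"])

    def test_training_predictions_equal_deshrunk_initials(
        self, toy_abundance, toy_gradient
    ):
        model = w.fit_wa(toy_abundance, toy_gradient)
        pred = w.predict(model, toy_abundance.data)
        expected = model.deshrink_intercept + model.deshrink_slope * pred.raw
        assert np.allclose(pred.values, expected, atol=1e-12)


@pytest.fixture(scope="module")
def mini_training():
    pool, env, abundance = w.benchmark_training_set(n_sites=30, n_taxa=12, seed=11)
    return abundance.to_relative(), env.transformed_variable("TP")


class TestJackknife:
    def test_matches_naive_loo_loop(self, mini_training):
        rel, x = mini_training
        report = w.jackknife(rel, x)
        # independent implementation: refit everything without sample i
        for i, sample in enumerate(rel.samples):
            sub_data = rel.data.drop(index=sample)
            sub = w.AbundanceMatrix(sub_data, rel.basis)
            with np.errstate(all="ignore"):
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    model_i = w.fit_wa(sub, x.drop(index=sample))
            pred_i = w.predict(model_i, rel.data.loc[[sample]])
            assert report.predictions_jack[sample] == pytest.approx(
                float(pred_i.values.iloc[0]), abs=1e-10
            )

    def test_rmsep_not_below_apparent_rmse(self, mini_training):
        rel, x = mini_training
        report = w.jackknife(rel, x)
        assert report.rmsep_jack >= report.rmse_apparent
        assert report.r2_jack <= report.r2_apparent + 1e-12

    def test_apparent_r2_consistent(self, mini_training):
        rel, x = mini_training
        report = w.jackknife(rel, x)
        assert apparent_r2(rel, x) == pytest.approx(report.r2_apparent)

    def test_too_few_samples_rejected(self, toy_abundance, toy_gradient):
        with pytest.raises(ValueError, match="at least 10"):
            w.jackknife(toy_abundance, toy_gradient)


class TestMAT:
    def test_squared_chord_hand_value(self):
        p = np.array([[0.25, 0.75]])
        q = np.array([[1.0, 0.0]])
        expected = (0.5 - 1.0) ** 2 + (np.sqrt(0.75) - 0.0) ** 2
        assert w.squared_chord(p, q)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_exact_match_with_k1_returns_its_gradient(
        self, toy_abundance, toy_gradient
    ):
        test = toy_abundance.data.loc[["s2"]].rename(index={"s2": "fossil"})
        result = w.mat_predict(toy_abundance, toy_gradient, test, k=1)
        assert result.values["fossil"] == pytest.approx(toy_gradient["s2"])
        assert result.analog_ids.loc["fossil", "analog_1"] == "s2"

    def test_k5_is_mean_of_nearest_gradients(self, toy_abundance, toy_gradient):
        test = pd.DataFrame(
            {"a": [0.2], "b": [0.4], "c": [0.4]}, index=["fossil"]
        )
        result = w.mat_predict(toy_abundance, toy_gradient, test, k=5)
        assert result.values["fossil"] == pytest.approx(toy_gradient.mean())

    def test_ties_at_kth_distance_are_included(self, toy_gradient):
        data = pd.DataFrame(
            {"a": [1.0, 0.0, 0.0, 0.5, 0.5], "b": [0.0, 1.0, 1.0, 0.5, 0.5]},
            index=toy_gradient.index,
        )
        training = w.AbundanceMatrix(data, "rel_density")
        test = pd.DataFrame({"a": [1.0], "b": [0.0]}, index=["f"])
        # distances: s0 -> 0; s1, s2 -> tied; s3, s4 -> tied closer than s1
        result = w.mat_predict(training, toy_gradient, test, k=2)
        ids = set(result.analog_ids.loc["f"].dropna())
        assert ids == {"s0", "s3", "s4"}

    def test_k_exceeding_training_rejected(self, toy_abundance, toy_gradient):
        with pytest.raises(ValueError, match="k cannot exceed"):
            w.mat_predict(
                toy_abundance, toy_gradient, toy_abundance.data.iloc[:1], k=6
            )
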