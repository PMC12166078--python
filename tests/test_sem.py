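"""Unit and property tests for the covariance-structure engine."""

import numpy as np
import pandas as pd
import pytest

from rhythmlink import sem
from rhythmlink.sem import (Cell, ConvergenceError, FactorModelSpec,
                            FitResult, IdentificationError, bootstrap_se,
                            fit_indices, fit_ml, implied_covariance,
                            standardize)


def two_indicator_spec():
    """Single factor, both loadings fixed to 1, residuals fixed to I."""
    return FactorModelSpec(
        observed=["y1", "y2"], factors=["f"],
        cells=[
            Cell("A", "y1", "f", free=False, value=1.0),
            Cell("A", "y2", "f", free=False, value=1.0),
            Cell("S", "y1", "y1", free=False, value=1.0),
            Cell("S", "y2", "y2", free=False, value=1.0),
            Cell("S", "f", "f", free=False, value=1.0),
        ],
    )


class TestImpliedCovariance:
    def test_single_factor_hand_algebra(self):
        spec = two_indicator_spec()
        Sigma = implied_covariance(spec, np.array([]))
        assert np.allclose(Sigma, [[2.0, 1.0], [1.0, 2.0]])

    def test_path_tracing_hum_syntax(self, stage3_spec, stage3_sigma):
        # cov(hum, syntax) = 0.74 * 0.42 * 0.59 through the factor chain
        names = stage3_spec.manifest
        i, j = names.index("hum_5y"), names.index("syntax_10y")
        assert stage3_sigma[i, j] == pytest.approx(0.74 * 0.42 * 0.59,
                                                   abs=1e-12)
        assert np.allclose(np.diag(stage3_sigma), 1.0)

    def test_zero_loadings_gives_diagonal(self):
        spec = FactorModelSpec.cfa({"f": {"a": 0.0, "b": 0.0}},
                                   loadings_free=False, residuals_free=False,
                                   residuals={"a": 0.7, "b": 0.4},
                                   correlations_free=False)
        Sigma = implied_covariance(spec, spec.start_vector())
        assert np.allclose(Sigma, np.diag([0.7, 0.4]))

    def test_wrong_parameter_length_raises(self, stage3_spec):
        with pytest.raises(ValueError, match="length"):
            implied_covariance(stage3_spec, np.zeros(3))


class TestFitML:
    def test_saturated_model_zero_discrepancy(self):
        # 3 indicators, 1 factor: 6 free parameters = 6 moments, df = 0
        spec = FactorModelSpec.cfa({"f": {"a": 0.5, "b": 0.5, "c": 0.5}})
        rng = np.random.default_rng(0)
        X = rng.multivariate_normal(
            np.zeros(3), [[1, .3, .2], [.3, 1, .25], [.2, .25, 1]], size=500)
        fit = fit_ml(spec, np.cov(X, rowvar=False), 500, seed=0)
        assert fit.df == 0
        assert fit.fml == pytest.approx(0.0, abs=1e-6)
        assert fit.statistic == pytest.approx(0.0, abs=1e-3)

    def test_two_factor_parameter_recovery(self):
        gen = FactorModelSpec.cfa(
            {"f1": {"a": 0.7, "b": 0.6, "c": 0.5},
             "f2": {"d": 0.8, "e": 0.65, "g": 0.55}},
            factor_correlations={("f1", "f2"): 0.4},
            residuals={m: 1 - l**2 for m, l in
                       zip("abcdeg", [0.7, 0.6, 0.5, 0.8, 0.65, 0.55])},
        )
        Sigma = implied_covariance(gen, gen.start_vector())
        rng = np.random.default_rng(42)
        X = rng.multivariate_normal(np.zeros(6), Sigma, size=10_000)
        fit = fit_ml(gen, np.cov(X, rowvar=False), 10_000, seed=1)
        assert fit.converged and fit.admissible
        for item, factor, lam in [("a", "f1", 0.7), ("d", "f2", 0.8),
                                  ("g", "f2", 0.55)]:
            assert fit.loading(item, factor) == pytest.approx(lam, abs=0.03)
        assert fit.factor_correlation("f1", "f2") == pytest.approx(0.4,
                                                                   abs=0.03)

    def test_overparameterised_spec_rejected(self):
        spec = FactorModelSpec.cfa({"f": {"a": 0.5, "b": 0.5}})  # 4 free, 3 moments
        with pytest.raises(IdentificationError, match="free parameters"):
            fit_ml(spec, np.eye(2), 100)

    def test_unanchored_factor_rejected(self):
        spec = FactorModelSpec(
            observed=["a", "b", "c"], factors=["f"],
            cells=[Cell("A", m, "f") for m in "abc"]
            + [Cell("S", m, m) for m in "abc"]
            + [Cell("S", "f", "f", free=True, value=1.0)],
        )
        with pytest.raises(IdentificationError, match="unanchored"):
            spec.validate()

    def test_non_pd_sample_cov_rejected(self, stage3_spec):
        S = np.ones((9, 9))  # rank 1
        with pytest.raises(ValueError, match="eigenvalue"):
            fit_ml(stage3_spec, S, 1000)

    def test_fml_nonnegative_on_random_data(self, stage3_spec):
        rng = np.random.default_rng(3)
        for _ in range(3):
            X = rng.standard_normal((400, 9))
            S = np.cov(X, rowvar=False)
            fit = fit_ml(stage3_spec, S, 400, n_restarts=2, seed=0,
                         compute_se=False)
            assert fit.fml >= 0.0


class TestFitIndices:
    def test_perfect_fit_corner(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = fit_indices(0.0, 5, 800.0, 10, 1000, S=S, Sigma=S.copy())
        assert out["cfi"] == 1.0
        assert out["rmsea"] == 0.0
        assert out["srmr"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cfi(self):
        out = fit_indices(300.0, 100, 3100.0, 120, 1001)
        assert out["cfi"] == pytest.approx(1 - 200 / 2980, abs=1e-6)
        # TLI = (T0/df0 - T/df) / (T0/df0 - 1), uncapped
        expected_tli = (3100 / 120 - 3.0) / (3100 / 120 - 1)
        assert out["tli"] == pytest.approx(expected_tli, abs=1e-9)
        assert out["rmsea"] == pytest.approx(np.sqrt(200 / (100 * 1000)),
                                             abs=1e-9)

    def test_zero_df_undefined_not_zero(self):
        out = fit_indices(0.0, 0, 100.0, 10, 500)
        assert out["rmsea"] is None
        assert out["tli"] is None
        assert out["cfi"] == 1.0

    def test_simulated_true_model_sits_near_perfect_corner(self, stage3_fit):
        # when the fitted model is exactly the generating model, indices
        # land near the perfect-fit corner rather than field-data values
        assert stage3_fit.indices["cfi"] > 0.99
        assert stage3_fit.indices["rmsea"] < 0.02
        assert stage3_fit.indices["srmr"] < 0.02


class TestStandardize:
    def test_hand_algebra_loading(self):
        # lambda = 2, factor var 1, residual 1 -> std lambda = 2/sqrt(5)
        spec = FactorModelSpec(
            observed=["y1", "y2"], factors=["f"],
            cells=[
                Cell("A", "y1", "f", free=False, value=2.0),
                Cell("A", "y2", "f", free=False, value=1.0),
                Cell("S", "y1", "y1", free=False, value=1.0),
                Cell("S", "y2", "y2", free=False, value=1.0),
                Cell("S", "f", "f", free=False, value=1.0),
            ],
        )
        fit = FitResult(spec=spec, estimates={}, se={}, fml=0, statistic=0,
                        df=0, baseline_statistic=0, baseline_df=0, n=100,
                        converged=True, admissible=True,
                        sample_cov=np.eye(2), implied_cov=np.eye(2))
        tab = standardize(fit)
        lam = tab[(tab.matrix == "A") & (tab.row == "y1")].iloc[0].std_est
        assert lam == pytest.approx(2 / np.sqrt(5), abs=1e-12)

    def test_already_standardised_is_identity(self, stage3_spec, stage3_fit):
        # generating spec has unit-variance measures; refitting and
        # standardising leaves estimates essentially unchanged
        tab = stage3_fit.standardized
        loadings = tab[tab.matrix == "A"]
        assert np.allclose(loadings.est, loadings.std_est, atol=0.02)

    def test_factor_correlations_bounded(self, stage3_fit):
        tab = stage3_fit.standardized
        fc = tab[(tab.matrix == "S") & tab.row.isin(stage3_fit.spec.factors)
                 & tab.col.isin(stage3_fit.spec.factors)]
        assert (fc.std_est.abs() <= 1.0 + 1e-9).all()

    def test_invariant_to_observed_rescaling(self, stage3_spec,
                                             stage3_sample):
        S = np.cov(stage3_sample, rowvar=False, ddof=1)
        n = stage3_sample.shape[0]
        scale = np.linspace(0.5, 3.0, 9)
        S_scaled = S * np.outer(scale, scale)
        f1 = fit_ml(stage3_spec, S, n, seed=0)
        f2 = fit_ml(stage3_spec, S_scaled, n, seed=0)
        t1 = f1.standardized.sort_values(["matrix", "row", "col"])
        t2 = f2.standardized.sort_values(["matrix", "row", "col"])
        assert np.allclose(t1.std_est.to_numpy(), t2.std_est.to_numpy(),
                           atol=1e-4)


@pytest.fixture(scope="module")
def gaussian_cohort():
    spec = FactorModelSpec.cfa(
        {"f": {"a": 0.7, "b": 0.6, "c": 0.5, "d": 0.55}},
        residuals={m: 1 - l**2 for m, l in
                   zip("abcd", [0.7, 0.6, 0.5, 0.55])})
    Sigma = implied_covariance(spec, spec.start_vector())
    rng = np.random.default_rng(9)
    X = rng.multivariate_normal(np.zeros(4), Sigma, size=2000)
    return spec, pd.DataFrame(X, columns=list("abcd"))


class TestBootstrap:
    def test_agrees_with_information_ses(self, gaussian_cohort):
        spec, data = gaussian_cohort
        fit = fit_ml(spec, data.cov().to_numpy(), len(data), seed=0)
        se_boot, _ = bootstrap_se(data, spec, B=200, seed=4)
        for label in ["lambda_a_f", "lambda_b_f"]:
            assert se_boot[label] == pytest.approx(fit.se[label], rel=0.20)

    def test_seed_reproducibility(self, gaussian_cohort):
        spec, data = gaussian_cohort
        se1, _ = bootstrap_se(data, spec, B=25, seed=7)
        se2, _ = bootstrap_se(data, spec, B=25, seed=7)
        assert se1 == se2

    def test_degenerate_cohort_rejected(self, gaussian_cohort):
        spec, data = gaussian_cohort
        with pytest.raises(ValueError, match="too small"):
            bootstrap_se(data.iloc[:2], spec, B=10, seed=0)


def test_defined_parameters_are_exact_products():
    spec = FactorModelSpec.cfa({"f": {"a": 0.6, "b": 0.6, "c": 0.6}})
    spec.defined = {"prod": "lambda_a_f * lambda_b_f"}
    rng = np.random.default_rng(5)
    Sigma = implied_covariance(spec, spec.start_vector())
    X = rng.multivariate_normal(np.zeros(3), Sigma, size=800)
    fit = fit_ml(spec, np.cov(X, rowvar=False), 800, seed=0)
    assert fit.defined["prod"] == fit.estimates["lambda_a_f"] * \
        fit.estimates["lambda_b_f"]
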