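"""Tests of the data-driven factor-structure discovery recipe."""

import numpy as np
import pandas as pd
import pytest

from rhythmlink import presets, sem, simulate
from rhythmlink.discovery import (build_cfa_spec, confirm_and_refit, discover,
                                  efa_two_block, estimate_n_factors, oblimin,
                                  split_half, varimax)
from rhythmlink.screen import residualize
from rhythmlink.simulate import CohortTable


class TestEstimateNFactors:
    def test_identity_flat_scree(self):
        with pytest.warns(UserWarning, match="flat scree"):
            k, ev = estimate_n_factors(np.eye(10))
        assert k == 0
        assert np.allclose(ev, 1.0)

    def test_two_block_structure(self):
        R = np.eye(10)
        for block in (slice(0, 5), slice(5, 10)):
            R[block, block] = 0.8
        np.fill_diagonal(R, 1.0)
        k, ev = estimate_n_factors(R)
        assert k == 2
        assert ev[0] == pytest.approx(1 + 4 * 0.8)
        assert ev[1] == pytest.approx(1 + 4 * 0.8)

    def test_rank_one_matrix(self):
        k, _ = estimate_n_factors(np.ones((6, 6)))
        assert k == 1

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            estimate_n_factors(R)


@pytest.fixture(scope="module")
def missing_cohort():
    cfg = simulate.default_config(6101)
    cfg.missing_rates = {"syntax_10y": 0.15, "nonword_9y": 0.08}
    return simulate.generate_cohort(cfg, seed=17)


class TestSplitHalf:
    def test_disjoint_exhaustive_balanced(self, missing_cohort):
        a, b = split_half(missing_cohort, seed=1)
        ids_a, ids_b = set(a.data.index), set(b.data.index)
        assert ids_a.isdisjoint(ids_b)
        assert ids_a | ids_b == set(missing_cohort.data.index)
        assert abs(a.n - b.n) <= 1

    def test_sex_proportions_matched(self, missing_cohort):
        a, b = split_half(missing_cohort, seed=2)
        pa, pb = a.data["sex"].mean(), b.data["sex"].mean()
        assert abs(pa - pb) < 0.02

    def test_missingness_patterns_matched(self, missing_cohort):
        a, b = split_half(missing_cohort, seed=3)
        ra = a.data["syntax_10y"].isna().mean()
        rb = b.data["syntax_10y"].isna().mean()
        assert abs(ra - rb) < 0.02

    def test_single_sex_degenerates_gracefully(self, missing_cohort):
        c = CohortTable(missing_cohort.data.copy(),
                        missing_cohort.metadata.copy())
        c.data["sex"] = 1.0
        a, b = split_half(c, seed=4)
        assert abs(a.n - b.n) <= 1

    def test_missing_stratifier_column_rejected(self, missing_cohort):
        with pytest.raises(ValueError, match="absent"):
            split_half(missing_cohort, seed=5, stratifiers=("site",))

    def test_reproducible(self, missing_cohort):
        a1, _ = split_half(missing_cohort, seed=6)
        a2, _ = split_half(missing_cohort, seed=6)
        assert a1.data.index.equals(a2.data.index)


class TestRotations:
    def test_varimax_fixed_point_on_simple_structure(self):
        L = np.array([[0.8, 0.0], [0.7, 0.0], [0.0, 0.75], [0.0, 0.6]])
        Lr = varimax(L)
        # unchanged up to column permutation and sign
        best = np.abs(Lr.T @ L)
        assert np.allclose(np.sort(best.max(axis=0)),
                           np.sort((L**2).sum(axis=0)), atol=1e-6)
        assert np.allclose(np.sort(np.abs(Lr).ravel()),
                           np.sort(np.abs(L).ravel()), atol=1e-6)

    def test_oblimin_preserves_communalities_vs_varimax(self):
        rng = np.random.default_rng(0)
        L = rng.uniform(-0.8, 0.8, size=(8, 2))
        Lv = varimax(L)
        Lo, Phi = oblimin(L)
        # both rotations reproduce the same common-part covariance,
        # i.e. the fit is rotation-invariant
        assert np.allclose(Lv @ Lv.T, L @ L.T, atol=1e-8)
        assert np.allclose(Lo @ Phi @ Lo.T, L @ L.T, atol=1e-6)
        assert np.allclose(np.diag(Phi), 1.0, atol=1e-8)


@pytest.fixture(scope="module")
def stage3_cohort(stage3_spec, stage3_sigma):
    rng = np.random.default_rng(77)
    X = rng.multivariate_normal(np.zeros(9), stage3_sigma,
                                size=presets.STAGE3_N)
    data = pd.DataFrame(X, columns=stage3_spec.manifest)
    data["sex"] = rng.integers(0, 2, presets.STAGE3_N).astype(float)
    data.index.name = "individual_id"
    meta = pd.DataFrame({
        "role": ["predictor"] * 3 + ["outcome"] * 6,
        "scale": "continuous", "composite": False,
    }, index=pd.Index(stage3_spec.manifest, name="measure"))
    return CohortTable(data=data, metadata=meta)


class TestEfaTwoBlock:
    def test_single_factor_blocks_recover_pattern(self, stage3_cohort):
        preds = stage3_cohort.measures[:3]
        outs = stage3_cohort.measures[3:]
        efa = efa_two_block(stage3_cohort.data, preds, outs, 1, 2,
                            rotation="varimax", seed=0)
        lam = efa.loadings
        assert (lam.loc[preds, "P1"].abs() > 0.3).all()
        assert (lam.loc[preds, ["O1", "O2"]] == 0).all().all()
        speech_items = ["intelligibility_10y", "syntax_10y", "rapport_10y"]
        cog_col = lam.loc[["nonword_9y", "verbal_iq_9y"]].abs().idxmax(axis=1)
        assert cog_col.nunique() == 1
        speech_col = lam.loc[speech_items].abs().idxmax(axis=1)
        assert speech_col.nunique() == 1
        assert cog_col.iloc[0] != speech_col.iloc[0]

    def test_excess_factors_rejected(self, stage3_cohort):
        with pytest.raises(ValueError, match="identification limit"):
            efa_two_block(stage3_cohort.data, stage3_cohort.measures[:3],
                          stage3_cohort.measures[3:], 4, 2)


class TestBuildCfaSpec:
    def test_threshold_is_strict(self):
        lam = pd.DataFrame({"F1": [0.05, 0.74, 0.1]},
                           index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="dropped"):
            spec = build_cfa_spec(lam, retain_threshold=0.1)
        loadings = [(c.row, c.col) for c in spec.cells if c.matrix == "A"]
        assert loadings == [("b", "F1")]

    def test_all_subthreshold_rejected(self):
        lam = pd.DataFrame({"F1": [0.01, 0.02]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty model"), \
                pytest.warns(UserWarning, match="dropped"):
            build_cfa_spec(lam)


class TestConfirmAndRefit:
    def test_recovers_published_loadings(self, stage3_cohort):
        # confirming the generating pattern itself reproduces the
        # published standardised estimates within sampling error
        spec = sem.FactorModelSpec.cfa(presets.STAGE3_LOADINGS)
        data = stage3_cohort.data[stage3_cohort.measures]
        half_b = data.iloc[presets.STAGE3_N // 2:]
        result = confirm_and_refit({"varimax": spec}, half_b, data,
                                   b_boot=0, seed=11)
        fit = result.full_fit
        for factor, items in presets.STAGE3_LOADINGS.items():
            for item, lam in items.items():
                assert fit.loading(item, factor) == pytest.approx(
                    lam, abs=0.04), (item, factor)
        for (f1, f2), r in presets.STAGE3_FACTOR_CORRELATIONS.items():
            assert fit.factor_correlation(f1, f2) == pytest.approx(
                r, abs=0.04)

    def test_holdout_and_full_agree(self, stage3_cohort):
        resid = stage3_cohort.data[stage3_cohort.measures]
        result = discover(stage3_cohort, resid, seed=12)
        hold, full = result.holdout_fit, result.full_fit
        for label, est in full.estimates.items():
            se = hold.se.get(label)
            if se and np.isfinite(se):
                assert abs(hold.estimates[label] - est) <= 2.5 * se, label

    def test_meaningfulness_flag_is_strict(self, stage3_cohort):
        resid = stage3_cohort.data[stage3_cohort.measures]
        result = discover(stage3_cohort, resid, seed=13)
        tab = result.interpretation
        weak = tab[(tab.matrix == "A") & (tab.std_est.abs() <= 0.3)]
        assert not weak.meaningful.any()
        strong = tab[(tab.matrix == "A") & (tab.std_est.abs() > 0.35)]
        assert strong.meaningful.all()


def _match_factors(fit, generating_spec):
    """Map generating factor names to discovered block-factor names by
    their highest-loading indicator."""
    tab = fit.standardized
    loadings = tab[tab.matrix == "A"]
    mapping = {}
    for factor, items in presets.STAGE3_LOADINGS.items():
        anchor = max(items, key=lambda m: abs(items[m]))
        sub = loadings[loadings.row == anchor]
        mapping[factor] = sub.loc[sub.std_est.abs().idxmax(), "col"]
    return mapping


def test_end_to_end_recovery_across_seeds(stage3_spec, stage3_sigma):
    """The full recipe re-identifies 3 factors and the generating pattern."""
    successes = 0
    n_seeds = 5
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        X = rng.multivariate_normal(np.zeros(9), stage3_sigma, size=3000)
        data = pd.DataFrame(X, columns=stage3_spec.manifest)
        data["sex"] = rng.integers(0, 2, 3000).astype(float)
        data.index.name = "individual_id"
        meta = pd.DataFrame({"role": ["predictor"] * 3 + ["outcome"] * 6,
                             "scale": "continuous", "composite": False},
                            index=pd.Index(stage3_spec.manifest,
                                           name="measure"))
        cohort = CohortTable(data=data, metadata=meta)
        try:
            result = discover(cohort, data[cohort.measures], seed=seed)
        except Exception:
            continue
        if result.n_factors != 3:
            continue
        fit = result.full_fit
        mapping = _match_factors(fit, stage3_spec)
        ok = True
        for factor, items in presets.STAGE3_LOADINGS.items():
            for item, lam in items.items():
                if abs(lam) >= 0.2:
                    try:
                        fit.loading(item, mapping[factor])
                    except KeyError:
                        ok = False
        tab = fit.standardized
        gen_pairs = {(i, f) for f, items in presets.STAGE3_LOADINGS.items()
                     for i in items}
        inv = {v: k for k, v in mapping.items()}
        for _, r in tab[tab.matrix == "A"].iterrows():
            gen_f = inv.get(r.col)
            if gen_f is not None and (r.row, gen_f) not in gen_pairs \
                    and abs(r.std_est) > 0.3:
                ok = False
        successes += ok
    assert successes >= n_seeds - 1
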