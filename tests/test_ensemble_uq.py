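import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from crtcascade import (
    BaseLearnerSpec,
    EnsembleModel,
    EnsembleSpec,
    FeatureTable,
    UncertaintyPrediction,
    draw_pseudo_bootstrap,
    fit_base,
    fit_ensemble,
    select_features_rfe,
    tune_ensemble,
)


def ridge_logistic_oracle(Z, y, lam):
    """Brute-force convex minimization of the penalized negative
    log-likelihood (ridge, intercept unpenalized)."""
    Z = np.asarray(Z)
    n, p = Z.shape

    def objective(w):
        eta = Z @ w[:p] + w[p]
        nll = np.sum(np.log1p(np.exp(-eta * (2 * np.asarray(y) - 1))))
        return nll + lam * 0.5 * np.sum(w[:p] ** 2)

    res = minimize(objective, np.zeros(p + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return res.x[:p], res.x[p]


class TestPseudoBootstrap:
    def test_full_fraction_returns_everything(self):
        subsets = draw_pseudo_bootstrap(10, EnsembleSpec(3, 1.0, seed=0))
        assert len(subsets) == 3
        for s in subsets:
            assert sorted(s.tolist()) == list(range(10))

    def test_subset_size_is_rounded_fraction(self):
        subsets = draw_pseudo_bootstrap(100, EnsembleSpec(25, 0.95, seed=1))
        assert all(len(s) == 95 for s in subsets)
        # without replacement: no duplicates inside a subset
        assert all(len(np.unique(s)) == 95 for s in subsets)

    def test_seed_determinism(self):
        a = draw_pseudo_bootstrap(50, EnsembleSpec(5, 0.8, seed=9))
        b = draw_pseudo_bootstrap(50, EnsembleSpec(5, 0.8, seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_too_small_subset_rejected(self):
        with pytest.raises(ValueError):
            draw_pseudo_bootstrap(2, EnsembleSpec(2, 0.5, seed=0))


class TestBaseLearner:
    def test_huge_penalty_gives_prevalence_prediction(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((200, 3))
        y = (rng.random(200) < 0.7).astype(int)
        base = fit_base(Z, y, BaseLearnerSpec(alpha=0.5, lam=1e6))
        probs = base.predict_proba(Z)
        assert np.allclose(base.coef, 0.0, atol=1e-3)
        assert np.allclose(probs, y.mean(), atol=0.01)

    def test_monotone_in_separating_feature(self):
        Z = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (Z.ravel() > 0).astype(int)
        base = fit_base(Z, y, BaseLearnerSpec(alpha=0.5, lam=0.01))
        probs = base.predict_proba(Z)
        assert np.all(np.diff(probs) >= 0)

    def test_ridge_matches_convex_oracle(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((60, 2))
        y = (Z[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
        lam = 2.0
        base = fit_base(Z, y, BaseLearnerSpec(alpha=0.0, lam=lam, tol=1e-10))
        coef_o, int_o = ridge_logistic_oracle(Z, y, lam)
        np.testing.assert_allclose(base.coef, coef_o, atol=1e-4)
        assert base.intercept == pytest.approx(int_o, abs=1e-4)

    def test_unpenalized_matches_oracle(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((80, 2))
        y = (Z[:, 0] - Z[:, 1] + rng.standard_normal(80) > 0).astype(int)
        base = fit_base(Z, y, BaseLearnerSpec(alpha=0.0, lam=0.0, tol=1e-10))
        coef_o, int_o = ridge_logistic_oracle(Z, y, 0.0)
        np.testing.assert_allclose(base.coef, coef_o, atol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_base(np.zeros((5, 1)), [1, 1, 1, 1, 1], BaseLearnerSpec())


class TestUncertaintyPrediction:
    def test_two_member_mean_and_std(self):
        pred = UncertaintyPrediction.from_members(np.array([[0.4, 0.6]]))
        assert pred.p_mean[0] == pytest.approx(0.5)
        assert pred.p_std[0] == pytest.approx(0.14142, abs=1e-4)

    def test_identical_members_zero_std(self):
        pred = UncertaintyPrediction.from_members(np.full((3, 5), 0.3))
        np.testing.assert_allclose(pred.p_std, 0.0)

    def test_mean_bounded_by_members(self):
        rng = np.random.default_rng(1)
        probs = rng.random((20, 7))
        pred = UncertaintyPrediction.from_members(probs)
        assert np.all(pred.p_mean >= probs.min(axis=1))
        assert np.all(pred.p_mean <= probs.max(axis=1))

    def test_std_bound(self):
        rng = np.random.default_rng(2)
        B = 9
        probs = rng.random((50, B))
        pred = UncertaintyPrediction.from_members(probs)
        assert np.all(pred.p_std <= 0.5 * np.sqrt(B / (B - 1)) + 1e-12)


class TestEnsemble:
    def test_single_member_warns_and_reports_zero_std(self, toy_table):
        model = fit_ensemble(toy_table, None, EnsembleSpec(1, 1.0, seed=0),
                             BaseLearnerSpec())
        with pytest.warns(UserWarning, match="single-member"):
            pred = model.predict(toy_table)
        np.testing.assert_allclose(pred.p_std, 0.0)

    def test_full_fraction_members_agree(self, toy_table):
        # phi = 1 makes every subset identical, hence every member identical
        model = fit_ensemble(toy_table, None, EnsembleSpec(3, 1.0, seed=0),
                             BaseLearnerSpec())
        pred = model.predict(toy_table)
        np.testing.assert_allclose(pred.p_std, 0.0, atol=1e-12)
        single = fit_ensemble(toy_table, None, EnsembleSpec(1, 1.0, seed=0),
                              BaseLearnerSpec())
        with pytest.warns(UserWarning):
            pred1 = single.predict(toy_table)
        np.testing.assert_allclose(pred.p_mean, pred1.p_mean)

    def test_member_count_and_subset_size(self, medium_cohort):
        table = medium_cohort.table
        model = fit_ensemble(table, None, EnsembleSpec(25, 0.95, seed=0),
                             BaseLearnerSpec())
        assert len(model.bases) == 25

    def test_uncertainty_shrinks_as_fraction_grows(self, toy_table):
        low = fit_ensemble(toy_table, None, EnsembleSpec(15, 0.5, seed=0),
                           BaseLearnerSpec())
        high = fit_ensemble(toy_table, None, EnsembleSpec(15, 0.95, seed=0),
                            BaseLearnerSpec())
        assert high.predict(toy_table).p_std.mean() < low.predict(toy_table).p_std.mean()

    def test_json_roundtrip_preserves_predictions(self, toy_table, tmp_path):
        model = fit_ensemble(toy_table, None, EnsembleSpec(4, 0.8, seed=2),
                             BaseLearnerSpec())
        path = tmp_path / "model.json"
        model.save(path)
        loaded = EnsembleModel.load(path)
        np.testing.assert_allclose(loaded.predict(toy_table).p_mean,
                                   model.predict(toy_table).p_mean)


class TestRFE:
    def test_informative_feature_survives_noise_dropped(self):
        rng = np.random.default_rng(1)
        n = 300
        X = pd.DataFrame({"signal": rng.standard_normal(n),
                          **{f"noise{j}": rng.standard_normal(n)
                             for j in range(4)}})
        y = (2.0 * X["signal"] + 0.5 * rng.standard_normal(n) > 0).astype(int)
        table = FeatureTable(X=X, y=pd.Series(y),
                            stage_of={c: 1 for c in X.columns})
        selected = select_features_rfe(table, BaseLearnerSpec(lam=0.3),
                                       seed=1, spatial_sign=False)
        assert selected[0] == "signal"   # informative feature ranked first
        assert len(selected) <= 2        # noise block eliminated

    def test_single_feature_returned_unchanged(self, toy_table):
        assert select_features_rfe(toy_table.with_columns(["a"]),
                                   BaseLearnerSpec()) == ["a"]

    def test_duplicated_informative_feature_keeps_a_copy(self):
        rng = np.random.default_rng(1)
        n = 400
        sig = rng.standard_normal(n)
        X = pd.DataFrame({"s1": sig, "s2": sig + 1e-6 * rng.standard_normal(n),
                          "noise": rng.standard_normal(n)})
        y = (2.0 * sig + 0.5 * rng.standard_normal(n) > 0).astype(int)
        table = FeatureTable(X=X, y=pd.Series(y),
                            stage_of={c: 1 for c in X.columns})
        selected = select_features_rfe(table, BaseLearnerSpec(lam=0.1), seed=0)
        assert "s1" in selected or "s2" in selected


class TestTuneEnsemble:
    def test_single_point_grid_returned(self, toy_table):
        espec, bspec = tune_ensemble(toy_table, None, b_grid=(7,),
                                     phi_grid=(0.8,), alpha_grid=(0.3,),
                                     lambda_grid=(0.5,), inner_folds=3, seed=0)
        assert espec.n_models == 7
        assert espec.sample_fraction == 0.8
        assert bspec.alpha == 0.3 and bspec.lam == 0.5

    def test_empty_grid_rejected(self, toy_table):
        with pytest.raises(ValueError):
            tune_ensemble(toy_table, None, b_grid=(), inner_folds=3)

    def test_selection_stays_on_grid(self, medium_cohort):
        table = medium_cohort.table.with_columns(
            [c for c in medium_cohort.table.feature_names
             if medium_cohort.table.stage_of[c] == 1])
        espec, bspec = tune_ensemble(table, None, b_grid=(5, 10),
                                     phi_grid=(0.7, 0.95), alpha_grid=(0.5,),
                                     lambda_grid=(0.3, 3.0), inner_folds=3, seed=1)
        assert espec.n_models in (5, 10)
        assert espec.sample_fraction in (0.7, 0.95)
        assert bspec.lam in (0.3, 3.0)

    def test_one_se_rule_prefers_regularization_on_flat_auc(self):
        # pure-noise outcome: AUC is flat, so the 1-SE rule picks the
        # largest penalty on the grid
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        y = pd.Series(np.resize([0, 1], 80))
        table = FeatureTable(X=X, y=y, stage_of={c: 1 for c in "abc"})
        _, bspec = tune_ensemble(table, None, b_grid=(5,), phi_grid=(0.8,),
                                 alpha_grid=(0.5,), lambda_grid=(0.1, 10.0),
                                 inner_folds=3, seed=0, one_se_rule=True)
        assert bspec.lam == 10.0
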