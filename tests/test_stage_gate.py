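import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtcascade import (
    BaseLearnerSpec,
    EnsembleSpec,
    GatePolicy,
    cascade_from_predictions,
    fit_ensemble,
    gate_decision,
    predict_cascade,
    roc_auc,
    scaled_weighted_auc,
    scaling_weight_fn,
    split_stages,
)
from crtcascade.ensemble_uq import UncertaintyPrediction
from crtcascade.stage_gate import (
    select_scaling_on_predictions,
    tune_thresholds_on_predictions,
)
from crtcascade.tabular_io import SchemaError


def make_pred(p_mean, p_std):
    p_mean = np.asarray(p_mean, dtype=float)
    p_std = np.asarray(p_std, dtype=float)
    return UncertaintyPrediction(member_probs=p_mean[:, None],
                                 p_mean=p_mean, p_std=p_std)


class TestGateDecision:
    @pytest.mark.parametrize("p_mean,p_std,expected,reason", [
        (0.90, 0.01, False, "none"),        # confident, certain: stays
        (0.52, 0.01, True, "near_midway"),  # close to the 0.5 midpoint
        (0.90, 0.20, True, "high_std"),     # ensemble disagreement
        (0.52, 0.20, True, "both"),
    ])
    def test_rule_clauses(self, p_mean, p_std, expected, reason):
        policy = GatePolicy(0.15, 0.04, 8)  # thresholds seen in practice
        needs, reasons = gate_decision(make_pred([p_mean], [p_std]), policy)
        assert needs[0] == expected
        assert reasons[0] == reason

    def test_strict_inequalities_at_thresholds(self):
        policy = GatePolicy(0.15, 0.04, 1)
        needs, _ = gate_decision(make_pred([0.54, 0.9], [0.01, 0.15]), policy)
        assert not needs.any()  # |0.54-0.5| == tau_m and p_std == tau_sigma


class TestScalingWeight:
    def test_boundaries(self):
        for s in (0.5, 1, 5, 9):
            assert scaling_weight_fn(1.0, s) == 1.0
            assert scaling_weight_fn(0.0, s) == 0.0

    def test_quarter_at_half_scale(self):
        assert scaling_weight_fn(0.25, 0.5) == pytest.approx(0.0625)  # 0.25^2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scaling_weight_fn(1.5, 1.0)
        with pytest.raises(ValueError):
            scaling_weight_fn(0.5, 10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.5, 9), st.floats(0.5, 9))
    def test_monotone_in_both_arguments(self, f1, f2, s1, s2):
        lo_f, hi_f = sorted([f1, f2])
        lo_s, hi_s = sorted([s1, s2])
        assert scaling_weight_fn(lo_f, lo_s) <= scaling_weight_fn(hi_f, lo_s) + 1e-12
        assert scaling_weight_fn(lo_f, lo_s) <= scaling_weight_fn(lo_f, hi_s) + 1e-12


class TestScaledWeightedAUC:
    labels = np.array([0, 1, 0, 1])
    scores = np.array([0.2, 0.3, 0.4, 0.5])  # AUC 0.75 by pair counting

    def test_full_retention_equals_plain_auc(self):
        assert scaled_weighted_auc(self.labels, self.scores, 1.0, 2.0) == \
            pytest.approx(roc_auc(self.labels, self.scores))

    def test_zero_retention_zeroes_objective(self):
        assert scaled_weighted_auc(self.labels, self.scores, 0.0, 2.0) == 0.0

    def test_half_retention_unit_scale(self):
        assert scaled_weighted_auc(self.labels, self.scores, 0.5, 1.0) == \
            pytest.approx(0.75 * 0.5)

    def test_never_exceeds_plain_auc(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = rng.random()
            s = 0.5 + 8.5 * rng.random()
            obj = scaled_weighted_auc(self.labels, self.scores, f, s)
            assert obj <= roc_auc(self.labels, self.scores) + 1e-12
            if f == 1.0:
                assert obj == roc_auc(self.labels, self.scores)


class TestCascadeMonotonicity:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.pred = make_pred(rng.random(100), 0.25 * rng.random(100))

    def test_fraction_kept_monotone_in_std_threshold(self):
        policy = lambda ts, tm: GatePolicy(ts, tm, 1.0)
        fs = []
        for ts in np.linspace(0, 0.3, 10):
            needs, _ = gate_decision(self.pred, policy(ts, 0.05))
            fs.append(1.0 - needs.mean())
        assert np.all(np.diff(fs) >= 0)

    def test_fraction_kept_monotone_in_midway_threshold(self):
        fs = []
        for tm in np.linspace(0, 0.5, 11):
            needs, _ = gate_decision(self.pred, GatePolicy(0.1, tm, 1.0))
            fs.append(1.0 - needs.mean())
        assert np.all(np.diff(fs) <= 0)


class TestTuneThresholds:
    def test_identical_ensembles_escalate_nobody(self):
        rng = np.random.default_rng(1)
        labels = np.resize([0, 1], 40)
        p = make_pred(rng.random(40), 0.1 * rng.random(40))
        policy = tune_thresholds_on_predictions(
            labels, p, p, s=1.0,
            std_grid=(0.02, 0.05, 1.0), midway_grid=(0.0, 0.05, 0.2))
        needs, _ = gate_decision(p, policy)
        assert not needs.any()  # tie-break: keep everyone at stage 1

    def test_policy_lies_on_grid(self):
        rng = np.random.default_rng(2)
        labels = np.resize([0, 1], 60)
        p1 = make_pred(rng.random(60), 0.2 * rng.random(60))
        p2 = make_pred(rng.random(60), 0.2 * rng.random(60))
        std_grid = tuple(np.round(np.arange(0.01, 0.201, 0.01), 2))
        mid_grid = tuple(np.round(np.arange(0.02, 0.101, 0.01), 2))
        policy = tune_thresholds_on_predictions(labels, p1, p2, 2.0,
                                                std_grid, mid_grid)
        assert policy.std_threshold in std_grid
        assert policy.midway_threshold in mid_grid

    def test_matches_exhaustive_grid_oracle(self):
        """A crafted validation set where the stage-2 model resolves an
        ambiguous subgroup: the tuned policy must coincide with independent
        exhaustive enumeration of the grid objective."""
        rng = np.random.default_rng(5)
        n = 80
        ambiguous = np.arange(n) < 30
        labels = np.resize([0, 1], n)
        p1_mean = np.where(ambiguous, 0.5 + 0.02 * rng.standard_normal(n),
                           np.where(labels, 0.85, 0.15))
        p1_std = np.where(ambiguous, 0.2, 0.02)
        p2_mean = np.where(labels, 0.9, 0.1)
        p1 = make_pred(p1_mean, p1_std)
        p2 = make_pred(p2_mean, np.full(n, 0.02))
        s = 2.0
        std_grid = (0.05, 0.10, 0.15)
        mid_grid = (0.02, 0.05, 0.10)
        policy = tune_thresholds_on_predictions(labels, p1, p2, s,
                                                std_grid, mid_grid)

        best = None
        for ts, tm in itertools.product(std_grid, mid_grid):
            cand = GatePolicy(ts, tm, s)
            probs, needs, f = cascade_from_predictions(p1, p2, cand)
            obj = roc_auc(labels, probs) * f ** (1 / s)
            key = (obj, f, ts)
            if best is None or key > best[0]:
                best = (key, cand)
        assert policy == best[1]
        needs, _ = gate_decision(p1, policy)
        assert needs[ambiguous].mean() > 0.9  # the subgroup escalates

    def test_single_class_validation_rejected(self):
        p = make_pred([0.5, 0.6], [0.1, 0.1])
        with pytest.raises(ValueError):
            tune_thresholds_on_predictions(np.array([1, 1]), p, p, 1.0)


class TestSelectScaling:
    def test_single_candidate_returned(self):
        labels = np.resize([0, 1], 20)
        p = make_pred(np.linspace(0.1, 0.9, 20), np.full(20, 0.05))
        cand = GatePolicy(0.1, 0.05, 3.0)
        assert select_scaling_on_predictions(labels, p, p, [cand]) == cand

    def test_tie_prefers_fewer_escalations(self):
        labels = np.resize([0, 1], 20)
        p = make_pred(np.linspace(0.1, 0.9, 20), np.full(20, 0.05))
        keep_all = GatePolicy(1.0, 0.0, 1.0)
        escalate_all = GatePolicy(0.0, 0.5, 1.0)
        # identical predictions: equal AUC; the low-escalation policy wins
        best = select_scaling_on_predictions(labels, p, p,
                                             [escalate_all, keep_all])
        assert best == keep_all


class TestPredictCascade:
    @pytest.fixture
    def fitted(self, medium_cohort):
        table = medium_cohort.table
        s1, s2 = split_stages(table)
        ens1 = fit_ensemble(s1, None, EnsembleSpec(5, 0.8, seed=0),
                            BaseLearnerSpec())
        ens2 = fit_ensemble(s2, None, EnsembleSpec(5, 0.8, seed=1),
                            BaseLearnerSpec())
        return table, s1, s2, ens1, ens2

    def test_keep_all_boundary_equals_ensemble1(self, fitted):
        table, s1, _, ens1, ens2 = fitted
        frame, summary = predict_cascade(ens1, ens2,
                                         GatePolicy(np.inf, 0.0, 1.0), table)
        np.testing.assert_array_equal(frame["final_prob"].to_numpy(),
                                      ens1.predict(s1).p_mean)
        assert summary.fraction_stage1 == 1.0
        assert (frame["stage_used"] == 1).all()

    def test_escalate_all_boundary_equals_ensemble2(self, fitted):
        table, _, s2, ens1, ens2 = fitted
        frame, summary = predict_cascade(ens1, ens2,
                                         GatePolicy(np.inf, 0.5, 1.0), table)
        np.testing.assert_array_equal(frame["final_prob"].to_numpy(),
                                      ens2.predict(s2).p_mean)
        assert summary.fraction_stage1 == 0.0

    def test_mixed_policy_fraction_matches_rule(self, fitted):
        table, s1, _, ens1, ens2 = fitted
        policy = GatePolicy(0.05, 0.08, 1.0)
        frame, summary = predict_cascade(ens1, ens2, policy, table)
        pred1 = ens1.predict(s1)
        needs = (pred1.p_std > policy.std_threshold) | \
                (np.abs(pred1.p_mean - 0.5) < policy.midway_threshold)
        assert summary.fraction_stage1 == pytest.approx(1.0 - needs.mean())
        np.testing.assert_array_equal(frame["stage_used"].to_numpy(),
                                      np.where(needs, 2, 1))

    def test_missing_stage2_features_error_lists_patients(self, fitted):
        table, s1, _, ens1, ens2 = fitted
        with pytest.raises(SchemaError, match="acquisition required"):
            predict_cascade(ens1, ens2, GatePolicy(0.0, 0.5, 1.0), s1)
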