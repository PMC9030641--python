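"""Hierarchical Behavior Learner: inputs, losses, mixing, end-to-end."""

import numpy as np
import pandas as pd
import pytest

from fuzzymoth import behavior, schema, synth
from fuzzymoth.behavior import _fit_mlr


class TestHistoryAccumulation:
    def test_constant_history_is_preserved(self):
        v = np.full(7, 0.3)
        np.testing.assert_allclose(behavior.accumulate_history([v, v, v]), v)

    def test_empty_history_is_zero(self):
        np.testing.assert_array_equal(behavior.accumulate_history([]),
                                      np.zeros(7))

    def test_exponential_weights_most_recent_first(self):
        steps = [np.full(7, 1.0), np.zeros(7), np.zeros(7)]
        out = behavior.accumulate_history(steps)
        np.testing.assert_allclose(out, 4.0 / 7.0)   # weights (4,2,1)/7

    def test_extra_steps_beyond_three_are_ignored(self):
        steps = [np.zeros(7)] * 3 + [np.full(7, 9.0)]
        np.testing.assert_array_equal(behavior.accumulate_history(steps),
                                      np.zeros(7))


class TestInputVector:
    def _record(self, wind=0.5):
        row = {c: 0.5 for c in schema.RECORD_COLUMNS}
        row[schema.AMB_COLS[schema.WIND_IDX[0]]] = wind
        return row

    def test_length_is_eighty(self):
        assert behavior.build_input_vector(self._record()).shape == (80,)

    def test_overcap_wind_rejected(self):
        with pytest.raises(ValueError, match="1.5 m/s"):
            behavior.build_input_vector(self._record(wind=2.0))

    def test_all_minimum_features_normalise_to_zero(self):
        row = {c: 0.0 for c in schema.RECORD_COLUMNS}
        np.testing.assert_array_equal(behavior.build_input_vector(row),
                                      np.zeros(80))

    def test_matrix_and_vector_paths_agree(self, small_records):
        X = behavior.build_input_matrix(small_records.head(5))
        for k in range(5):
            np.testing.assert_allclose(
                X[k], behavior.build_input_vector(small_records.iloc[k]))


class TestWeightedError:
    def test_perfect_prediction(self):
        y = np.random.default_rng(0).random(7)
        assert behavior.weighted_regression_error(y, y) == 0.0

    @pytest.mark.parametrize("dim,expected", [(0, 0.24), (3, 0.15)])
    def test_unit_error_in_single_dimension(self, dim, expected):
        a = np.zeros(7)
        b = np.zeros(7)
        b[dim] = 1.0
        assert behavior.weighted_regression_error(b, a) == pytest.approx(expected)

    def test_matches_hand_summation_on_batch(self):
        pred = np.array([[0.1, 0.2, 0.0, 0.5, 0.5, 0.5, 0.5],
                         [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        act = np.array([[0.2, 0.2, 0.4, 0.5, 0.5, 0.5, 0.5],
                        [0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        w = behavior.OUTPUT_WEIGHTS
        hand = np.mean([w[0] * 0.01 + w[2] * 0.16, w[0] * 0.01])
        assert behavior.weighted_regression_error(pred, act) == pytest.approx(hand)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            behavior.weighted_regression_error(np.zeros(6), np.zeros(6))


class TestGroupMixing:
    def test_one_hot_membership_copies_single_group(self):
        outs = np.random.default_rng(1).random((3, 4, 9))
        u = np.array([0.0, 1.0, 0.0])
        np.testing.assert_array_equal(
            behavior.mix_group_outputs(u, outs), outs[1])

    def test_even_mixture_hand_value(self):
        outs = np.array([[[0.2]], [[0.4]]])
        out = behavior.mix_group_outputs(np.array([0.5, 0.5]), outs)
        assert out[0, 0] == pytest.approx(0.3)

    def test_floor_excludes_weak_groups(self):
        outs = np.array([[[1.0]], [[100.0]]])
        out = behavior.mix_group_outputs(np.array([0.95, 0.05]), outs,
                                         u_floor=0.1)
        assert out[0, 0] == pytest.approx(0.95)

    def test_no_group_above_floor_rejected(self):
        with pytest.raises(ValueError):
            behavior.mix_group_outputs(np.array([0.05, 0.05]),
                                       np.zeros((2, 1, 9)), u_floor=0.1)

    def test_renormalized_mixture(self):
        outs = np.array([[[0.2]], [[0.4]]])
        out = behavior.mix_group_outputs(np.array([0.4, 0.4]), outs,
                                         renormalize=True)
        assert out[0, 0] == pytest.approx(0.3)


class TestMLRHead:
    def test_exact_recovery_of_linear_ground_truth(self):
        rng = np.random.default_rng(2)
        Z = rng.random((50, 7))
        C = rng.standard_normal((7, 7))
        b = rng.standard_normal(7)
        coef, intercept = _fit_mlr(Z, Z @ C + b)
        np.testing.assert_allclose(coef, C, atol=1e-8)
        np.testing.assert_allclose(intercept, b, atol=1e-8)

    def test_rank_deficient_design_falls_back_to_ridge(self):
        Z = np.ones((10, 3))          # rank 1
        Y = np.random.default_rng(3).random((10, 2))
        coef, intercept = _fit_mlr(Z, Y)
        assert np.isfinite(coef).all() and np.isfinite(intercept).all()


class TestParameterCounting:
    def test_stack_parameter_count(self):
        # (4*6+4+6) for 6->4 plus (2*4+2+4) for 4->2
        assert behavior.count_fuzzy_params((6, 4, 2)) == 34 + 14

    def test_matched_monolith_is_close_to_hierarchy(self):
        widths = behavior.monolithic_widths_matching(3, 12)
        target = (behavior.count_fuzzy_params((80, 46, 26))
                  + 3 * behavior.count_fuzzy_params((26, 15, 9))
                  + 12 * behavior.count_fuzzy_params((9, 6, 7)))
        got = behavior.count_fuzzy_params(widths)
        assert abs(got - target) / target < 0.1


@pytest.fixture(scope="module")
def fitted(small_cohort, small_records, small_probes):
    amb, stim, resp = small_probes
    m = behavior.HierarchicalBehaviorLearner(
        n_groups=3, budget_common=60, budget_group=40,
        budget_individual=30, cluster_budget=40, random_state=0)
    return m.fit(small_records, shapes=small_cohort.shapes,
                 probe_resp=resp, probe_amb=amb, probe_stim=stim)


class TestEndToEnd:
    def test_shape_contract(self, fitted):
        assert [l.d_out for l in fitted.common_.layers_] == [46, 26]
        for gs in fitted.group_stacks_:
            assert [l.d_out for l in gs.layers_] == [15, 9]
        for st, coef, _ in fitted.individual_.values():
            assert [l.d_out for l in st.layers_] == [6, 7]
            assert coef.shape == (7, 7)

    def test_profile_dimension(self, fitted, small_cohort):
        # 3 shape descriptors + 36 probes x topmost width 26
        assert fitted.profiles_.shape == (6, 3 + 36 * 26)

    def test_predictions_are_deterministic_and_bounded(self, fitted,
                                                       small_records):
        a = fitted.predict(small_records)
        b = fitted.predict(small_records)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (len(small_records), 7)
        assert (a >= 0).all() and (a <= 1).all()

    def test_unknown_moth_rejected(self, fitted, small_records):
        bad = small_records.copy()
        bad.loc[bad.index[0], "id"] = 999
        with pytest.raises(ValueError, match="unknown moth"):
            fitted.predict(bad)

    def test_training_errors_recorded_per_moth(self, fitted, small_cohort):
        assert set(fitted.training_errors_) == {m.id for m in
                                                small_cohort.moths}
        assert all(e >= 0 for e in fitted.training_errors_.values())

    def test_missing_probe_responses_rejected(self, small_records):
        m = behavior.HierarchicalBehaviorLearner(n_groups=2, budget_common=60,
                                                 random_state=0)
        with pytest.raises(ValueError, match="probe"):
            m.fit(small_records)
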