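"""Plasticity rules: traces, rewarded updates, scaling, freezing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnus.config import HomeostasisParams, StdpParams
from somnus.plasticity import (TraceBuffer, WeightState,
                               apply_rewarded_update,
                               apply_unsupervised_stdp, compute_trace,
                               freeze_top_fraction, heterosynaptic_rescale,
                               homeostatic_scale, inhibitory_balance,
                               pairing_traces)


@pytest.fixture
def stdp():
    return StdpParams()


def make_weights(n_h=6, n_o=4, w0=0.1):
    w_ho = np.full((n_h, n_o), w0)
    return WeightState(
        w_ih=np.full((n_h, 3), 0.2),
        w_ho=w_ho,
        wi_ho=-np.full((n_h, n_o), w0),
        w_j0=w_ho.sum(axis=0),
        w_i0=w_ho.sum(axis=1),
        w_ih_target=np.full(n_h, 0.6),
        frozen_mask=np.zeros((n_h, n_o), dtype=bool),
    )


class TestTrace:
    def test_simultaneous_pairing_is_positive_maximum(self, stdp):
        assert compute_trace(0.0, 0.0, stdp) == pytest.approx(0.04)

    def test_closed_form_pre_before_post(self, stdp):
        # dt = Tc = 40 ms -> K * e^-1
        assert compute_trace(0.0, 40.0, stdp) == pytest.approx(
            0.04 * np.exp(-1.0), abs=1e-12)

    def test_closed_form_post_before_pre(self, stdp):
        # post 10 ms before pre -> -K * e^-0.25
        assert compute_trace(10.0, 0.0, stdp) == pytest.approx(
            -0.04 * np.exp(-0.25), abs=1e-12)

    def test_pairing_matrix_window_and_signs(self, stdp):
        tr = pairing_traces([0, 200], [10, 130], stdp, dt_ms=0.5)
        assert tr.shape == (2, 2)
        assert tr[0, 0] == pytest.approx(0.04 * np.exp(-5.0 / 40.0))
        assert tr[0, 1] == 0.0                       # 130 steps > window
        assert tr[1, 0] == 0.0                       # -190 steps, outside
        assert tr[1, 1] == pytest.approx(-0.04 * np.exp(-35.0 / 40.0))

    @settings(max_examples=50, deadline=None)
    @given(dt=st.integers(-120, 120))
    def test_property_magnitude_bounded_and_sign_matches_order(self, dt):
        stdp = StdpParams()
        tr = pairing_traces([100], [100 + dt], stdp, dt_ms=0.5)[0, 0]
        assert abs(tr) <= stdp.k + 1e-15
        if dt >= 0:
            assert tr > 0
        else:
            assert tr < 0


class TestUnsupervised:
    def test_zero_trace_leaves_weight(self, stdp):
        w = np.array([[0.5, 0.2]])
        apply_unsupervised_stdp(w, np.array([0]), np.array([0]),
                                np.array([0.0]), stdp)
        assert w[0, 0] == 0.5

    def test_repeated_causal_pairing_monotone_growth(self, stdp):
        w = np.array([[0.1]])
        prev = w[0, 0]
        for _ in range(30):
            apply_unsupervised_stdp(w, np.array([0]), np.array([0]),
                                    np.array([0.04]), stdp)
            assert w[0, 0] > prev
            prev = w[0, 0]

    def test_depression_on_zero_weight_stays_zero(self, stdp):
        w = np.array([[0.0]])
        apply_unsupervised_stdp(w, np.array([0]), np.array([0]),
                                np.array([-0.04]), stdp)
        assert w[0, 0] == 0.0

    def test_additive_mode(self):
        stdp = StdpParams(unsupervised_mode="additive")
        w = np.array([[0.1]])
        apply_unsupervised_stdp(w, np.array([0]), np.array([0]),
                                np.array([0.03]), stdp)
        assert w[0, 0] == pytest.approx(0.13)


class TestRewardedUpdate:
    def test_no_live_traces_decays_average(self, stdp):
        weights = make_weights()
        avg = apply_rewarded_update(weights, TraceBuffer(), 1.0, 10, 0.5, stdp)
        assert avg == pytest.approx(0.5 * (1 - stdp.delta))
        assert np.all(weights.w_ho == 0.1)

    def test_zero_reward_leaves_weights_exactly(self, stdp):
        weights = make_weights()
        buf = TraceBuffer()
        buf.add(np.array([0, 5]), np.array([0.04, -0.02]), epoch=9)
        before = weights.w_ho.copy()
        apply_rewarded_update(weights, buf, 0.0, 10, 0.5, stdp)
        assert np.array_equal(weights.w_ho, before)

    def test_single_trace_closed_form_multiplier(self, stdp):
        # one trace tr=0.04 aged 1 epoch, c=1 -> discounted 0.02; with
        # Avg_tr equal to that sum and W_i = W_i0 the multiplier is
        # exactly 1 + S_rp * 0.02.
        weights = make_weights()
        buf = TraceBuffer()
        buf.add(np.array([0]), np.array([0.04]), epoch=9)
        s_rp = 1.0
        apply_rewarded_update(weights, buf, s_rp, 10, avg_tr=0.02,
                              params=stdp)
        assert weights.w_ho[0, 0] == pytest.approx(0.1 * 1.02, rel=1e-12)
        assert np.all(weights.w_ho.ravel()[1:] == 0.1)

    def test_trace_lifetime_respected(self, stdp):
        weights = make_weights()
        buf = TraceBuffer()
        buf.add(np.array([0]), np.array([0.04]), epoch=0)
        # age 6 epochs: stored traces no longer act
        before = weights.w_ho.copy()
        apply_rewarded_update(weights, buf, 1.0, 6, 0.02, stdp)
        assert len(buf) == 0
        assert np.array_equal(weights.w_ho, before)
        # age 5: still live
        buf.add(np.array([0]), np.array([0.04]), epoch=0)
        apply_rewarded_update(weights, buf, 1.0, 5, 0.02, stdp)
        assert weights.w_ho[0, 0] > 0.1

    def test_depression_cannot_kill_synapse(self, stdp):
        weights = make_weights()
        buf = TraceBuffer()
        for t in range(5):
            buf.add(np.array([0, 0, 0]), np.array([0.04, 0.04, 0.03]), epoch=9)
        apply_rewarded_update(weights, buf, -5.0, 10, 1e-4, stdp)
        # floored at w_floor_frac of the mean column weight, not zero
        assert weights.w_ho[0, 0] > 0.0

    def test_avg_tracks_sum(self, stdp):
        weights = make_weights()
        buf = TraceBuffer()
        buf.add(np.array([0]), np.array([0.04]), epoch=10)
        avg = apply_rewarded_update(weights, buf, 0.0, 10, 0.5, stdp)
        sum_tr = 0.04 / (0 + stdp.c)
        assert avg == pytest.approx(0.5 * (1 - stdp.delta)
                                    + stdp.delta * sum_tr)


class TestScalingRules:
    def test_heterosynaptic_restores_column_sums(self, rng):
        weights = make_weights()
        weights.w_ho += rng.random(weights.w_ho.shape) * 0.05
        heterosynaptic_rescale(weights)
        assert np.allclose(weights.w_ho.sum(axis=0), weights.w_j0, rtol=1e-12)

    def test_already_normalized_column_unchanged(self):
        weights = make_weights()
        before = weights.w_ho.copy()
        heterosynaptic_rescale(weights)
        assert np.allclose(weights.w_ho, before, rtol=1e-12)

    def test_doubling_one_weight_preserves_proportions(self):
        weights = make_weights()
        weights.w_ho[2, 1] *= 2
        heterosynaptic_rescale(weights)
        col = weights.w_ho[:, 1]
        assert col.sum() == pytest.approx(weights.w_j0[1])
        others = np.delete(col, 2)
        assert np.allclose(others, others[0])
        assert col[2] == pytest.approx(2 * others[0])

    def test_zero_column_skipped_and_flagged(self):
        weights = make_weights()
        weights.w_ho[:, 3] = 0.0
        skipped = heterosynaptic_rescale(weights)
        assert skipped == [3]

    def test_inhibitory_equals_negative_row_mean(self):
        weights = make_weights()
        weights.w_ho[1] = [0.1, 0.2, 0.3, 0.4]
        inhibitory_balance(weights)
        assert np.allclose(weights.wi_ho[1], -0.25)
        assert np.allclose(weights.wi_ho[0], -0.1)   # uniform row -> -w

    def test_homeostatic_target_compounds_closed_form(self):
        weights = make_weights()
        params = HomeostasisParams(d_tar=0.001, target_rate=1.0)
        w_j0_start = weights.w_j0.copy()
        for _ in range(10):
            homeostatic_scale(weights, np.zeros(4), params)   # rate < target
        assert np.allclose(weights.w_j0, w_j0_start * 1.001 ** 10, rtol=1e-12)
        assert np.allclose(weights.w_ho.sum(axis=0), weights.w_j0)

    def test_homeostatic_equal_rate_leaves_target(self):
        weights = make_weights()
        params = HomeostasisParams(d_tar=0.001, target_rate=1.0)
        before = weights.w_j0.copy()
        homeostatic_scale(weights, np.ones(4), params)
        assert np.array_equal(weights.w_j0, before)


class TestFreezing:
    def test_fraction_bounds(self):
        w = np.arange(12, dtype=float).reshape(3, 4)
        assert freeze_top_fraction(w, 0.0).sum() == 0
        assert freeze_top_fraction(w, 1.0).all()

    def test_floor_count_rule(self, rng):
        w = rng.random((784, 8))
        mask = freeze_top_fraction(w, 0.1)
        assert mask.sum() == 627    # floor(0.1 * 6272)

    def test_ties_broken_by_index(self):
        w = np.ones((2, 3))
        mask = freeze_top_fraction(w, 0.5)       # floor(0.5*6) = 3
        assert mask.ravel().tolist() == [True, True, True, False, False, False]

    def test_frozen_synapses_immutable_under_all_rules(self, stdp, rng):
        weights = make_weights()
        weights.w_ho += rng.random(weights.w_ho.shape) * 0.01
        weights.frozen_mask = freeze_top_fraction(weights.w_ho, 0.25)
        frozen_vals = weights.w_ho[weights.frozen_mask].copy()
        buf = TraceBuffer()
        buf.add(np.arange(24), rng.uniform(-0.04, 0.04, 24), epoch=9)
        apply_rewarded_update(weights, buf, 1.0, 10, 0.02, stdp)
        heterosynaptic_rescale(weights)
        homeostatic_scale(weights, np.zeros(4), HomeostasisParams())
        assert np.array_equal(weights.w_ho[weights.frozen_mask], frozen_vals)

    def test_full_freeze_training_is_identity(self, stdp, rng):
        weights = make_weights()
        weights.frozen_mask[:] = True
        before = weights.w_ho.copy()
        buf = TraceBuffer()
        buf.add(np.arange(10), rng.uniform(-0.04, 0.04, 10), epoch=9)
        apply_rewarded_update(weights, buf, 1.0, 10, 0.02, stdp)
        heterosynaptic_rescale(weights)
        assert np.array_equal(weights.w_ho, before)


def test_sign_discipline_preserved_under_random_updates(rng, stdp):
    weights = make_weights()
    for t in range(20):
        buf = TraceBuffer()
        buf.add(rng.integers(0, 24, 30), rng.uniform(-0.04, 0.04, 30),
                epoch=t)
        apply_rewarded_update(weights, buf, rng.choice([1.0, -0.001, -0.0001]),
                              t, 0.02, stdp)
        heterosynaptic_rescale(weights)
        inhibitory_balance(weights)
        assert np.all(weights.w_ho >= 0)
        assert np.all(weights.wi_ho <= 0)
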