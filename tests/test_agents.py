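"""Mixture-of-agents learning and choice rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sailrl import agents
from sailrl.agents import AgentParams, initial_state
from sailrl.task import TrialRecord


def make_params(**kw):
    return AgentParams(**kw)


class TestBoatValueUpdate:
    @pytest.mark.parametrize(
        "v0,alpha,reward,expected",
        [(0.5, 0.2, 1, 0.6), (0.5, 0.2, 0, 0.4), (0.123, 0.999999, 1, 0.999999 + 0.123e-6)],
    )
    def test_delta_rule(self, v0, alpha, reward, expected):
        st_ = initial_state()
        st_.v_boat[2] = v0
        p = make_params(alpha_A=alpha)
        out = agents.update_boat_value(st_, 2, reward, "traversal", p)
        assert out.v_boat[2] == pytest.approx(expected, abs=1e-9)
        # other boats untouched
        np.testing.assert_array_equal(out.v_boat[[0, 1, 3]], st_.v_boat[[0, 1, 3]])

    def test_passive_rate_used_on_nontraversal(self):
        p = make_params(alpha_A=0.9, alpha_P=0.1)
        st_ = initial_state()
        out = agents.update_boat_value(st_, 0, 1, "nontraversal", p)
        assert out.v_boat[0] == pytest.approx(0.55)


class TestChoiceProbs:
    def test_symmetric_values_give_uniform(self):
        p = make_params(beta_boat=3.0)
        probs = agents.boat_choice_probs(initial_state(), 0, p)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_logistic_oracle_boat(self):
        st_ = initial_state()
        st_.v_boat[:2] = [0.6, 0.4]
        p = make_params(beta_boat=2.0)
        expected = 1.0 / (1.0 + np.exp(-2.0 * 0.2))
        assert agents.boat_choice_probs(st_, 0, p)[0] == pytest.approx(expected, abs=1e-6)

    def test_persistence_dominates_at_high_weight(self):
        st_ = initial_state()
        st_.last_boat[0] = 0
        p = make_params(beta_boat=0.0, beta_persist_boat=50.0)
        assert agents.boat_choice_probs(st_, 0, p)[0] > 0.999999

    def test_island_uniform_when_all_betas_zero(self):
        p = make_params(beta_boat=0.0, beta_MB=0.0, beta_SR=0.0, beta_TD=0.0)
        np.testing.assert_allclose(agents.island_choice_probs(initial_state(), p), [0.5, 0.5])

    def test_island_logistic_oracle_mb_only(self):
        st_ = initial_state()
        st_.v_boat[:] = [0.9, 0.1, 0.675, 0.2]  # maxima 0.9 and 0.675
        p = make_params(beta_MB=2.0, beta_SR=0.0, beta_TD=0.0)
        expected = 1.0 / (1.0 + np.exp(-2.0 * (0.9 - 0.675)))
        assert agents.island_choice_probs(st_, p)[0] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.612, abs=0.002)


class TestValuations:
    def test_mb_is_per_island_max(self):
        st_ = initial_state()
        st_.v_boat[:] = [0.3, 0.7, 0.2, 0.9]
        np.testing.assert_allclose(agents.mb_island_values(st_), [0.7, 0.9])

    def test_sr_one_hot_row_reads_single_boat(self):
        st_ = initial_state()
        st_.v_boat[:] = [0.2, 0.8, 0.5, 0.5]
        st_.m_sr[0] = [1.0, 0.0, 0.0, 0.0]
        assert agents.sr_island_values(st_)[0] == pytest.approx(0.2)

    def test_sr_uniform_row_is_mean(self):
        st_ = initial_state()
        st_.v_boat[:] = [0.2, 0.8, 0.5, 0.5]
        assert agents.sr_island_values(st_)[0] == pytest.approx(0.5)

    def test_sr_never_exceeds_mb(self, rng):
        for _ in range(50):
            st_ = initial_state()
            st_.v_boat[:] = rng.random(4)
            w = rng.random(2)
            st_.m_sr[0, :2] = [w[0], 1 - w[0]]
            st_.m_sr[1, 2:] = [w[1], 1 - w[1]]
            assert np.all(agents.sr_island_values(st_) <= agents.mb_island_values(st_) + 1e-12)


class TestSRUpdate:
    def test_row_update_values(self):
        p = make_params(alpha_M=0.1)
        out = agents.sr_update_M(initial_state(), 0, 0, p)
        np.testing.assert_allclose(out.m_sr[0], [0.55, 0.45, 0.0, 0.0])
        np.testing.assert_allclose(out.m_sr[1], [0.0, 0.0, 0.5, 0.5])

    def test_full_rate_gives_one_hot(self):
        p = make_params(alpha_M=1 - 1e-12)
        out = agents.sr_update_M(initial_state(), 1, 3, p)
        np.testing.assert_allclose(out.m_sr[1], [0, 0, 0, 1], atol=1e-9)

    def test_repeated_choice_converges_monotonically(self):
        p = make_params(alpha_M=0.3)
        st_ = initial_state()
        prev = st_.m_sr[0, 0]
        for _ in range(30):
            st_ = agents.sr_update_M(st_, 0, 0, p)
            assert st_.m_sr[0, 0] > prev
            prev = st_.m_sr[0, 0]
        assert prev > 0.999

    def test_wrong_island_rejected(self):
        with pytest.raises(ValueError, match="not on island"):
            agents.sr_update_M(initial_state(), 0, 2, make_params())


class TestTDUpdate:
    def test_convex_step_toward_boat_value(self):
        st_ = initial_state()
        st_.v_boat[1] = 0.9
        p = make_params(alpha_A=0.25)
        out = agents.td_update(st_, 0, 1, p)
        assert out.v_td[0] == pytest.approx(0.6)
        assert out.v_td[1] == st_.v_td[1]

    def test_full_rate_copies_boat_value(self):
        st_ = initial_state()
        st_.v_boat[2] = 0.77
        p = make_params(alpha_A=1 - 1e-12)
        assert agents.td_update(st_, 1, 2, p).v_td[1] == pytest.approx(0.77)


class TestStepTrial:
    def test_nontraversal_leaves_model_state_untouched(self):
        p = make_params()
        st_ = initial_state()
        rec = TrialRecord("s", 0, "nontraversal", 0, "initial", None, 2, 1)
        out = agents.step_trial(st_, rec, p)
        np.testing.assert_array_equal(out.m_sr, st_.m_sr)
        np.testing.assert_array_equal(out.v_td, st_.v_td)
        assert out.last_island == st_.last_island
        assert out.v_boat[2] != st_.v_boat[2]

    def test_traversal_updates_exactly_one_of_each(self):
        p = make_params()
        st_ = initial_state()
        rec = TrialRecord("s", 0, "traversal", 0, "initial", 1, 3, 1)
        out = agents.step_trial(st_, rec, p)
        assert np.sum(out.v_boat != st_.v_boat) == 1
        assert np.any(out.m_sr[1] != st_.m_sr[1]) and np.all(out.m_sr[0] == st_.m_sr[0])
        assert out.v_td[1] != st_.v_td[1] and out.v_td[0] == st_.v_td[0]
        assert out.last_island == 1 and out.last_boat[1] == 3

    def test_td_bootstraps_from_updated_boat_value(self):
        # after the boat update V(3) = 0.5 + alpha*(1-0.5); TD must use it
        p = make_params(alpha_A=0.5)
        rec = TrialRecord("s", 0, "traversal", 0, "initial", 1, 3, 1)
        out = agents.step_trial(initial_state(), rec, p)
        assert out.v_boat[3] == pytest.approx(0.75)
        assert out.v_td[1] == pytest.approx(0.5 * 0.5 + 0.5 * 0.75)

    def test_replay_is_deterministic(self, rng):
        p = make_params()
        recs = []
        for i in range(10):
            isl = int(rng.integers(2))
            recs.append(TrialRecord("s", i, "traversal", 0, "initial",
                                    isl, 2 * isl + int(rng.integers(2)), int(rng.integers(2))))
            recs.append(TrialRecord("s", i, "nontraversal", 0, "initial",
                                    None, int(rng.integers(4)), int(rng.integers(2))))
        final = []
        for _ in range(2):
            st_ = initial_state()
            for rec in recs:
                st_ = agents.step_trial(st_, rec, p)
            final.append(st_)
        np.testing.assert_array_equal(final[0].v_boat, final[1].v_boat)
        np.testing.assert_array_equal(final[0].m_sr, final[1].m_sr)
        np.testing.assert_array_equal(final[0].v_td, final[1].v_td)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_state_invariants_hold_after_random_sequences(seed):
    """M rows stay normalized and values bounded through arbitrary play."""
    rng = np.random.default_rng(seed)
    p = AgentParams(
        alpha_A=rng.uniform(0.05, 0.95),
        alpha_P=rng.uniform(0.05, 0.95),
        alpha_M=rng.uniform(0.05, 0.95),
    )
    st_ = initial_state()
    for i in range(60):
        if rng.random() < 0.5:
            isl = int(rng.integers(2))
            rec = TrialRecord("s", i, "traversal", 0, "initial",
                              isl, 2 * isl + int(rng.integers(2)), int(rng.integers(2)))
        else:
            rec = TrialRecord("s", i, "nontraversal", 0, "initial",
                              None, int(rng.integers(4)), int(rng.integers(2)))
        st_ = agents.step_trial(st_, rec, p)
        np.testing.assert_allclose(st_.m_sr.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((st_.v_boat >= 0) & (st_.v_boat <= 1))
        assert np.all((st_.v_td >= 0) & (st_.v_td <= 1))
        probs = agents.island_choice_probs(st_, p)
        assert probs.sum() == pytest.approx(1.0)


class TestOneTrialBackSignatures:
    def test_mb_insensitive_when_neighbor_dominates(self):
        """Max-based valuation ignores a sampled boat's reward whenever the
        neighboring boat's value exceeds anything the sample could reach."""
        p = make_params(beta_MB=3.0, beta_SR=0.0, beta_TD=0.0, alpha_P=0.3)
        base = initial_state()
        base.v_boat[:] = [0.1, 0.9, 0.5, 0.5]  # neighbor 0.9 > max attainable 0.37
        out = {}
        for r in (0, 1):
            st_ = agents.update_boat_value(base, 0, r, "nontraversal", p)
            out[r] = agents.island_choice_probs(st_, p)
        np.testing.assert_allclose(out[0], out[1])

    def test_sr_insensitive_with_zero_occupancy(self):
        """Occupancy-weighted valuation ignores rewards of boats the policy
        never visits."""
        p = make_params(beta_MB=0.0, beta_SR=3.0, beta_TD=0.0, alpha_P=0.3)
        base = initial_state()
        base.m_sr[0] = [0.0, 1.0, 0.0, 0.0]  # no mass on boat 0
        out = {}
        for r in (0, 1):
            st_ = agents.update_boat_value(base, 0, r, "nontraversal", p)
            out[r] = agents.island_choice_probs(st_, p)
        np.testing.assert_allclose(out[0], out[1])
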