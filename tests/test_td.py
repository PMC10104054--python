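"""LSTD, TD errors, and RPE summaries against closed-form oracles."""

import numpy as np
import pytest

from beliefrnn.beliefs import build_starkweather_space, run_beliefs
from beliefrnn.tasks import BabayanConfig, StarkweatherConfig, generate_session
from beliefrnn.td import (
    RankDeficientRepresentation,
    bellman_values,
    lstd_fit,
    reward_time_rpes,
    rpe_mse,
    rpe_summaries,
    td_errors,
)

GAMMA = 0.93


class TestLstd:
    def test_recovers_bellman_values_on_task1_beliefs(self, space1):
        """LSTD on (point-mass) beliefs converges to the linear Bellman solve."""
        V = bellman_values(space1, GAMMA)
        devs = []
        for n in (500, 4000):
            s = generate_session(StarkweatherConfig(variant=1), n, 123)
            B = run_beliefs(space1, s)
            readout = lstd_fit(B, s.reward, GAMMA, name="beliefs")
            dev = np.abs(readout.values(B) - V[s.states]).max()
            devs.append(dev)
        assert devs[-1] < 0.02
        assert devs[-1] < devs[0]  # error shrinks with session length

    def test_zero_rewards_give_zero_weights(self, rng):
        Z = rng.normal(size=(200, 4))
        readout = lstd_fit(Z, np.zeros(200), GAMMA)
        assert np.allclose(readout.w, 0) and readout.w0 == pytest.approx(0.0)

    def test_gamma_zero_reduces_to_regression_on_next_reward(self, rng):
        Z = rng.normal(size=(400, 3))
        r = rng.normal(size=400)
        readout = lstd_fit(Z, r, 0.0)
        # OLS of r_{t+1} on [z_t, 1]
        A = np.hstack([Z[:-1], np.ones((399, 1))])
        coef, *_ = np.linalg.lstsq(A, r[1:], rcond=None)
        assert np.allclose(np.append(readout.w, readout.w0), coef, atol=1e-8)

    def test_collinear_but_consistent_system_is_solved(self, space2, session2):
        # beliefs sum to one, so beliefs + intercept are exactly collinear;
        # the TD system is still consistent and must be solved, not rejected
        B = run_beliefs(space2, session2)
        readout = lstd_fit(B, session2.reward, GAMMA, name="beliefs")
        assert np.isfinite(readout.w).all()

    def test_inconsistent_singular_system_raises(self, rng):
        # a trace growing exactly as gamma^(-t) makes z_t - gamma*z_{t+1} = 0,
        # so that feature's moment matrix column vanishes while d does not
        t = np.arange(20)
        Z = (GAMMA ** (-t.astype(float)))[:, None]
        r = rng.normal(size=20)
        with pytest.raises(RankDeficientRepresentation):
            lstd_fit(Z, r, GAMMA)

    def test_ridge_option_handles_degenerate_representation(self, rng):
        Z = np.zeros((100, 2))
        r = rng.normal(size=100)
        readout = lstd_fit(Z, r, GAMMA, ridge=1e-6)
        assert np.isfinite(readout.w).all()

    def test_mean_td_error_is_zero_with_true_values(self, space1):
        s = generate_session(StarkweatherConfig(variant=1), 5000, 3)
        V = bellman_values(space1, GAMMA)
        values = V[s.states]
        delta = td_errors(values, s.reward, GAMMA)
        se = delta.std() / np.sqrt(len(delta))
        assert abs(delta.mean()) < 3 * se


class TestTdErrors:
    def test_constant_value_zero_reward_algebra(self):
        values = np.full(50, 2.0)
        delta = td_errors(values, np.zeros(50), GAMMA)
        assert np.allclose(delta, (GAMMA - 1) * 2.0)
        assert (delta < 0).all()

    def test_length_is_t_minus_one(self, rng):
        delta = td_errors(rng.normal(size=30), rng.normal(size=30), GAMMA)
        assert len(delta) == 29

    def test_constant_value_offset_shifts_rpes_exactly(self, space2, session2):
        """A value trace offset by c changes every delta by (gamma-1)c."""
        B = run_beliefs(space2, session2)
        readout = lstd_fit(B, session2.reward, GAMMA, name="beliefs")
        values = readout.values(B)
        d0 = td_errors(values, session2.reward, GAMMA)
        c = 1.7
        d1 = td_errors(values + c, session2.reward, GAMMA)
        assert np.allclose(d1 - d0, (GAMMA - 1) * c)
        t0 = reward_time_rpes(session2, d0)
        t1 = reward_time_rpes(session2, d1)
        assert rpe_mse(t1, t0) == pytest.approx(((1 - GAMMA) * c) ** 2)

    def test_rpe_mse_identity_is_zero(self, space2, session2):
        B = run_beliefs(space2, session2)
        readout = lstd_fit(B, session2.reward, GAMMA, name="beliefs")
        delta = td_errors(readout.values(B), session2.reward, GAMMA)
        trace = reward_time_rpes(session2, delta)
        assert rpe_mse(trace, trace) == 0.0

    def test_rpe_mse_requires_rewarded_trials(self):
        with pytest.raises(ValueError):
            rpe_mse(np.array([]), np.array([]))


def _belief_rpe_curve(variant, n_trials=4000, seed=0):
    space = build_starkweather_space(variant)
    s = generate_session(StarkweatherConfig(variant=variant), n_trials, seed)
    B = run_beliefs(space, s)
    readout = lstd_fit(B, s.reward, GAMMA, name="beliefs")
    delta = td_errors(readout.values(B), s.reward, GAMMA)
    return rpe_summaries(s, delta)


class TestRpePatterns:
    """Reward-time dependence of belief-model RPEs.

    With a rising reward hazard and no omissions, late rewards are almost
    fully predicted, so the RPE at reward falls with reward time (to
    exactly 0 at the last possible reward time).  With 10% omissions the
    posterior drifts toward the omission interpretation as time passes, so
    sufficiently late rewards become *more* surprising than early ones.
    """

    def test_deterministic_task_rpe_decreases_with_reward_time(self):
        curve = _belief_rpe_curve(1)
        means = curve.sort_values("group")["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)
        assert means[-1] == pytest.approx(0.0, abs=0.02)

    def test_omission_task_rpe_rises_at_late_reward_times(self):
        curve = _belief_rpe_curve(2)
        means = curve.sort_values("group")["mean"].to_numpy()
        # late rewards (arriving when omission is the likelier explanation)
        # carry larger RPEs than mid-range ones and than the earliest ones
        assert means[-1] > means[0] > means[4]
        assert np.all(np.diff(means[-4:]) > 0)

    def test_single_isi_task_curve_has_one_point(self):
        cfg = StarkweatherConfig(isi_min=10, isi_max=10, variant=1)
        space = build_starkweather_space(cfg)
        s = generate_session(cfg, 300, 1)
        B = run_beliefs(space, s)
        readout = lstd_fit(B, s.reward, GAMMA, name="beliefs")
        delta = td_errors(readout.values(B), s.reward, GAMMA)
        curve = rpe_summaries(s, delta)
        assert len(curve) == 1
        trace = reward_time_rpes(s, delta)
        assert curve["mean"].iloc[0] == pytest.approx(trace.reward_time_rpes.mean())


class TestBabayanRpes:
    def test_block_transition_modulates_reward_rpe(self, space_b):
        """After a 1->10 block switch, the first large reward is a surprise;
        by trial 5 the block is known and the RPE has shrunk."""
        s = generate_session(BabayanConfig(), 3000, 17)
        B = run_beliefs(space_b, s)
        readout = lstd_fit(B, s.reward, GAMMA, name="beliefs")
        delta = td_errors(readout.values(B), s.reward, GAMMA)
        summ = rpe_summaries(s, delta)
        rew = summ[(summ["event"] == "reward") & (summ["current_reward"] == 10.0)]
        first = rew.loc[rew["trial_in_block"] == 1, "mean"].iloc[0]
        last = rew.loc[rew["trial_in_block"] == 5, "mean"].iloc[0]
        assert first > last

    def test_summary_is_tidy(self, space_b, session_b):
        B = run_beliefs(space_b, session_b)
        readout = lstd_fit(B, session_b.reward, GAMMA, name="beliefs")
        delta = td_errors(readout.values(B), session_b.reward, GAMMA)
        summ = rpe_summaries(session_b, delta)
        assert {"event", "trial_in_block", "current_reward", "mean", "sem", "n"} <= set(summ.columns)
        assert set(summ["event"]) == {"odor", "reward"}
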