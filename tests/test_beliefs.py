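"""Belief filtering vs. an independent forward-algorithm oracle, and
structural checks on the micro-state spaces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beliefrnn.beliefs import (
    BlockBelief,
    ImpossibleObservation,
    babayan_belief_step,
    belief_step,
    block_likelihood,
    build_starkweather_space,
    run_beliefs,
)
from beliefrnn.tasks import StarkweatherConfig, generate_session


def forward_oracle(space, b0, kinds):
    """Brute-force forward filter: explicit nested sums, no matrix algebra."""
    K = space.K
    b = np.array(b0, dtype=float)
    out = []
    for kind in kinds:
        new = np.zeros(K)
        for kp in range(K):
            acc = 0.0
            for k in range(K):
                acc += space.O[kind][kp, k] * space.T[kp, k] * b[k]
            new[kp] = acc
        s = new.sum()
        if s <= 0:
            raise ImpossibleObservation(kind)
        b = new / s
        out.append(b.copy())
    return np.array(out)


class TestSpaces:
    def test_state_counts(self, space1, space2, space_b):
        assert space1.K == 25 and space2.K == 25
        assert space_b.K == 22

    @pytest.mark.parametrize("which", ["space1", "space2", "space_b"])
    def test_transition_and_emission_stochasticity(self, which, request):
        space = request.getfixturevalue(which)
        assert np.allclose(space.T.sum(axis=0), 1.0)
        total_emission = sum(space.O[k] for k in ("null", "odor", "reward"))
        mask = space.T > 0
        assert np.allclose(total_emission[mask], 1.0)

    def test_hazard_from_discretized_gaussian(self, space1):
        # h_t = p_t / (1 - F_{t-1}); brute force from the pmf
        pmf, support = space1.reward_pmf, space1.reward_support
        for i, t in enumerate(support):
            surv = 1.0 - pmf[:i].sum()
            assert space1.hazard[t] == pytest.approx(pmf[i] / surv)
        assert space1.hazard[14] == pytest.approx(1.0)

    def test_babayan_uniform_hazards(self, space_b):
        assert space_b.hazard[9] == pytest.approx(1 / 3)
        assert space_b.hazard[10] == pytest.approx(1 / 2)
        assert space_b.hazard[11] == pytest.approx(1.0)

    def test_task2_odor_splits_by_omission_probability(self, space2):
        absorbing = space2.absorbing
        assert space2.T[0, absorbing] == pytest.approx((1 / 8) * 0.9)
        assert space2.T[space2.iti_start, absorbing] == pytest.approx((1 / 8) * 0.1)


class TestBeliefStep:
    def test_odor_from_iti_is_point_mass_on_isi_start(self, space1, rng):
        b = np.zeros(space1.K)
        b[space1.iti_start:] = rng.dirichlet(np.ones(space1.K - space1.iti_start))
        out = belief_step(space1, b, "odor")
        expected = np.zeros(space1.K)
        expected[0] = 1.0
        assert np.allclose(out, expected)

    def test_reward_from_isi_is_point_mass_on_iti_start(self, space2, rng):
        b = np.zeros(space2.K)
        b[5:14] = rng.dirichlet(np.ones(9))
        out = belief_step(space2, b, "reward")
        assert out[space2.iti_start] == pytest.approx(1.0)

    def test_absorbing_state_is_null_fixed_point(self, space1, space2):
        for space in (space1, space2):
            b = space.initial_belief()
            assert np.allclose(belief_step(space, b, "null"), b)

    def test_impossible_observation_raises(self, space1):
        b = space1.initial_belief()
        with pytest.raises(ImpossibleObservation):
            belief_step(space1, b, "reward")

    def test_task2_post_odor_isi_mass_is_reward_probability(self, space2):
        b = belief_step(space2, space2.initial_belief(), "odor")
        isi_mass = b[: space2.n_isi].sum()
        assert isi_mass == pytest.approx(0.9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_simplex_conservation_on_random_sequences(self, seed):
        space = build_starkweather_space(2)
        s = generate_session(StarkweatherConfig(variant=2), 5, seed)
        B = run_beliefs(space, s)
        assert np.all(B >= -1e-15)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)


class TestRunBeliefs:
    @pytest.mark.parametrize("variant", [1, 2])
    def test_matches_forward_oracle(self, variant):
        space = build_starkweather_space(variant)
        s = generate_session(StarkweatherConfig(variant=variant), 3, 99)
        kinds = [
            "odor" if s.odor[t] else ("reward" if s.reward[t] > 0 else "null")
            for t in range(min(len(s), 50))
        ]
        expected = forward_oracle(space, space.initial_belief(), kinds)
        B = run_beliefs(space, s)[: len(kinds)]
        assert np.abs(B - expected).max() < 1e-12

    def test_task1_beliefs_are_point_masses(self, space1, session1):
        B = run_beliefs(space1, session1)
        assert np.allclose(B.max(axis=1), 1.0)
        # zero entropy throughout
        ent = -(np.where(B > 0, B * np.log(B + 1e-300), 0.0)).sum(axis=1)
        assert np.abs(ent).max() < 1e-12

    def test_task2_omission_isi_mass_decays_by_step_15(self, space2):
        b = belief_step(space2, space2.initial_belief(), "odor")
        for _ in range(14):
            b = belief_step(space2, b, "null")
        assert b[: space2.n_isi].sum() < 1e-12

    def test_beliefs_track_true_states_task1(self, space1, session1):
        B = run_beliefs(space1, session1)
        assert np.array_equal(B.argmax(axis=1), session1.states)


class TestBabayanBeliefs:
    def test_block_likelihood_extremes_and_midpoint(self):
        assert block_likelihood(1.0) > 1 - 1e-12
        assert block_likelihood(10.0) < 1e-12
        assert block_likelihood(5.5) == pytest.approx(0.5)

    def test_p_updates_only_at_rewards(self, space_b):
        b0 = space_b.initial_belief()
        bb = BlockBelief(p_block1=0.3, b1=b0.copy(), b2=b0.copy())
        stepped = babayan_belief_step(space_b, bb, "null", 0.0)
        assert stepped.p_block1 == 0.3
        stepped = babayan_belief_step(space_b, stepped, "odor", 0.0)
        assert stepped.p_block1 == 0.3

    def test_reward_snaps_block_posterior(self, space_b):
        b0 = space_b.initial_belief()
        bb = BlockBelief(p_block1=0.5, b1=b0.copy(), b2=b0.copy())
        bb = babayan_belief_step(space_b, bb, "odor", 0.0)
        for _ in range(8):
            bb = babayan_belief_step(space_b, bb, "null", 0.0)
        small = babayan_belief_step(space_b, bb, "reward", 1.0)
        large = babayan_belief_step(space_b, bb, "reward", 10.0)
        assert small.p_block1 > 1 - 1e-9
        assert large.p_block1 < 1e-9

    def test_composite_is_44_dimensional_simplex(self, space_b, session_b):
        B = run_beliefs(space_b, session_b)
        assert B.shape[1] == 44
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_composite_concentrates_on_true_copy_late_in_block(
        self, space_b, session_b
    ):
        B = run_beliefs(space_b, session_b)
        trials = session_b.trials
        late = trials["trial_in_block"] >= 3
        starts = session_b.trial_starts
        for i in np.flatnonzero(late.to_numpy()):
            t_odor = starts[i] + trials["iti"].iloc[i] - 1
            copy = trials["copy"].iloc[i]
            mass = B[t_odor, copy * 22:(copy + 1) * 22].sum()
            assert mass > 0.99
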