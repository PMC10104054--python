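"""Linear value estimation and TD errors on arbitrary representations.

Value weights are fit by Least-Squares TD (LSTD) on a representation trace
Z (beliefs, GRU activity, or reservoir activity); TD errors (reward
prediction errors, RPEs) are computed from the resulting value trace.

Alignment convention: the representation z_t has consumed the observation
o_t, and the reward delivered together with the transition t → t+1 is the
one predicted by V_t.  The TD error for that transition is

    δ_t = r_{t+1} + γ V̂_{t+1} − V̂_t ,

and the LSTD moment vector pairs z_t with r_{t+1}.  The RPE "at the time
of reward" of a trial whose reward arrives at step t_r is δ_{t_r − 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tasks import BabayanConfig, Session

__all__ = [
    "ValueReadout",
    "RpeTrace",
    "RankDeficientRepresentation",
    "lstd_fit",
    "td_errors",
    "reward_time_rpes",
    "rpe_mse",
    "rpe_summaries",
    "bellman_values",
]


class RankDeficientRepresentation(np.linalg.LinAlgError):
    """LSTD system is singular and inconsistent for this representation."""


@dataclass
class ValueReadout:
    """Linear value function V̂_t = w·z_t + w0 with discount γ."""

    w: np.ndarray
    w0: float
    gamma: float

    def values(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.w + self.w0


@dataclass
class RpeTrace:
    """Per-step TD errors plus per-trial RPEs at reward delivery."""

    delta: np.ndarray                  # length T-1
    reward_steps: np.ndarray           # session step index of each reward
    reward_time_rpes: np.ndarray       # δ at reward delivery, one per rewarded trial


def lstd_fit(
    Z: np.ndarray,
    rewards: np.ndarray,
    gamma: float,
    ridge: float = 0.0,
    name: str = "representation",
) -> ValueReadout:
    """Least-squares TD on a representation trace.

    Solves  D̂ w = d̂  with  D̂ = Σ_t z̃_t (z̃_t − γ z̃_{t+1})ᵀ  and
    d̂ = Σ_t r_{t+1} z̃_t, where z̃ is Z augmented with a constant-one
    feature so the offset w0 is estimated jointly.

    Representations that are exactly collinear (e.g. beliefs, which sum to
    one, plus the constant feature) give a singular D̂ but a *consistent*
    system; the minimum-norm solution is then the TD value function and is
    returned.  A singular *inconsistent* system raises
    :class:`RankDeficientRepresentation` unless ``ridge`` > 0.
    """
    Z = np.asarray(Z, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    if Z.ndim != 2 or len(Z) < 2:
        raise ValueError("Z must be (T, D) with T >= 2")
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    Z1 = np.hstack([Z, np.ones((len(Z), 1))])
    A, Bn = Z1[:-1], Z1[1:]
    D = A.T @ (A - gamma * Bn)
    d = rewards[1:] @ A
    if ridge > 0:
        w = np.linalg.solve(D + ridge * np.eye(len(D)), d)
    else:
        w, *_ = np.linalg.lstsq(D, d, rcond=None)
        resid = np.linalg.norm(D @ w - d)
        scale = np.linalg.norm(d) + 1e-30
        if resid / scale > 1e-6:
            raise RankDeficientRepresentation(
                f"LSTD system for {name!r} is rank deficient and inconsistent "
                f"(relative residual {resid / scale:.2e}); pass ridge > 0 "
                "for degenerate representations"
            )
    return ValueReadout(w=w[:-1], w0=float(w[-1]), gamma=gamma)


def td_errors(
    values: np.ndarray, rewards: np.ndarray, gamma: float
) -> np.ndarray:
    """δ_t = r_{t+1} + γ V̂_{t+1} − V̂_t for t = 0..T−2."""
    values = np.asarray(values, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    if len(values) != len(rewards) or len(values) < 2:
        raise ValueError("values and rewards must be aligned, length >= 2")
    return rewards[1:] + gamma * values[1:] - values[:-1]


def reward_time_rpes(session: Session, delta: np.ndarray) -> RpeTrace:
    """Collect δ at the reward-delivery step of each rewarded trial."""
    steps = np.flatnonzero(session.reward > 0)
    steps = steps[(steps >= 1) & (steps - 1 < len(delta))]
    return RpeTrace(
        delta=delta, reward_steps=steps, reward_time_rpes=delta[steps - 1]
    )


def rpe_mse(model_rpes: RpeTrace | np.ndarray, belief_rpes: RpeTrace | np.ndarray) -> float:
    """Mean squared difference of per-trial reward-time RPEs."""
    a = model_rpes.reward_time_rpes if isinstance(model_rpes, RpeTrace) else np.asarray(model_rpes)
    b = belief_rpes.reward_time_rpes if isinstance(belief_rpes, RpeTrace) else np.asarray(belief_rpes)
    if len(a) != len(b):
        raise ValueError("RPE traces come from different sessions")
    if len(a) == 0:
        raise ValueError("no rewarded trials to compare")
    return float(np.mean((a - b) ** 2))


def rpe_summaries(session: Session, delta: np.ndarray) -> pd.DataFrame:
    """Tidy per-group RPE summaries.

    Starkweather sessions: mean δ at reward grouped by ISI (reward time).
    Babayan sessions: mean δ at odor and at reward grouped by within-block
    trial index and the (previous block, current block) reward pair.
    """
    if isinstance(session.config, BabayanConfig):
        return _babayan_summary(session, delta)
    trace = reward_time_rpes(session, delta)
    rewarded = session.trials.loc[~session.trials["omission"].astype(bool)]
    isis = rewarded["isi"].to_numpy()[: len(trace.reward_time_rpes)]
    frame = pd.DataFrame({"group": isis, "rpe": trace.reward_time_rpes})
    out = frame.groupby("group")["rpe"].agg(["mean", "sem", "count"]).reset_index()
    out.columns = ["group", "mean", "sem", "n"]
    return out


def _babayan_summary(session: Session, delta: np.ndarray) -> pd.DataFrame:
    trials = session.trials.copy()
    starts = session.trial_starts
    odor_steps = np.array(
        [starts[i] + trials["iti"].iloc[i] - 1 for i in range(len(trials))]
    )
    reward_steps = odor_steps + trials["isi"].to_numpy()
    prev_reward = trials["reward_size"].shift(1)
    rows = []
    for i in range(len(trials)):
        for event, step in (("odor", odor_steps[i]), ("reward", reward_steps[i])):
            if step - 1 < 0 or step - 1 >= len(delta):
                continue
            rows.append(
                {
                    "event": event,
                    "trial_in_block": int(trials["trial_in_block"].iloc[i]),
                    "current_reward": float(trials["reward_size"].iloc[i]),
                    "previous_reward": float(prev_reward.iloc[i]) if i > 0 else np.nan,
                    "rpe": float(delta[step - 1]),
                }
            )
    frame = pd.DataFrame(rows)
    # block pair = reward size of previous block (the one before this block started)
    out = (
        frame.groupby(["event", "trial_in_block", "current_reward"])["rpe"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    out = out.rename(columns={"count": "n"})
    return out


def bellman_values(space, gamma: float) -> np.ndarray:
    """Exact state values of a micro-state chain: V = r̄ + γ Tᵀ V.

    r̄(k) is the expected one-step reward on leaving state k (reward
    magnitude 1 on reward-emitting transitions), so V(k) matches the LSTD
    target for a fully observable chain.
    """
    T, O = space.T, space.O["reward"]
    rbar = (T * O).sum(axis=0)
    K = space.K
    V = np.linalg.solve(np.eye(K) - gamma * T.T, rbar)
    return V
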