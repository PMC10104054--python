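"""Micro-state POMDPs and Bayesian belief filtering.

Each task is formalized as a Markov chain over time-indexed micro-states
with observations emitted on transitions: the belief update is

    b_t(k') ∝ Σ_k O_o(k', k) T(k', k) b_{t-1}(k)

where ``T(k', k)`` is the probability of the transition k→k' and
``O_o(k', k)`` the probability that this transition emits observation
``o`` ∈ {null, odor, reward}.

Starkweather tasks use a single chain of K=25 states: ISI micro-states
(elapsed time since odor, indices 0..13) with a reward hazard derived from
the discretized-Gaussian ISI distribution, and ITI micro-states (indices
14..24) ending in an absorbing state whose odor hazard is ``p_iti``.  In
Task 2 the odor transition splits: with probability ``p_omission`` it leads
directly back to the ITI (the agent cannot tell from the odor alone).

The Babayan task uses two copies of a K=22 chain (one per reward block)
plus a scalar block posterior ``p_t`` that is re-estimated from each
nonzero reward through a Normal likelihood ratio; the composite belief is
the 44-dimensional concatenation [p_t·b1, (1-p_t)·b2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tasks import BabayanConfig, Session, StarkweatherConfig, isi_pmf

__all__ = [
    "MicrostateSpace",
    "BlockBelief",
    "ImpossibleObservation",
    "build_starkweather_space",
    "build_babayan_space",
    "belief_step",
    "babayan_belief_step",
    "run_beliefs",
    "block_likelihood",
]

OBS_KINDS = ("null", "odor", "reward")


class ImpossibleObservation(ValueError):
    """Observation has zero probability under the micro-state model."""


@dataclass
class MicrostateSpace:
    """Transition matrix, per-observation emissions, and hazards of one chain.

    ``T[k_next, k_prev]`` is the probability of the transition
    k_prev → k_next; for every source state the column sums to one.
    ``O[o][k_next, k_prev]`` is the probability that this transition emits
    observation ``o``; emissions sum to one over observations wherever the
    transition has positive probability.
    """

    K: int
    T: np.ndarray
    O: dict[str, np.ndarray]
    hazard: np.ndarray          # reward hazard indexed by ISI step (1-based time)
    reward_pmf: np.ndarray      # ISI distribution over the support
    reward_support: np.ndarray
    n_isi: int                  # number of ISI micro-states
    labels: np.ndarray = field(default=None)  # "ISI"/"ITI" per micro-state

    def __post_init__(self):
        if self.labels is None:
            self.labels = np.array(
                ["ISI"] * self.n_isi + ["ITI"] * (self.K - self.n_isi)
            )

    @property
    def iti_start(self) -> int:
        """Index of the micro-state reached by a reward transition."""
        return self.n_isi

    @property
    def absorbing(self) -> int:
        """Index of the absorbing ITI (odor-hazard) micro-state."""
        return self.K - 1

    def effective(self, kind: str) -> np.ndarray:
        """Elementwise product O_o * T used by the filter."""
        return self.O[kind] * self.T

    def initial_belief(self) -> np.ndarray:
        b = np.zeros(self.K)
        b[self.absorbing] = 1.0
        return b


def _hazards(support: np.ndarray, pmf: np.ndarray) -> np.ndarray:
    """h_t = p_t / (1 - F_{t-1}); the hazard at the last support point is 1."""
    F = np.cumsum(pmf)
    surv_before = np.concatenate([[1.0], 1.0 - F[:-1]])
    h = np.zeros(int(support.max()) + 1)
    h[support] = pmf / surv_before
    return h


def _build_chain(
    n_isi: int,
    iti_min: int,
    p_iti: float,
    p_omission: float,
    support: np.ndarray,
    pmf: np.ndarray,
) -> MicrostateSpace:
    K = n_isi + iti_min + 1
    hazard = _hazards(support, pmf)
    T = np.zeros((K, K))
    O = {o: np.zeros((K, K)) for o in OBS_KINDS}
    iti_start = n_isi
    absorbing = K - 1

    # ISI micro-states: index k holds elapsed ISI time t = k + 1
    for k in range(n_isi):
        t = k + 1
        h = hazard[t] if t < len(hazard) else 0.0
        if h > 0:
            T[iti_start, k] = h
            O["reward"][iti_start, k] = 1.0
        if k + 1 < n_isi:
            T[k + 1, k] = 1.0 - h
            O["null"][k + 1, k] = 1.0

    # ITI advance then absorbing odor-hazard state
    for k in range(iti_start, absorbing):
        T[k + 1, k] = 1.0
        O["null"][k + 1, k] = 1.0
    T[absorbing, absorbing] = 1.0 - p_iti
    O["null"][absorbing, absorbing] = 1.0
    T[0, absorbing] = p_iti * (1.0 - p_omission)
    O["odor"][0, absorbing] = 1.0
    if p_omission > 0:
        T[iti_start, absorbing] = p_iti * p_omission
        O["odor"][iti_start, absorbing] = 1.0

    return MicrostateSpace(
        K=K, T=T, O=O, hazard=hazard, reward_pmf=pmf,
        reward_support=support, n_isi=n_isi,
    )


def build_starkweather_space(
    variant_or_config: int | StarkweatherConfig,
) -> MicrostateSpace:
    """Micro-state space of Starkweather Task 1 or 2 (K = 25)."""
    cfg = (
        variant_or_config
        if isinstance(variant_or_config, StarkweatherConfig)
        else StarkweatherConfig(variant=variant_or_config)
    )
    support, pmf = isi_pmf(cfg)
    return _build_chain(
        n_isi=cfg.isi_max, iti_min=cfg.iti_min, p_iti=cfg.p_iti,
        p_omission=cfg.p_omission, support=support, pmf=pmf,
    )


def build_babayan_space(config: BabayanConfig | None = None) -> MicrostateSpace:
    """Per-block-copy micro-state space of the Babayan task (K = 22)."""
    cfg = config or BabayanConfig()
    support, pmf = isi_pmf(cfg)
    return _build_chain(
        n_isi=max(cfg.isi_support), iti_min=cfg.iti_min, p_iti=cfg.p_iti,
        p_omission=0.0, support=support, pmf=pmf,
    )


def obs_kind(odor: float, reward: float) -> str:
    if odor > 0 and reward > 0:
        raise ValueError("odor and reward cannot co-occur")
    if odor > 0:
        return "odor"
    if reward > 0:
        return "reward"
    return "null"


def belief_step(
    space: MicrostateSpace, b_prev: np.ndarray, kind: str
) -> np.ndarray:
    """One Bayesian filtering update given observation ``kind``."""
    b = space.effective(kind) @ b_prev
    s = b.sum()
    if s <= 0.0:
        raise ImpossibleObservation(
            f"observation {kind!r} has zero probability under the model"
        )
    return b / s


@dataclass
class BlockBelief:
    """Composite Babayan belief: block posterior plus one belief per copy."""

    p_block1: float
    b1: np.ndarray
    b2: np.ndarray

    @property
    def composite(self) -> np.ndarray:
        return np.concatenate([self.p_block1 * self.b1, (1 - self.p_block1) * self.b2])


def block_likelihood(
    r: float, mu1: float = 1.0, mu2: float = 10.0, sigma_r: float = 0.001
) -> float:
    """Posterior probability of block 1 given a nonzero reward.

    f(r) = φ(r; μ1, σ_r) / (φ(r; μ1, σ_r) + φ(r; μ2, σ_r)); with an
    arbitrarily small σ_r this is a sharp sigmoid centered between the two
    block reward sizes.  Computed in log space to avoid underflow.
    """
    # log φ ratio; φ(r;μ,σ) ∝ exp(-(r-μ)²/2σ²)
    a = -((r - mu1) ** 2) / (2 * sigma_r**2)
    b = -((r - mu2) ** 2) / (2 * sigma_r**2)
    m = max(a, b)
    ea, eb = np.exp(a - m), np.exp(b - m)
    return float(ea / (ea + eb))


def babayan_belief_step(
    space: MicrostateSpace,
    bb: BlockBelief,
    kind: str,
    reward_value: float = 0.0,
    mu: tuple[float, float] = (1.0, 10.0),
    sigma_r: float = 0.001,
) -> BlockBelief:
    """Advance both block copies; re-estimate p only at nonzero rewards."""
    b1 = belief_step(space, bb.b1, kind)
    b2 = belief_step(space, bb.b2, kind)
    p = bb.p_block1
    if reward_value > 0:
        p = block_likelihood(reward_value, mu[0], mu[1], sigma_r)
    return BlockBelief(p_block1=p, b1=b1, b2=b2)


def run_beliefs(
    space: MicrostateSpace,
    session: Session,
    p0: float = 0.5,
) -> np.ndarray:
    """Belief trace for a session: one row per time step, rows on the simplex.

    For Starkweather sessions the rows are the K-dimensional posterior; for
    Babayan sessions they are the 2K-dimensional composite belief (block
    posterior starts at ``p0``).  The initial belief is a point mass on the
    absorbing ITI state.
    """
    if isinstance(session.config, BabayanConfig):
        return _run_babayan(space, session, p0)
    B = np.empty((len(session), space.K))
    b = space.initial_belief()
    eff = {k: space.effective(k) for k in OBS_KINDS}
    odor, reward = session.odor, session.reward
    for t in range(len(session)):
        kind = "odor" if odor[t] else ("reward" if reward[t] > 0 else "null")
        b = eff[kind] @ b
        s = b.sum()
        if s <= 0.0:
            raise ImpossibleObservation(f"impossible {kind!r} at step {t}")
        b = b / s
        B[t] = b
    return B


def _run_babayan(space: MicrostateSpace, session: Session, p0: float) -> np.ndarray:
    cfg: BabayanConfig = session.config
    mu = cfg.block_rewards
    B = np.empty((len(session), 2 * space.K))
    b0 = space.initial_belief()
    bb = BlockBelief(p_block1=p0, b1=b0.copy(), b2=b0.copy())
    odor, reward = session.odor, session.reward
    for t in range(len(session)):
        kind = "odor" if odor[t] else ("reward" if reward[t] > 0 else "null")
        bb = babayan_belief_step(space, bb, kind, float(reward[t]), mu=mu)
        B[t] = bb.composite
    return B
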