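"""Fixed points and observation-memory durations of state-update maps.

Works on any map z_t = f(o_t, z_{t−1}) — a belief update or an RNN forward
step.  Fixed points are sought under the null observation (the only
observation that can leave a belief unchanged); candidates are generated by
iterating the null map from seed states until the step size converges,
verified by a residual test, and merged by distance.

The *odor memory* (or *reward memory*) of a map is the number of steps its
state, perturbed from the fixed point by a single odor (reward)
observation, needs to return within a threshold squared distance of that
fixed point under null input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .beliefs import ImpossibleObservation, MicrostateSpace
from .rnn import ValueRnn

__all__ = [
    "StateUpdateMap",
    "BeliefMap",
    "RnnMap",
    "FixedPointSet",
    "MemoryDuration",
    "find_fixed_points",
    "memory_duration",
    "seed_states_from_session",
]


class StateUpdateMap:
    """Protocol: ``null_step(z)`` and ``obs_step(z, kind)`` -> next state."""

    def null_step(self, z: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def obs_step(self, z: np.ndarray, kind: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BeliefMap(StateUpdateMap):
    """Belief update of a micro-state space as a dynamical system.

    If the probing observation is impossible at the current belief (e.g. a
    reward at the ITI fixed point, where no reward-emitting transition
    exists), ``obs_step`` falls back to the observation-conditioned landing
    distribution — the posterior over arrival states given that the
    observation occurred from a uniformly random source state.  All reward
    transitions land on the first post-reward ITI micro-state, so this
    reproduces the deterministic post-reward trajectory.
    """

    def __init__(self, space: MicrostateSpace):
        self.space = space
        self._eff = {k: space.effective(k) for k in ("null", "odor", "reward")}

    def null_step(self, z):
        b = self._eff["null"] @ z
        s = b.sum()
        if s <= 0:
            raise ImpossibleObservation("null observation impossible here")
        return b / s

    def obs_step(self, z, kind):
        b = self._eff[kind] @ z
        s = b.sum()
        if s <= 0:
            b = self._eff[kind] @ np.full(self.space.K, 1.0 / self.space.K)
            s = b.sum()
            if s <= 0:
                raise ImpossibleObservation(
                    f"{kind!r} is impossible from every state"
                )
        return b / s


class RnnMap(StateUpdateMap):
    """An RNN forward step under a fixed observation encoding.

    Odor is encoded as [1, 0]; reward as [0, r] with the task's nonzero
    reward magnitude.
    """

    def __init__(self, model: ValueRnn, reward_size: float = 1.0):
        self.model = model
        self.obs = {
            "null": np.zeros(model.n_inputs),
            "odor": np.array([1.0, 0.0]),
            "reward": np.array([0.0, float(reward_size)]),
        }

    def null_step(self, z):
        return self.model.step(self.obs["null"], z)

    def obs_step(self, z, kind):
        return self.model.step(self.obs[kind], z)


@dataclass
class FixedPointSet:
    points: list[np.ndarray]
    eps: float
    merge_tol: float
    n_seeds: int
    n_converged: int
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class MemoryDuration:
    kind: str
    steps: int
    trace: np.ndarray          # η_t = ‖z_t − z0‖², t = 1..
    threshold: float
    exceeded_cap: bool = False

    def normalized_trace(self) -> np.ndarray:
        m = self.trace.max()
        return self.trace / m if m > 0 else self.trace


def _iterate_to_convergence(step, z, eps, cap):
    """Iterate the null map until squared step size < eps; None if no return."""
    for _ in range(cap):
        z_new = step(z)
        if float(((z_new - z) ** 2).sum()) < eps:
            return z_new
        z = z_new
    return None


def _polish(step, z, cap=5000, tol=1e-24):
    """Tighten a converged candidate to numerical precision."""
    for _ in range(cap):
        z_new = step(z)
        if float(((z_new - z) ** 2).sum()) < tol:
            return z_new
        z = z_new
    return z


def find_fixed_points(
    step_map: StateUpdateMap | Callable[[np.ndarray], np.ndarray],
    seed_states: Sequence[np.ndarray],
    eps: float = 1e-5,
    merge_tol: float = 1e-3,
    max_iter: int = 1000,
    polish: bool = False,
) -> FixedPointSet:
    """Null-input fixed points found by iteration from seed states.

    From each seed the null map is iterated until the squared step size
    falls below ``eps`` (candidates failing to converge within ``max_iter``
    are counted, not raised; belief seeds for which prolonged null input is
    impossible are likewise skipped).  Candidates are kept if they pass the
    residual test ‖f(∅,z) − z‖² < eps and merged when within ``merge_tol``
    of an accepted point.

    By default the ε-converged iterate itself is the reported fixed point,
    exactly as produced by the iterative procedure; ``polish=True``
    additionally iterates each candidate to numerical precision, which
    matters when the subsequent analysis is sensitive to small offsets
    (e.g. thresholded distance traces on slowly contracting maps).
    """
    if len(seed_states) == 0:
        raise ValueError("need at least one seed state")
    step = step_map.null_step if isinstance(step_map, StateUpdateMap) else step_map
    points: list[np.ndarray] = []
    n_converged = 0
    n_failed = 0
    for z0 in seed_states:
        try:
            z = _iterate_to_convergence(step, np.asarray(z0, float), eps, max_iter)
        except ImpossibleObservation:
            n_failed += 1
            continue
        if z is None:
            n_failed += 1
            continue
        n_converged += 1
        if polish:
            z = _polish(step, z)
        if float(((step(z) - z) ** 2).sum()) >= eps:
            continue
        if not any(np.linalg.norm(z - p) < merge_tol for p in points):
            points.append(z)
    return FixedPointSet(points=points, eps=eps, merge_tol=merge_tol,
                         n_seeds=len(seed_states), n_converged=n_converged,
                         n_failed=n_failed)


def memory_duration(
    step_map: StateUpdateMap,
    fixed_point: np.ndarray,
    observation: str,
    threshold: float = 1e-3,
    cap: int = 1000,
) -> MemoryDuration:
    """Steps for the state to return near its fixed point after a perturbation.

    The state starts at ``fixed_point``; the observation is applied at
    t = 1, then null input only.  Returns the first t with
    η_t = ‖z_t − z0‖² < ``threshold`` (and the full η trace); if the state
    has not returned within ``cap`` steps the result is flagged and
    ``steps`` is reported as ``cap``.
    """
    z0 = np.asarray(fixed_point, dtype=float)
    z = step_map.obs_step(z0, observation)
    trace = [float(((z - z0) ** 2).sum())]
    t = 1
    while trace[-1] >= threshold and t < cap:
        z = step_map.null_step(z)
        trace.append(float(((z - z0) ** 2).sum()))
        t += 1
    return MemoryDuration(
        kind=observation, steps=t, trace=np.asarray(trace),
        threshold=threshold, exceeded_cap=trace[-1] >= threshold,
    )


def seed_states_from_session(
    Z: np.ndarray, odor: np.ndarray, reward: np.ndarray,
    n_seeds: int = 20, rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Randomly selected states following odor or reward observations."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = np.flatnonzero((odor > 0) | (reward > 0))
    if len(idx) == 0:
        raise ValueError("session contains no odor or reward observations")
    pick = rng.choice(idx, size=min(n_seeds, len(idx)), replace=False)
    return Z[pick]
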