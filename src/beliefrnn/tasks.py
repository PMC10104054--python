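"""Generative simulators for the conditioning tasks.

Two task families are implemented, both discretized at 200 ms per time step:

* **Starkweather tasks** — an odor is followed, after a variable
  interstimulus interval (ISI, 6-14 steps, discretized Gaussian), by a
  unit reward.  Task 1 rewards every trial; Task 2 omits the reward on 10%
  of trials, which makes the post-odor state ambiguous.
* **Babayan task** — every trial is rewarded after a uniform ISI of 9-11
  steps, but the reward size alternates between hidden blocks of five
  trials (1 vs. 10), optionally with rare intermediate-size probe blocks.

The intertrial interval (ITI) in every task is ``iti_min`` deterministic
steps plus a geometric tail, i.e. a constant odor hazard once the minimum
has elapsed.

Each generated :class:`Session` carries, per time step, the observation
(odor flag, reward magnitude) and the ground-truth micro-state label of the
equivalent Markov chain over time-indexed micro-states (see
:mod:`beliefrnn.beliefs`); labels and observations are mutually consistent
by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

TIME_BIN_SECONDS = 0.2  # metadata only; all computation is in steps

__all__ = [
    "StarkweatherConfig",
    "BabayanConfig",
    "Session",
    "sample_iti",
    "sample_isi",
    "isi_pmf",
    "generate_session",
    "save_session",
    "load_session",
]


@dataclass(frozen=True)
class StarkweatherConfig:
    """Starkweather task parameters.

    ``variant`` 1 rewards every trial; variant 2 omits reward with
    probability ``p_omission`` (0.1).  The ISI distribution is a Gaussian
    with mean ``isi_mean`` and sd ``isi_sd`` evaluated at the integers
    ``isi_min..isi_max`` and renormalized.
    """

    variant: Literal[1, 2] = 1
    p_iti: float = 1.0 / 8.0
    iti_min: int = 10
    isi_min: int = 6
    isi_max: int = 14
    isi_mean: float = 10.0
    isi_sd: float = 2.5
    reward_size: float = 1.0

    @property
    def p_omission(self) -> float:
        return 0.1 if self.variant == 2 else 0.0

    def __post_init__(self) -> None:
        if self.variant not in (1, 2):
            raise ValueError(f"variant must be 1 or 2, got {self.variant}")
        if not 0 < self.p_iti <= 1:
            raise ValueError("p_iti must be in (0, 1]")
        if self.isi_min < 1 or self.isi_max < self.isi_min:
            raise ValueError("ISI support must be positive integers")


@dataclass(frozen=True)
class BabayanConfig:
    """Block-structured task: 5-trial blocks of small (1) or large (10) rewards.

    Block identity is hidden and resampled uniformly at every block
    boundary.  With ``probe_enabled``, blocks may instead carry an
    intermediate reward size; standard blocks keep ~90% of the mixture.
    """

    block_rewards: tuple[float, float] = (1.0, 10.0)
    block_len: int = 5
    isi_support: tuple[int, ...] = (9, 10, 11)
    p_iti: float = 1.0 / 8.0
    iti_min: int = 10
    probe_enabled: bool = False
    probe_rewards: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    probe_weight_each: float = 0.025

    def __post_init__(self) -> None:
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        if not 0 < self.p_iti <= 1:
            raise ValueError("p_iti must be in (0, 1]")

    def block_reward_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """Reward sizes and mixture weights for sampling a block identity."""
        if not self.probe_enabled:
            sizes = np.array(self.block_rewards, dtype=float)
            return sizes, np.full(2, 0.5)
        sizes = np.array(list(self.block_rewards) + list(self.probe_rewards))
        w_probe = self.probe_weight_each
        w_std = (1.0 - w_probe * len(self.probe_rewards)) / 2.0
        weights = np.array([w_std, w_std] + [w_probe] * len(self.probe_rewards))
        return sizes, weights


TaskConfig = Union[StarkweatherConfig, BabayanConfig]


@dataclass
class Session:
    """A per-time-step record of one simulated session.

    ``odor`` and ``reward`` form the observation vector o_t = [c_t, r_t];
    the two are never simultaneously nonzero.  ``states`` holds the
    ground-truth micro-state index at each step (0-based, consistent with
    the task's :class:`~beliefrnn.beliefs.MicrostateSpace`).  ``trials`` is
    a per-trial table (iti, isi, reward size, omission flag, block id).
    """

    odor: np.ndarray
    reward: np.ndarray
    states: np.ndarray
    trial_index: np.ndarray
    trials: pd.DataFrame
    config: TaskConfig
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.odor)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def observations(self) -> np.ndarray:
        """(T, 2) array of [odor, reward] observation vectors."""
        return np.column_stack([self.odor.astype(float), self.reward])

    @property
    def trial_starts(self) -> np.ndarray:
        first = pd.Series(np.arange(len(self.trial_index))).groupby(
            self.trial_index
        ).min()
        return first.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(len(self)),
                "odor": self.odor.astype(int),
                "reward": self.reward,
                "state": self.states,
                "trial_index": self.trial_index,
                "block_id": self.trial_index_to_block(),
            }
        )

    def trial_index_to_block(self) -> np.ndarray:
        if "block_id" in self.trials.columns:
            return self.trials["block_id"].to_numpy()[self.trial_index]
        return np.full(len(self), -1)


def isi_pmf(config: TaskConfig) -> tuple[np.ndarray, np.ndarray]:
    """ISI support and probability mass for a task configuration.

    Starkweather: Normal(isi_mean, isi_sd) pdf evaluated at the integer
    support and renormalized.  Babayan: uniform over ``isi_support``.
    """
    if isinstance(config, StarkweatherConfig):
        support = np.arange(config.isi_min, config.isi_max + 1)
        pmf = norm.pdf(support, loc=config.isi_mean, scale=config.isi_sd)
        return support, pmf / pmf.sum()
    support = np.asarray(config.isi_support, dtype=int)
    return support, np.full(len(support), 1.0 / len(support))


def sample_iti(config: TaskConfig, rng: np.random.Generator) -> int:
    """Sample an ITI: ``iti_min`` + Geometric(p_iti) on {1, 2, ...}.

    The minimum ITI is therefore ``iti_min + 1`` steps, matching the
    micro-state chain in which the absorbing ITI state is reached after
    ``iti_min`` deterministic steps and emits the odor with hazard
    ``p_iti`` on each subsequent transition.
    """
    return config.iti_min + int(rng.geometric(config.p_iti))


def sample_isi(config: TaskConfig, rng: np.random.Generator) -> int:
    support, pmf = isi_pmf(config)
    return int(rng.choice(support, p=pmf))


def _starkweather_trial_states(
    iti: int, isi: int, omission: bool, cfg: StarkweatherConfig
) -> tuple[list[int], list[int], list[float]]:
    """Micro-state labels and observations for one trial.

    State indexing (0-based): ISI micro-states 0..isi_max-1 (elapsed ISI
    time), ITI micro-states isi_max..isi_max+iti_min (the last is the
    absorbing odor-hazard state).
    """
    n_isi = cfg.isi_max
    absorbing = n_isi + cfg.iti_min
    states: list[int] = []
    odor: list[int] = []
    rew: list[float] = []
    # pre-odor nulls: continue the previous trial's ITI advance
    for _ in range(iti - 1):
        states.append(-1)  # placeholder, filled by the session stitcher
        odor.append(0)
        rew.append(0.0)
    # odor step: enter ISI state 0, or (omission) jump straight to ITI start
    states.append(n_isi if omission else 0)
    odor.append(1)
    rew.append(0.0)
    if omission:
        # the scheduled ISI elapses with no observations; ITI advance continues
        for _ in range(isi):
            states.append(-1)
            odor.append(0)
            rew.append(0.0)
    else:
        for k in range(1, isi):
            states.append(k)
            odor.append(0)
            rew.append(0.0)
        states.append(n_isi)  # reward transition lands on the first ITI state
        odor.append(0)
        rew.append(cfg.reward_size)
    return states, odor, rew


def _fill_iti_advance(states: np.ndarray, absorbing: int) -> None:
    """Replace -1 placeholders by advancing the preceding ITI micro-state."""
    for t in range(len(states)):
        if states[t] == -1:
            prev = states[t - 1] if t > 0 else absorbing
            states[t] = min(prev + 1, absorbing) if prev != absorbing else absorbing


def generate_session(
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
) -> Session:
    """Simulate ``n_trials`` concatenated trials of a task.

    Every trial is ITI-nulls, one odor, ISI-nulls, then a reward step
    (empty on omission trials).  Ground-truth micro-state labels are
    attached; the session starts in the absorbing ITI state.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)

    if isinstance(config, StarkweatherConfig):
        return _generate_starkweather(config, n_trials, rng, seed)
    if isinstance(config, BabayanConfig):
        return _generate_babayan(config, n_trials, rng, seed)
    raise TypeError(f"unknown config type {type(config)!r}")


def _generate_starkweather(
    cfg: StarkweatherConfig, n_trials: int, rng: np.random.Generator, seed
) -> Session:
    absorbing = cfg.isi_max + cfg.iti_min
    states: list[int] = []
    odor: list[int] = []
    rew: list[float] = []
    tidx: list[int] = []
    rows = []
    for i in range(n_trials):
        iti = sample_iti(cfg, rng)
        isi = sample_isi(cfg, rng)
        omission = bool(rng.random() < cfg.p_omission)
        s, o, r = _starkweather_trial_states(iti, isi, omission, cfg)
        states += s
        odor += o
        rew += r
        tidx += [i] * len(s)
        rows.append(
            {"trial": i, "iti": iti, "isi": isi,
             "reward_size": 0.0 if omission else cfg.reward_size,
             "omission": omission}
        )
    st = np.array(states)
    _fill_iti_advance(st, absorbing)
    return Session(
        odor=np.array(odor, dtype=np.int8),
        reward=np.array(rew),
        states=st,
        trial_index=np.array(tidx),
        trials=pd.DataFrame(rows),
        config=cfg,
        seed=seed,
        meta={"time_bin_s": TIME_BIN_SECONDS, "task": f"starkweather{cfg.variant}"},
    )


def _babayan_block_copy(reward_size: float, cfg: BabayanConfig) -> int:
    """Which of the two belief copies a block's reward size maps onto."""
    mu1, mu2 = cfg.block_rewards
    return 0 if abs(reward_size - mu1) <= abs(reward_size - mu2) else 1


def _generate_babayan(
    cfg: BabayanConfig, n_trials: int, rng: np.random.Generator, seed
) -> Session:
    n_isi = max(cfg.isi_support)
    k_copy = n_isi + cfg.iti_min + 1  # per-copy state count
    absorbing_local = k_copy - 1
    sizes, weights = cfg.block_reward_mixture()

    states: list[int] = []
    odor: list[int] = []
    rew: list[float] = []
    tidx: list[int] = []
    rows = []
    for i in range(n_trials):
        if i % cfg.block_len == 0:
            block_reward = float(rng.choice(sizes, p=weights))
            block_id = i // cfg.block_len
            copy = _babayan_block_copy(block_reward, cfg)
        iti = sample_iti(cfg, rng)
        isi = sample_isi(cfg, rng)
        # pre-odor nulls continue the previous block's ITI advance
        for _ in range(iti - 1):
            states.append(-1)
            odor.append(0)
            rew.append(0.0)
        offset = copy * k_copy
        states.append(offset + 0)
        odor.append(1)
        rew.append(0.0)
        for k in range(1, isi):
            states.append(offset + k)
            odor.append(0)
            rew.append(0.0)
        states.append(offset + n_isi)  # first ITI micro-state of the copy
        odor.append(0)
        rew.append(block_reward)
        tidx += [i] * (iti + isi)
        rows.append(
            {"trial": i, "iti": iti, "isi": isi, "reward_size": block_reward,
             "omission": False, "block_id": block_id,
             "trial_in_block": i % cfg.block_len + 1, "copy": copy}
        )
        cur_copy = copy
    st = np.array(states)
    # fill ITI advance within the proper copy
    for t in range(len(st)):
        if st[t] == -1:
            prev = st[t - 1] if t > 0 else absorbing_local
            local = prev % k_copy
            base = (prev // k_copy) * k_copy
            st[t] = base + min(local + 1, absorbing_local)
    return Session(
        odor=np.array(odor, dtype=np.int8),
        reward=np.array(rew),
        states=st,
        trial_index=np.array(tidx),
        trials=pd.DataFrame(rows),
        config=cfg,
        seed=seed,
        meta={"time_bin_s": TIME_BIN_SECONDS, "task": "babayan"},
    )


# ---------------------------------------------------------------------------
# serialization: CSV table + JSON sidecar, lossless round trip


def _config_to_dict(config: TaskConfig) -> dict:
    d = {k: getattr(config, k) for k in config.__dataclass_fields__}
    d["kind"] = type(config).__name__
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _config_from_dict(d: dict) -> TaskConfig:
    d = dict(d)
    kind = d.pop("kind")
    cls = {"StarkweatherConfig": StarkweatherConfig, "BabayanConfig": BabayanConfig}[kind]
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)


def save_session(session: Session, path: str | Path) -> None:
    """Write a session as CSV plus a JSON sidecar (config, seed, trials)."""
    path = Path(path)
    session.to_frame().to_csv(path, index=False)
    sidecar = {
        "config": _config_to_dict(session.config),
        "seed": session.seed,
        "meta": session.meta,
        "trials": session.trials.to_dict(orient="list"),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_session(path: str | Path) -> Session:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    trials = pd.DataFrame(sidecar["trials"])
    return Session(
        odor=frame["odor"].to_numpy(dtype=np.int8),
        reward=frame["reward"].to_numpy(dtype=float),
        states=frame["state"].to_numpy(dtype=int),
        trial_index=frame["trial_index"].to_numpy(dtype=int),
        trials=trials,
        config=_config_from_dict(sidecar["config"]),
        seed=sidecar["seed"],
        meta=sidecar["meta"],
    )
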