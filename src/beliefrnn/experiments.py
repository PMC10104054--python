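"""End-to-end experiment orchestration: cohorts, sweeps, summary tables.

A cohort is N independently initialized and trained Value RNNs for one
(task, hidden size) cell.  Every model is evaluated with the same protocol:
two fresh sessions of ``eval_trials`` concatenated trials (one for fitting
value weights, regressions and decoders; one held out for scoring), 40 dB
noise injected into RNN traces before fitting, LSTD value weights refit on
the fit session for every model class, and dynamics measured on noise-free
traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import probes
from .beliefs import build_babayan_space, build_starkweather_space, run_beliefs
from .dynamics import (
    RnnMap,
    find_fixed_points,
    memory_duration,
    seed_states_from_session,
)
from .rnn import TrainConfig, ValueRnn, train_td
from .tasks import (
    BabayanConfig,
    Session,
    StarkweatherConfig,
    generate_session,
)
from .td import lstd_fit, reward_time_rpes, rpe_mse, td_errors

__all__ = [
    "TASKS",
    "task_config",
    "belief_space",
    "ExperimentConfig",
    "ProbeData",
    "make_probe_data",
    "evaluate_model",
    "run_cohort",
    "run_esn_sweep",
    "summarize_cohort",
    "derive_seed",
]

TASKS = ("starkweather1", "starkweather2", "babayan")
_TASK_IDS = {name: i + 1 for i, name in enumerate(TASKS)}


def task_config(task: str):
    if task == "starkweather1":
        return StarkweatherConfig(variant=1)
    if task == "starkweather2":
        return StarkweatherConfig(variant=2)
    if task == "babayan":
        return BabayanConfig()
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def belief_space(config):
    if isinstance(config, BabayanConfig):
        return build_babayan_space(config)
    return build_starkweather_space(config)


def derive_seed(global_seed: int, task: str, hidden: int, index: int) -> int:
    """Deterministic per-model seed below 2**31."""
    ss = np.random.SeedSequence([global_seed, _TASK_IDS[task], hidden, index])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    """One cohort specification plus the shared evaluation protocol."""

    task: str = "starkweather2"
    cohort: int = 12
    hidden_sizes: tuple[int, ...] = (50,)
    esn_gains: tuple[float, ...] = ()
    session_trials: int = 10_000
    eval_trials: int = 1_000
    max_epochs: int = 150
    seed: int = 0
    fast: bool = False

    def resolved(self) -> "ExperimentConfig":
        """Desk-scale profile: smaller cohort, fewer epochs, shorter sessions."""
        if not self.fast:
            return self
        return replace(
            self,
            cohort=min(self.cohort, 3),
            session_trials=min(self.session_trials, 2_000),
            max_epochs=min(self.max_epochs, 30),
            hidden_sizes=tuple(h for h in self.hidden_sizes if h <= 50),
            fast=False,
        )

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig.for_task(
            task_config(self.task), max_epochs=self.max_epochs, seed=seed
        )


@dataclass
class ProbeData:
    """Shared per-task evaluation data: sessions, beliefs, belief RPEs."""

    task: str
    config: object
    space: object
    fit_session: Session
    eval_session: Session
    B_fit: np.ndarray
    B_eval: np.ndarray
    belief_delta_eval: np.ndarray
    gamma: float
    decode_mask: np.ndarray | None = None


def make_probe_data(task: str, seed: int, eval_trials: int = 1000,
                    gamma: float = 0.93) -> ProbeData:
    """Generate the two 1,000-trial analysis sessions and belief baselines."""
    config = task_config(task)
    space = belief_space(config)
    fit_session = generate_session(config, eval_trials, seed)
    eval_session = generate_session(config, eval_trials, seed + 1)
    B_fit = run_beliefs(space, fit_session)
    B_eval = run_beliefs(space, eval_session)
    readout = lstd_fit(B_fit, fit_session.reward, gamma, name="beliefs")
    delta = td_errors(readout.values(B_eval), eval_session.reward, gamma)
    mask = None
    if task == "babayan":
        # score decoding on all trials except the first of each block, where
        # the belief cannot yet know the block identity
        tib = eval_session.trials["trial_in_block"].to_numpy()
        mask = tib[eval_session.trial_index] != 1
    return ProbeData(
        task=task, config=config, space=space,
        fit_session=fit_session, eval_session=eval_session,
        B_fit=B_fit, B_eval=B_eval, belief_delta_eval=delta,
        gamma=gamma, decode_mask=mask,
    )


def evaluate_model(model: ValueRnn, data: ProbeData,
                   noise_seed: int = 0, decode: bool = False,
                   dynamics: bool = True) -> dict[str, float]:
    """All belief-likeness metrics for one model on shared probe data."""
    rng = np.random.default_rng(noise_seed)
    Z_fit_clean = model.forward(data.fit_session)
    Z_eval_clean = model.forward(data.eval_session)
    Z_fit = probes.inject_noise(Z_fit_clean, rng)
    Z_eval = probes.inject_noise(Z_eval_clean, rng)

    readout = lstd_fit(Z_fit, data.fit_session.reward, data.gamma, name="rnn")
    delta = td_errors(readout.values(Z_eval), data.eval_session.reward, data.gamma)
    mse = rpe_mse(
        reward_time_rpes(data.eval_session, delta),
        reward_time_rpes(data.eval_session, data.belief_delta_eval),
    )
    r2 = probes.belief_r2(Z_fit, data.B_fit, Z_eval, data.B_eval)
    _, pca2 = probes.pca_top2(Z_eval_clean)

    out = {"rpe_mse": mse, "belief_r2": r2, "pca2_frac": pca2}

    if decode:
        dec = probes.fit_state_decoder(Z_fit, data.fit_session.states,
                                       n_states=data.B_fit.shape[1])
        out["decoder_loglik"] = probes.decoder_loglik(
            dec, Z_eval, data.eval_session.states, mask=data.decode_mask
        )

    if dynamics:
        reward_size = (
            max(data.config.block_rewards)
            if isinstance(data.config, BabayanConfig)
            else data.config.reward_size
        )
        rmap = RnnMap(model, reward_size=reward_size)
        seeds = seed_states_from_session(
            Z_eval_clean, data.eval_session.odor, data.eval_session.reward,
            rng=noise_seed,
        )
        fps = find_fixed_points(rmap, seeds, polish=True)
        out["n_fixed_points"] = float(len(fps))
        if len(fps.points) > 0:
            fp = fps.points[0]
            for kind in ("odor", "reward"):
                # distance < 1e-3 from the polished fixed point
                mem = memory_duration(rmap, fp, kind, threshold=1e-6)
                out[f"{kind}_memory"] = float(mem.steps)
                out[f"{kind}_memory_exceeded"] = float(mem.exceeded_cap)
    return out


def run_cohort(config: ExperimentConfig, decode: bool = False,
               progress: bool = False) -> pd.DataFrame:
    """Train and evaluate a cohort of Value RNNs; tidy per-model results.

    Each model is evaluated both before (untrained) and after training.
    Individual model failures are logged as rows with ``error`` set and
    excluded from summaries.
    """
    cfg = config.resolved()
    data = make_probe_data(cfg.task, derive_seed(cfg.seed, cfg.task, 0, 0),
                           eval_trials=cfg.eval_trials)
    train_session = generate_session(
        task_config(cfg.task), cfg.session_trials,
        derive_seed(cfg.seed, cfg.task, 0, 1),
    )
    rows = []
    for H in cfg.hidden_sizes:
        for i in range(cfg.cohort):
            seed = derive_seed(cfg.seed, cfg.task, H, 10 + i)
            model = ValueRnn.init_default(H, seed)
            base = {"task": cfg.task, "hidden": H, "index": i, "seed": seed}
            try:
                m0 = evaluate_model(model, data, noise_seed=seed,
                                    decode=decode)
                rows += [dict(base, stage="untrained", metric=k, value=v)
                         for k, v in m0.items()]
                result = train_td(model, train_session, cfg.train_config(seed))
                m1 = evaluate_model(result.model, data, noise_seed=seed,
                                    decode=decode)
                m1["final_loss"] = min(result.losses)
                m1["n_epochs"] = len(result.losses)
                rows += [dict(base, stage="trained", metric=k, value=v)
                         for k, v in m1.items()]
            except Exception as exc:  # noqa: BLE001 — logged, not silenced
                rows.append(dict(base, stage="error", metric="error",
                                 value=np.nan, error=repr(exc)))
            if progress:
                print(f"[cohort {cfg.task} H={H}] model {i + 1}/{cfg.cohort} done",
                      flush=True)
    return pd.DataFrame(rows)


def run_esn_sweep(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Value ESNs across an initialization-gain grid (one per gain by default)."""
    cfg = config.resolved()
    if not cfg.esn_gains:
        raise ValueError("esn_gains is empty")
    data = make_probe_data(cfg.task, derive_seed(cfg.seed, cfg.task, 0, 0),
                           eval_trials=cfg.eval_trials)
    train_session = generate_session(
        task_config(cfg.task), cfg.session_trials,
        derive_seed(cfg.seed, cfg.task, 0, 1),
    )
    rows = []
    H = cfg.hidden_sizes[0]
    for gain in cfg.esn_gains:
        for i in range(cfg.cohort):
            seed = derive_seed(cfg.seed, cfg.task, H, 1000 + i)
            model = ValueRnn.init_esn(H, gain, seed)
            base = {"task": cfg.task, "hidden": H, "gain": gain,
                    "index": i, "seed": seed}
            try:
                result = train_td(model, train_session, cfg.train_config(seed))
                m = evaluate_model(result.model, data, noise_seed=seed)
                rows += [dict(base, metric=k, value=v) for k, v in m.items()]
            except Exception as exc:  # noqa: BLE001
                rows.append(dict(base, metric="error", value=np.nan,
                                 error=repr(exc)))
            if progress:
                print(f"[esn gain={gain}] model {i + 1}/{cfg.cohort} done",
                      flush=True)
    return pd.DataFrame(rows)


def summarize_cohort(results: pd.DataFrame,
                     by: tuple[str, ...] = ("task", "hidden", "stage", "metric"),
                     ) -> pd.DataFrame:
    """Cohort mean ± SE per metric."""
    ok = results[results["metric"] != "error"]
    by = [c for c in by if c in ok.columns]
    g = ok.groupby(list(by))["value"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"count": "n"})
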