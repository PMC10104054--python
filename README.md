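# beliefrnn

Reinforcement-learning models of dopamine reward prediction errors in
partially observable Pavlovian conditioning, and tools for asking whether a
recurrent network trained only to predict reward ends up representing
Bayesian beliefs.

## The problem

In trace-conditioning tasks an animal hears/smells a cue and receives a
reward after a variable delay — sometimes not at all, or with a hidden
block-dependent size. The environment state (waiting for a cue vs. waiting
for a reward; which reward block is active) is only partially observable.
Classical TD learning needs a Markov state, and the canonical fix is the
**belief state**: the posterior over hidden states given the observation
history,

    b_t(k') ∝ Σ_k O_o(k',k) T(k',k) b_{t−1}(k),

with value estimated linearly from beliefs, V̂_t = wᵀb_t + w0, and the TD
error (the reward-prediction-error signal carried by dopamine)

    δ_t = r_{t+1} + γ V̂_{t+1} − V̂_t .

An alternative needs no knowledge of (T, O): let a GRU learn its own state,
z_t = f_φ(z_{t−1}, o_t), and train everything end-to-end by semi-gradient
TD on observations alone (a **Value RNN**), or freeze the recurrence at a
gain-scaled orthogonal initialization and learn only the readout (a
**Value ESN**). This package implements the tasks, the belief filter, the
TD/LSTD machinery, the numpy GRU trainer, and the probes that measure how
belief-like a learned representation is:

* **belief R²** — held-out total variance of beliefs explained by a linear
  readout of the representation;
* **state decoding** — multinomial logistic decoding of the true hidden
  micro-state, scored by held-out log-likelihood against the belief ceiling;
* **dynamics** — null-input fixed points and the number of steps activity
  takes to return to them after an odor or reward ("odor/reward memory").

Tasks: the two Starkweather tasks (discretized-Gaussian reward delays of
6–14 steps at 200 ms/step; Task 1 always rewarded, Task 2 with 10%
omissions; 25 micro-states) and the Babayan block task (5-trial blocks of
reward size 1 or 10, uniform 9–11 step delays; 2 × 22 micro-states plus a
block posterior updated from each reward).

## Worked example

```python
import numpy as np
from beliefrnn import (
    StarkweatherConfig, generate_session, build_starkweather_space,
    run_beliefs, lstd_fit, td_errors,
)
from beliefrnn.td import rpe_summaries

cfg = StarkweatherConfig(variant=2)            # 10% omission task
session = generate_session(cfg, 4000, rng=1)   # ~113k time steps
space = build_starkweather_space(cfg)          # K=25 micro-states
B = run_beliefs(space, session)                # posterior per time step
readout = lstd_fit(B, session.reward, gamma=0.93)
delta = td_errors(readout.values(B), session.reward, 0.93)
print(rpe_summaries(session, delta)[["group", "mean"]].to_string(index=False))
```

```
 group     mean
     6 0.353693
     7 0.309983
     8 0.275207
     9 0.251304
    10 0.242672
    11 0.262425
    12 0.313002
    13 0.417123
    14 0.596866
```

The belief model's RPE at reward delivery is U-shaped in reward time for
the omission task: early rewards are surprising because the hazard is still
low; *late* rewards are surprising again because by then the posterior
favors the omission interpretation. In Task 1 (no omissions) the same
computation decreases monotonically to exactly 0 at the last possible
reward time — the hazard leaves nothing unpredicted.

Training a Value RNN and probing it:

```python
from beliefrnn import ValueRnn, TrainConfig, train_td
from beliefrnn.experiments import make_probe_data, evaluate_model

model = ValueRnn.init_default(50, seed=0)
result = train_td(model, session, TrainConfig(max_epochs=100, seed=0))
data = make_probe_data("starkweather2", seed=12345)
print(evaluate_model(result.model, data, noise_seed=0))
```

Typical desk-scale outcome (4,000-trial session, ≤100 epochs, a couple of
minutes on one CPU): belief R² rises from ≈0.48 untrained to ≈0.72 trained,
the RPE mean-squared error versus the belief model falls by two orders of
magnitude, one null-input fixed point remains, and the trained network's
activity returns to it within a few tens of steps after an odor.

## Analysis pipeline

Numbered scripts under `analysis/` re-run the study end to end and write
tidy tables under `results/` (figures via `analysis/07_figures.py`):

1. `01_simulate_tasks.py` — example sessions and interval statistics
2. `02_belief_model.py` — belief filtering, LSTD values, RPE curves, belief dynamics
3. `03_train_value_rnns.py` — Value RNN cohorts per task (`--full` for N=12/150 epochs)
4. `04_capacity_sweep.py` — hidden-size sweep
5. `05_esn_sweep.py` — echo-state gain sweep
6. `06_dynamics_traces.py` — fixed-point distance traces and PCA trajectories

A thin CLI covers the common cases: `beliefrnn simulate`, `beliefrnn
train`, `beliefrnn run`, `beliefrnn figures`.

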