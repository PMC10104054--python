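# Methods

## Tasks as micro-state Markov chains

All tasks are discrete-time (one step ≙ 200 ms, stored as metadata only;
every computation is in steps). A trial is an intertrial interval (ITI), a
single odor, an interstimulus interval (ISI), and a reward step (empty on
omission trials). The ITI is `iti_min = 10` deterministic steps plus a
geometric tail, `t_ITI − 10 ~ Geom(p_ITI = 1/8)` on {1, 2, …}, so the
shortest odor-to-previous-reward gap is 11 steps and the odor hazard is
constant once the minimum has elapsed. Starkweather ISIs are a Gaussian
(μ = 10, σ = 2.5) evaluated at the integers 6…14 and renormalized —
"discretized Gaussian" is read as pdf-at-integers, the simplest convention
consistent with the stated support; Babayan ISIs are uniform on {9, 10, 11}.

The equivalent hidden-Markov formulation indexes elapsed time explicitly:
ISI micro-states 1…14 with reward hazard h_t = p_t / (1 − F_{t−1}) (the
hazard at the last support point is 1 by construction; the alternative
reading h_t = p_t / (1 − F_t) is undefined there), ITI micro-states with 10
deterministic advances into an absorbing odor-hazard state; K = 25 for
Starkweather, K = 22 per block copy for Babayan. Observations (null, odor,
reward) attach to *transitions*: O_o(k′,k) is the probability that the
transition k → k′ emits o. In Task 2 the odor transition splits, going to
the first ISI state with probability 1 − p_omission and straight back to
the ITI start with probability p_omission = 0.1 — after an odor the agent
cannot tell whether a reward is coming.

Ground-truth labels are attached per step by the generator and are
consistent with (T, O) by construction; the test suite verifies every
transition/emission pair. On omission trials the true state jumps to the
ITI start at the odor, so the post-odor period of an omission trial is
ITI advance — the generative trial still has its scheduled ISI period
(null observations), which the chain happily assigns positive probability.

Babayan block identities are resampled uniformly every 5 trials. With
probes enabled, standard blocks (rewards 1 and 10) carry 45% weight each
and each intermediate size {2, 4, 6, 8} carries 2.5%, keeping standard
blocks at ~90% of trials.

## Beliefs

The belief update is b_t(k′) ∝ Σ_k O_o(k′,k) T(k′,k) b_{t−1}(k),
renormalized each step; sessions start with a point mass on the absorbing
ITI state (sessions begin in an ITI). An observation with zero probability
under the model raises an explicit error rather than silently
renormalizing — this surfaces task/space mismatches (and is the expected
behavior for Task 1 beliefs under nulls beyond the last reward time, where
the posterior is genuinely undefined).

For the Babayan task the full belief is the 44-dimensional concatenation
[p_t·b⁽¹⁾, (1−p_t)·b⁽²⁾] of the two block copies, where the block
posterior p_t is re-estimated only at nonzero rewards through the Normal
likelihood ratio f(r) = φ(r; μ₁, σ_r) / (φ(r; μ₁, σ_r) + φ(r; μ₂, σ_r))
with μ₁ = 1, μ₂ = 10, σ_r = 0.001 (computed in log space; with σ_r this
small, f is effectively a step at the midpoint 5.5). The block prior at
session start is 0.5 (uniform over blocks; the first trial's odor therefore
engages both copies equally).

## Values, TD errors, LSTD

Value weights for *every* representation (beliefs, trained GRUs, frozen
reservoirs) are fit by least-squares TD with an intercept feature appended:
D̂ = Σ_t z̃_t (z̃_t − γ z̃_{t+1})ᵀ, d̂ = Σ_t r_{t+1} z̃_t, ŵ = D̂⁻¹ d̂, with
γ = 0.93 throughout.

**Alignment.** The representation z_t has consumed o_t, and the TD error of
the transition t → t+1 is δ_t = r_{t+1} + γV̂_{t+1} − V̂_t; the RPE "at the
time of reward" is δ of the transition that delivers the reward. The
alternative pairing (the current step's reward in δ_t) makes the reward
already part of the conditioning state, which collapses the reward-time
RPE to a constant for the fully observable task — incompatible with any of
the phenomena this model family exists to produce — so the standard
alignment above is used everywhere, in LSTD, in the RPE traces, and in the
RNN training loss.

With this machinery the belief model's reward-time RPE *decreases* with
reward time in the deterministic task (the rising hazard makes late rewards
fully predicted; δ = 0 exactly at the last possible time) and grows at late
times in the omission task (the posterior drifts toward the omission
interpretation, so a late reward is a surprise). These are the directions
the implementation asserts in its tests.

Numerics: D̂ is solved by least squares. Beliefs plus an intercept are
exactly collinear (the posterior sums to one), so D̂ is singular but the
system is consistent; the minimum-norm solution is the TD value function
and predictions on the belief simplex are unique. A singular *and
inconsistent* system raises a rank-deficiency error naming the
representation; an explicit ridge option (default off) exists for
degenerate representations.

## Value RNN training

The network is a standard GRU (reset/update/candidate gates) with a linear
value readout; inputs are the raw observations o_t = [c_t, r_t]. Default
initialization: every parameter i.i.d. uniform(−1/√H, 1/√H). Training
minimizes Σ_t δ_t² per episode by semi-gradient TD — the bootstrap target
r_{t+1} + γV̂_{t+1} is held constant under differentiation (a full-gradient
option exists, default off) — using Adam at learning rate 0.003, batches of
12 episodes, episodes of 20 consecutive trials (50 for Babayan) cut from
the training session and reshuffled each epoch, hidden state zeroed at
episode starts, no TD term for an episode's last step. Training stops after 4 consecutive epochs of
increasing loss (or at 150 epochs), and parameters from the best epoch are
kept. The epoch loss oscillates on a multi-epoch scale under this
optimizer, so the consecutive-increase rule (which any downtick resets) is
markedly more robust here than a no-improvement patience rule, which
fires at the first plateau; keep-best makes the stopping time mostly a
compute budget. Forward, BPTT, and Adam are hand-written
numpy; gradient correctness is established against finite differences and
an independent scalar-loop GRU implementation in the tests.

The Value ESN freezes the GRU core: biases zero, each gate's recurrent
block an independent random orthogonal H×H matrix scaled by the gain,
input weights Xavier-uniform (bound √(6/(2+H))). Per-gate orthogonality
puts the origin Jacobian of the null-input map at 0.5·I + 0.25·Q_n, i.e.
spectral radius 0.5 + 0.25·gain, so reservoir time constants grow with
gain and stability is lost above gain 2 — matching the observed behavior
of these models. Only (w, w0) train; the core is verified bit-identical
after training.

## Probes

Analyses use two sessions of 1,000 concatenated trials (fit and held-out
evaluation). RNN traces receive zero-mean Gaussian noise with per-unit sd
0.01·σ_i (40 dB SNR; σ_i the unit's sd across the session, constant units
untouched) before any regression or decoding, because deterministic traces
otherwise overfit; beliefs stay noise-free, and PCA and dynamics use
noise-free traces.

* Belief R²: multivariate linear regression (with intercept) from
  representation to belief on the fit session, scored on the evaluation
  session as 1 − Var(B − ZŴ)/Var(B) with Var the total squared deviation
  from the row mean. Solved by a least-squares factorization rather than
  the literal normal-equations inverse.
* State decoding: per-unit standardization, then multinomial logistic
  regression (L2, C = 1, iteration cap 10⁴, scikit-learn); scored by mean
  held-out log π_t(s_t). Classes absent from the fit session are dropped
  and scored at a 1e−12 floor; non-convergence is recorded on the result.
  The belief ceiling uses the posterior itself as π_t. For Babayan the
  score excludes each block's first trial (the belief cannot yet know the
  block, so only then is it a valid ceiling).
* PCA: top-2 eigenvalue share of the mean-centered trace across time steps.

## Dynamics

Fixed points of the null-input map are found by iterating from seed states
(states sampled after odor/reward observations in held-out data) until the
squared step size falls below ε = 1e−5, keeping candidates that pass the
residual test ‖f(∅,z) − z‖² < ε and merging candidates within distance
1e−3; the iteration cap is 1,000 steps (well beyond every duration the
pipeline measures), and
non-convergent or impossible-observation seeds are counted, not fatal. By
default the ε-converged iterate itself is the fixed point, exactly as the
iterative procedure produces it; a `polish` option iterates candidates to
numerical precision for analyses sensitive to small offsets. Odor/reward
memory: start at the fixed point, apply the observation (odor [1, 0];
reward [0, r] at the task's magnitude) at t = 1, then nulls; the memory is
the first t with ‖z_t − z_0‖² below a threshold, with the cap reported
when never reached. The belief-side durations (15 steps after an odor in
the omission task, 11 after a reward) are threshold-insensitive because
the belief returns exactly; for RNN/reservoir maps, whose distance decays
geometrically, the pipeline measures from a polished fixed point with
Euclidean distance < 1e−3 (squared 1e−6) — the same tolerance that merges
fixed points, so a duration means "back within fixed-point resolution" —
and `memory_duration` keeps the threshold explicit.

For the belief map, a probing observation that is impossible at the fixed
point (a reward at the ITI point) falls back to the observation-conditioned
landing distribution from a uniform source; since every reward transition
lands on the same post-reward state, this yields the deterministic 11-step
reward memory (10 ITI advances after the landing step). The omission-task
belief returns 15 steps after an odor; the deterministic task's odor
response is undefined past step 14 and is skipped rather than asserted.

## Problem sizes

The publication-scale protocol (N = 12 networks per cell, 10,000-trial
training sessions, up to 150 epochs) takes hours per cohort on one CPU.
The package's desk profile — the default in the analysis scripts and the
basis of `scripts/acceptance.py` — trains 2–3 networks per cell on
4,000–10,000-trial sessions (longest for the block task, whose loss needs
the most updates) for up to 80–120 epochs, a minute or two per network
with the jitted training loop, and evaluates on the full two-session,
1,000-trial protocol. At this scale the headline quantities are stable:
belief R² ≈ 0.65–0.79 (trained, per network), ≈ 0.46–0.50 (untrained,
tightly concentrated), a single fixed point for trained networks, and
top-2 PCA fractions within a few points of the full-scale values. Short
sessions (≲2,000 trials) make the epoch loss noisy enough to trigger the
early-stopping rule prematurely, which is why the desk profile lengthens
sessions rather than changing the stopping rule.

How far training gets before the stop rule fires varies across seeds, and
single-network quantities (notably the top-2 PCA fraction, which drops as
training distributes activity across finer temporal structure) vary with
it. Where a single exemplar is reported, the pipeline uses the cohort's
best-trained network (lowest training loss); cohort quantities are plain
means.

## What the generator does and does not emulate

The simulators reproduce the tasks' generative statistics exactly:
interval laws, omission probability, block resampling, probe mixtures, and
per-step micro-state labels. They do not model licking or other behavior,
sensory noise, trial-onset cues, continuous time, or scalar timing noise
(animals' temporal uncertainty grows with elapsed time; the chain's clock
is exact). Passing tests therefore validate the computational claims about
these idealized tasks, not quantitative fits to animal data.

## Known limitations

* Trained-network dynamics quantities (odor memory in particular) are
  sensitive to training duration and to the ε-converged fixed-point
  convention; cohort means at desk scale can sit tens of percent from
  full-scale values even when R²/PCA metrics agree closely.
* The Babayan composite belief treats the block posterior as a function of
  the most recent reward only, so it is a ceiling for decoding only when
  each block's first trial is excluded.
* LSTD on near-degenerate representations relies on the minimum-norm
  solution; value *weights* are then not unique (value predictions on the
  data manifold are).
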