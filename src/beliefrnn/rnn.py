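"""Value RNNs: a GRU with a linear value readout, trained by semi-gradient TD.

The network consumes the raw two-dimensional observation o_t = [c_t, r_t]
(odor flag, reward magnitude) and maintains a hidden state
z_t = f_φ(z_{t−1}, o_t); its value estimate is V̂_t = wᵀz_t + w0.  All
parameters θ = [φ, w, w0] are trained by backpropagation through time on
the semi-gradient TD loss Σ_t δ_t² with the bootstrap target
r_{t+1} + γV̂_{t+1} held constant under differentiation.

The echo-state variant (Value ESN) freezes φ at a gain-scaled orthogonal
initialization; only the readout (w, w0) is learned.

Everything here is plain numpy: the forward pass, backpropagation through
the GRU cell, and Adam are implemented explicitly and verified against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # jitted inner loops; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .tasks import BabayanConfig, Session

__all__ = [
    "ValueRnn",
    "TrainConfig",
    "TrainResult",
    "gru_step",
    "train_td",
    "save_model",
    "load_model",
]

CORE_KEYS = ("Wx", "Wh", "bx", "bh")
READOUT_KEYS = ("w", "w0")
ALL_KEYS = CORE_KEYS + READOUT_KEYS


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class ValueRnn:
    """GRU cell plus linear value readout.

    Weight layout follows the usual reset/update/candidate gate order:
    ``Wx`` (2, 3H) input weights, ``Wh`` (H, 3H) recurrent weights,
    ``bx``/``bh`` (3H,) biases, ``w`` (H,) and ``w0`` the value readout.
    ``core_trainable=False`` marks an echo-state network whose GRU
    parameters are frozen during TD training.
    """

    params: dict[str, np.ndarray]
    core_trainable: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def hidden_size(self) -> int:
        return self.params["Wh"].shape[0]

    @property
    def n_inputs(self) -> int:
        return self.params["Wx"].shape[0]

    # -- initializers -------------------------------------------------------

    @classmethod
    def init_default(cls, hidden_size: int, seed: int | None = None,
                     n_inputs: int = 2) -> "ValueRnn":
        """All GRU and readout parameters i.i.d. uniform(−1/√H, 1/√H)."""
        if hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        rng = np.random.default_rng(seed)
        a = 1.0 / np.sqrt(hidden_size)
        H = hidden_size
        params = {
            "Wx": rng.uniform(-a, a, (n_inputs, 3 * H)),
            "Wh": rng.uniform(-a, a, (H, 3 * H)),
            "bx": rng.uniform(-a, a, 3 * H),
            "bh": rng.uniform(-a, a, 3 * H),
            "w": rng.uniform(-a, a, H),
            "w0": np.array([rng.uniform(-a, a)]),
        }
        return cls(params=params, meta={"init": "default", "seed": seed})

    @classmethod
    def init_esn(cls, hidden_size: int, gain: float, seed: int | None = None,
                 n_inputs: int = 2) -> "ValueRnn":
        """Echo-state initialization: gain-scaled orthogonal recurrence.

        Each gate's recurrent block is an independent random orthogonal
        (H, H) matrix scaled by ``gain`` (QᵀQ = gain²·I per gate), which
        places the null-input stability edge of the GRU at gain = 2: the
        origin Jacobian is 0.5·I + 0.25·Q_n, with spectral radius
        0.5 + 0.25·gain.  Input weights are Xavier-uniform with bound
        √(6/(n_inputs + H)); biases are zero.  The returned model has
        ``core_trainable=False``.
        """
        if hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if gain <= 0:
            raise ValueError("gain must be > 0")
        rng = np.random.default_rng(seed)
        H = hidden_size
        blocks = []
        for _ in range(3):
            G = rng.normal(size=(H, H))
            Q, R = np.linalg.qr(G)
            blocks.append(Q * np.sign(np.diag(R)))  # deterministic sign convention
        Q = np.vstack(blocks)
        a_in = np.sqrt(6.0 / (n_inputs + H))
        a_w = 1.0 / np.sqrt(H)
        params = {
            "Wx": rng.uniform(-a_in, a_in, (n_inputs, 3 * H)),
            "Wh": (gain * Q).T,
            "bx": np.zeros(3 * H),
            "bh": np.zeros(3 * H),
            "w": rng.uniform(-a_w, a_w, H),
            "w0": np.array([rng.uniform(-a_w, a_w)]),
        }
        return cls(params=params, core_trainable=False,
                   meta={"init": "esn", "gain": gain, "seed": seed})

    # -- forward ------------------------------------------------------------

    def step(self, o: np.ndarray, z_prev: np.ndarray) -> np.ndarray:
        """Single GRU update for one observation (no batch dimension)."""
        return gru_step(self.params, np.asarray(o, float), np.asarray(z_prev, float))

    def forward(self, session_or_obs: Session | np.ndarray,
                z0: np.ndarray | None = None) -> np.ndarray:
        """Hidden-state trace Z (T, H) for a session's observation sequence."""
        X = (
            session_or_obs.observations
            if isinstance(session_or_obs, Session)
            else np.asarray(session_or_obs, dtype=float)
        )
        Z, _ = _forward_batch(self.params, X[:, None, :],
                              None if z0 is None else z0[None, :])
        return Z[:, 0, :]

    def values(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.params["w"] + self.params["w0"][0]

    def copy(self) -> "ValueRnn":
        return ValueRnn(
            params={k: v.copy() for k, v in self.params.items()},
            core_trainable=self.core_trainable,
            meta=dict(self.meta),
        )


def gru_step(params: dict[str, np.ndarray], o: np.ndarray,
             z_prev: np.ndarray) -> np.ndarray:
    """Standard GRU cell update.

    r = σ(W_ir o + b_ir + W_hr z + b_hr),  u = σ(W_iu o + b_iu + W_hu z + b_hu),
    n = tanh(W_in o + b_in + r ∘ (W_hn z + b_hn)),  z' = (1−u)∘n + u∘z.
    """
    H = params["Wh"].shape[0]
    if o.shape[-1] != params["Wx"].shape[0] or z_prev.shape[-1] != H:
        raise ValueError("input/hidden dimensions do not match parameters")
    gi = o @ params["Wx"] + params["bx"]
    gh = z_prev @ params["Wh"] + params["bh"]
    r = _sigmoid(gi[..., :H] + gh[..., :H])
    u = _sigmoid(gi[..., H:2 * H] + gh[..., H:2 * H])
    n = np.tanh(gi[..., 2 * H:] + r * gh[..., 2 * H:])
    return (1 - u) * n + u * z_prev


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _fwd_loop(GI, Wh, bh, h0, Z, R, U, N, GHN):  # pragma: no cover — jitted
        T, B, H3 = GI.shape
        H = H3 // 3
        h = h0.copy()
        for t in range(T):
            gh = h @ Wh
            for b in range(B):
                for j in range(H):
                    r = 1.0 / (1.0 + np.exp(-(GI[t, b, j] + gh[b, j] + bh[j])))
                    u = 1.0 / (1.0 + np.exp(
                        -(GI[t, b, H + j] + gh[b, H + j] + bh[H + j])))
                    ghn = gh[b, 2 * H + j] + bh[2 * H + j]
                    n = np.tanh(GI[t, b, 2 * H + j] + r * ghn)
                    R[t, b, j] = r
                    U[t, b, j] = u
                    N[t, b, j] = n
                    GHN[t, b, j] = ghn
                    Z[t, b, j] = (1.0 - u) * n + u * h[b, j]
            h = Z[t].copy()

    @_njit(cache=False)
    def _bwd_loop(R, U, N, GHN, H_prev, WhT, dZ, dGI, dGHn):  # pragma: no cover
        T, B, H = R.shape
        dh_next = np.zeros((B, H))
        dgh = np.empty((B, 3 * H))
        for t in range(T - 1, -1, -1):
            for b in range(B):
                for j in range(H):
                    dh = dZ[t, b, j] + dh_next[b, j]
                    r = R[t, b, j]
                    u = U[t, b, j]
                    n = N[t, b, j]
                    dan = (dh * (1.0 - u)) * (1.0 - n * n)
                    dar = (dan * GHN[t, b, j]) * r * (1.0 - r)
                    dau = (dh * (H_prev[t, b, j] - n)) * u * (1.0 - u)
                    dghn = dan * r
                    dGI[t, b, j] = dar
                    dGI[t, b, H + j] = dau
                    dGI[t, b, 2 * H + j] = dan
                    dGHn[t, b, j] = dghn
                    dgh[b, j] = dar
                    dgh[b, H + j] = dau
                    dgh[b, 2 * H + j] = dghn
                    dh_next[b, j] = dh * u
            dh_next += dgh @ WhT


def _forward_batch(params, X, h0=None):
    """Batched forward pass. X: (T, B, D). Returns Z (T, B, H) and a cache.

    The input projection is hoisted out of the time loop; only the
    recurrent projection runs per step.  A numba-compiled loop is used when
    available; the numpy loop below is the mathematically identical
    reference (agreement is at machine precision).
    """
    T, B, _ = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H)) if h0 is None else np.broadcast_to(h0, (B, H)).copy()
    Z = np.empty((T, B, H))
    Wx, Wh, bx, bh = (params[k] for k in CORE_KEYS)
    GI = X.reshape(T * B, -1) @ Wx
    GI += bx
    GI = GI.reshape(T, B, 3 * H)
    R = np.empty((T, B, H))
    U = np.empty((T, B, H))
    N = np.empty((T, B, H))
    GHN = np.empty((T, B, H))
    if _HAVE_NUMBA:
        _fwd_loop(GI, Wh, bh, h, Z, R, U, N, GHN)
        return Z, (X, R, U, N, GHN, h0)
    for t in range(T):
        gh = h @ Wh + bh
        ru = _sigmoid(GI[t, :, :2 * H] + gh[:, :2 * H])
        r = ru[:, :H]
        u = ru[:, H:]
        ghn = gh[:, 2 * H:]
        n = np.tanh(GI[t, :, 2 * H:] + r * ghn)
        h = (1 - u) * n + u * h
        R[t], U[t], N[t], GHN[t], Z[t] = r, u, n, ghn, h
    cache = (X, R, U, N, GHN, h0)
    return Z, cache


def _backward_batch(params, Z, cache, dZ):
    """Backpropagation through time given per-step hidden-state gradients.

    The time loop carries only elementwise work and one matmul; weight
    gradients are accumulated in single batched contractions afterwards.
    """
    X, R, U, N, GHN, h0 = cache
    T, B, H = Z.shape
    Wh = params["Wh"]
    H_prev = np.empty_like(Z)
    H_prev[0] = 0.0 if h0 is None else h0
    H_prev[1:] = Z[:-1]
    dGI = np.empty((T, B, 3 * H))
    dGH_n = np.empty((T, B, H))
    if _HAVE_NUMBA:
        _bwd_loop(R, U, N, GHN, H_prev, np.ascontiguousarray(Wh.T), dZ,
                  dGI, dGH_n)
    else:
        dh_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            r, u, n, ghn, h_prev = R[t], U[t], N[t], GHN[t], H_prev[t]
            dh = dZ[t] + dh_next
            dan = (dh * (1 - u)) * (1 - n * n)
            dar = (dan * ghn) * r * (1 - r)
            dau = (dh * (h_prev - n)) * u * (1 - u)
            dgh_n = dan * r
            dGI[t, :, :H] = dar
            dGI[t, :, H:2 * H] = dau
            dGI[t, :, 2 * H:] = dan
            dGH_n[t] = dgh_n
            dgh = np.concatenate([dar, dau, dgh_n], axis=1)
            dh_next = dh * u + dgh @ Wh.T
    TB = T * B
    dGI_f = dGI.reshape(TB, 3 * H)
    Hp_f = H_prev.reshape(TB, H)
    dWh = Hp_f.T @ dGI_f
    dWh[:, 2 * H:] = Hp_f.T @ dGH_n.reshape(TB, H)
    dbh = dGI_f.sum(axis=0)
    dbh[2 * H:] = dGH_n.reshape(TB, H).sum(axis=0)
    g = {
        "Wx": X.reshape(TB, -1).T @ dGI_f,
        "bx": dGI_f.sum(axis=0),
        "Wh": dWh,
        "bh": dbh,
    }
    return g


@dataclass(frozen=True)
class TrainConfig:
    """TD training protocol.

    Episodes are disjoint consecutive blocks of ``episode_len_trials``
    trials (20 for Starkweather, 50 for Babayan), reshuffled each epoch;
    hidden state resets to zero at episode starts; the last step of an
    episode contributes no TD term.  Training stops early after
    ``patience`` consecutive epochs of increasing loss, and the parameters
    from the best epoch are kept.
    """

    episode_len_trials: int = 20
    batch_size: int = 12
    max_epochs: int = 150
    lr: float = 0.003
    patience: int = 4
    gamma: float = 0.93
    seed: int | None = None
    full_gradient: bool = False
    keep_best: bool = True
    clip_norm: float | None = None  # global gradient-norm clip (None = off)

    def __post_init__(self):
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must be in [0, 1)")
        for name in ("episode_len_trials", "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_task(cls, config, **kw) -> "TrainConfig":
        ep = 50 if isinstance(config, BabayanConfig) else 20
        return cls(episode_len_trials=ep, **kw)


@dataclass
class TrainResult:
    model: "ValueRnn"
    losses: list[float]
    best_epoch: int
    stopped_early: bool


class TrainingDiverged(FloatingPointError):
    """TD loss became non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite TD loss at epoch {epoch}")
        self.epoch = epoch


def _episodes(session: Session, ep_trials: int, rng: np.random.Generator):
    starts = session.trial_starts
    bounds = np.append(starts, len(session))
    n_ep = len(starts) // ep_trials
    order = rng.permutation(n_ep)
    X = session.observations
    R = session.reward
    out = []
    for e in order:
        a = bounds[e * ep_trials]
        b = bounds[(e + 1) * ep_trials]
        out.append((X[a:b], R[a:b]))
    return out


def _td_loss_and_grads(params, Xb, Rb, mask, gamma, full_gradient):
    T, B, _ = Xb.shape
    H = params["Wh"].shape[0]
    Z, cache = _forward_batch(params, Xb)
    V = (Z.reshape(T * B, H) @ params["w"]).reshape(T, B) + params["w0"][0]
    delta = np.zeros((T, B))
    delta[:-1] = (Rb[1:] + gamma * V[1:] - V[:-1]) * mask[:-1]
    loss = float((delta**2).sum() / B)
    dV = np.zeros((T, B))
    dV[:-1] = -2.0 * delta[:-1] / B
    if full_gradient:
        dV[1:] += 2.0 * gamma * delta[:-1] / B
    dZ = dV[..., None] * params["w"][None, None, :]
    g = _backward_batch(params, Z, cache, dZ)
    g["w"] = dV.reshape(T * B) @ Z.reshape(T * B, H)
    g["w0"] = np.array([dV.sum()])
    return loss, g


def train_td(model: ValueRnn, session: Session,
             config: TrainConfig | None = None) -> TrainResult:
    """Train a Value RNN (or the readout of a Value ESN) by semi-gradient TD.

    Returns a new model; the input model is not modified.  For echo-state
    models only the readout receives Adam updates — the GRU core is
    bit-identical before and after training.
    """
    config = config or TrainConfig()
    model = model.copy()
    p = model.params
    rng = np.random.default_rng(config.seed)
    trainable = ALL_KEYS if model.core_trainable else READOUT_KEYS

    m = {k: np.zeros_like(p[k]) for k in trainable}
    v = {k: np.zeros_like(p[k]) for k in trainable}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses: list[float] = []
    best_loss, best_params, best_epoch = np.inf, None, -1
    n_increasing = 0
    stopped = False

    for epoch in range(config.max_epochs):
        eps_list = _episodes(session, config.episode_len_trials, rng)
        n_full = len(eps_list) - len(eps_list) % config.batch_size
        if n_full == 0:
            raise ValueError(
                "session too short for one full batch of episodes"
            )
        epoch_losses = []
        for i in range(0, n_full, config.batch_size):
            group = eps_list[i:i + config.batch_size]
            Tmax = max(len(x) for x, _ in group)
            B = len(group)
            Xb = np.zeros((Tmax, B, group[0][0].shape[1]))
            Rb = np.zeros((Tmax, B))
            mask = np.zeros((Tmax, B))
            for j, (x, r) in enumerate(group):
                L = len(x)
                Xb[:L, j] = x
                Rb[:L, j] = r
                mask[:L - 1, j] = 1.0
            loss, g = _td_loss_and_grads(
                p, Xb, Rb, mask, config.gamma, config.full_gradient
            )
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            if config.clip_norm is not None:
                total = np.sqrt(sum(float((g[k] ** 2).sum()) for k in trainable))
                if total > config.clip_norm:
                    scale = config.clip_norm / total
                    for k in trainable:
                        g[k] = g[k] * scale
            step += 1
            for k in trainable:
                m[k] = b1 * m[k] + (1 - b1) * g[k]
                v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                p[k] -= config.lr * mh / (np.sqrt(vh) + eps)
            epoch_losses.append(loss)
        L = float(np.mean(epoch_losses))
        losses.append(L)
        if L < best_loss:
            best_loss = L
            best_epoch = epoch
            if config.keep_best:
                best_params = {k: p[k].copy() for k in trainable}
        # stop on `patience` consecutive epoch-to-epoch increases; the TD loss
        # oscillates on a multi-epoch scale, so any downtick resets the count
        # and keep_best retains the best parameters seen
        if len(losses) > 1 and losses[-1] > losses[-2]:
            n_increasing += 1
            if n_increasing >= config.patience:
                stopped = True
                break
        else:
            n_increasing = 0

    if config.keep_best and best_params is not None:
        p.update(best_params)
    model.meta.update(
        {"trained": True, "best_epoch": best_epoch, "n_epochs": len(losses)}
    )
    return TrainResult(model=model, losses=losses,
                       best_epoch=best_epoch, stopped_early=stopped)


# ---------------------------------------------------------------------------
# checkpoints: flat named-array JSON container


def save_model(model: ValueRnn, path: str | Path,
               losses: list[float] | None = None) -> None:
    payload = {
        "params": {k: v.tolist() for k, v in model.params.items()},
        "core_trainable": model.core_trainable,
        "meta": model.meta,
        "losses": losses,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ValueRnn:
    payload = json.loads(Path(path).read_text())
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    H = params["Wh"].shape[0]
    expected = {
        "Wx": (params["Wx"].shape[0], 3 * H), "Wh": (H, 3 * H),
        "bx": (3 * H,), "bh": (3 * H,), "w": (H,), "w0": (1,),
    }
    for k, shape in expected.items():
        if params[k].shape != shape:
            raise ValueError(f"checkpoint parameter {k} has shape "
                             f"{params[k].shape}, expected {shape}")
    return ValueRnn(params=params, core_trainable=payload["core_trainable"],
                    meta=payload.get("meta", {}))
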