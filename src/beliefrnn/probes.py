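"""Belief-likeness probes: regression to beliefs, state decoding, PCA.

All probes follow a fit/evaluate protocol on two disjoint sessions.
Because RNN activity is a deterministic function of its inputs, Gaussian
noise at a fixed 40 dB SNR is injected into RNN representations before any
fitting, to keep the held-out scores honest; beliefs are left noise-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "inject_noise",
    "belief_r2",
    "StateDecoder",
    "fit_state_decoder",
    "decoder_loglik",
    "beliefs_loglik",
    "pca_top2",
]

PROB_FLOOR = 1e-12


def inject_noise(Z: np.ndarray, rng: np.random.Generator,
                 snr_sd_fraction: float = 0.01) -> np.ndarray:
    """Add per-unit zero-mean Gaussian noise with sd = 0.01·σ_i (40 dB SNR).

    σ_i is unit i's sample standard deviation across the trace; constant
    units receive no noise.
    """
    Z = np.asarray(Z, dtype=float)
    sd = Z.std(axis=0)
    return Z + rng.normal(0.0, 1.0, Z.shape) * (snr_sd_fraction * sd)


def _total_variance(X: np.ndarray) -> float:
    """(1/T) Σ_t ‖x_t − x̄‖² — total squared deviation from the row mean."""
    return float(((X - X.mean(axis=0)) ** 2).sum() / len(X))


def belief_r2(Z_fit: np.ndarray, B_fit: np.ndarray,
              Z_eval: np.ndarray, B_eval: np.ndarray) -> float:
    """Held-out total variance of beliefs explained by a linear readout of Z.

    A multivariate linear regression (with intercept) maps the
    representation to the belief vector on the fit session; R² is evaluated
    on the second session as 1 − Var(B − ZŴ)/Var(B) with Var the total
    variance across rows.  Solved by least squares (numerically equivalent
    to the normal equations when those are well posed).
    """
    if len(Z_fit) != len(B_fit) or len(Z_eval) != len(B_eval):
        raise ValueError("representation and belief traces must align per session")
    Z1 = np.hstack([Z_fit, np.ones((len(Z_fit), 1))])
    W, *_ = np.linalg.lstsq(Z1, B_fit, rcond=None)
    Z1e = np.hstack([Z_eval, np.ones((len(Z_eval), 1))])
    resid = B_eval - Z1e @ W
    return 1.0 - _total_variance(resid) / _total_variance(B_eval)


@dataclass
class StateDecoder:
    """Multinomial logistic decoder with frozen per-unit standardization."""

    scaler: StandardScaler
    clf: LogisticRegression
    classes: np.ndarray
    converged: bool = True
    dropped_classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def predict_proba(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Class probabilities π_t (columns ordered by ``classes``)."""
        return self.clf.predict_proba(self.scaler.transform(Z)), self.classes


def fit_state_decoder(Z_fit: np.ndarray, states_fit: np.ndarray,
                      n_states: int | None = None,
                      max_iter: int = 10_000, C: float = 1.0) -> StateDecoder:
    """Multinomial logistic regression from representation to true state.

    Features are standardized (fit-session mean/sd); the decoder carries
    that standardization.  Classes absent from the fit session are dropped
    and later scored at a probability floor.  Non-convergence is recorded
    on the result rather than raised.
    """
    scaler = StandardScaler().fit(Z_fit)
    clf = LogisticRegression(C=C, max_iter=max_iter)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(scaler.transform(Z_fit), states_fit)
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
    present = clf.classes_
    dropped = (
        np.setdiff1d(np.arange(n_states), present)
        if n_states is not None
        else np.array([], dtype=int)
    )
    return StateDecoder(scaler=scaler, clf=clf, classes=present,
                        converged=converged, dropped_classes=dropped)


def _mean_loglik(P: np.ndarray, classes: np.ndarray,
                 states: np.ndarray, mask: np.ndarray | None) -> float:
    col = {c: i for i, c in enumerate(classes)}
    idx = np.array([col.get(s, -1) for s in states])
    probs = np.where(idx >= 0, P[np.arange(len(states)), np.clip(idx, 0, None)], 0.0)
    probs = np.clip(probs, PROB_FLOOR, None)
    ll = np.log(probs)
    if mask is not None:
        ll = ll[mask]
    return float(ll.mean())


def decoder_loglik(decoder: StateDecoder, Z_eval: np.ndarray,
                   states_eval: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Held-out mean log-likelihood ℓ = (1/T) Σ_t log π_t(s_t)."""
    P, classes = decoder.predict_proba(Z_eval)
    return _mean_loglik(P, classes, states_eval, mask)


def beliefs_loglik(B_eval: np.ndarray, states_eval: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Log-likelihood ceiling: the belief itself used as π_t (no decoder)."""
    classes = np.arange(B_eval.shape[1])
    return _mean_loglik(B_eval, classes, states_eval, mask)


def pca_top2(Z: np.ndarray) -> tuple[np.ndarray, float]:
    """Top-2 principal-component projection and their variance fraction."""
    Z = np.asarray(Z, dtype=float)
    if len(Z) <= 2:
        raise ValueError("need more than 2 time steps for PCA")
    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    proj = Zc @ Vt[:2].T
    ev = S**2
    return proj, float(ev[:2].sum() / ev.sum())
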