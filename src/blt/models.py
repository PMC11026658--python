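"""Rescorla-Wagner state equations and observation models.

Learning model
--------------
The predicted outcome evolves as ``v[t+1] = v[t] + alpha * (o[t] - v[t])``
with ``v[0] = v0`` (0.5: complete uncertainty).  The dual-rate variant uses
``alpha_p`` on positive-valence trials (no resistance, ``s = 0``) and
``alpha_n`` on negative-valence trials (resistance, ``s = 1``).

Observation models
------------------
*Binary*: the probability of predicting "resistance pairing" is a softmax of
the predicted outcome, ``p = exp(beta*v) / (exp(beta*v) + exp(beta*(1-v)))``,
equivalently ``logistic(beta * (2v - 1))``; ``beta`` is the inverse
temperature (larger = more deterministic choices).

*Continuous*: a slider response in [0, 1] is modelled as Beta-distributed
around the predicted outcome using the mean-dispersion parameterisation
``a = mu * phi``, ``b = (1 - mu) * phi``; the dispersion ``phi`` is shared
across subjects and trials (larger ``phi`` = tighter responses = less noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, log_expit

__all__ = [
    "ModelParams",
    "Trajectory",
    "rw_trajectory",
    "rw_dual_trajectory",
    "softmax_prob",
    "binary_loglik",
    "beta_shapes",
    "continuous_loglik",
    "BOUNDARY_EPS",
]

#: Responses and means are clipped to [BOUNDARY_EPS, 1 - BOUNDARY_EPS] before
#: beta-density evaluation (the density is degenerate at the boundary).
BOUNDARY_EPS = 1e-4


@dataclass(frozen=True)
class ModelParams:
    """Container for model parameters with bound checking.

    ``alpha`` is used by single-rate models, ``alpha_p``/``alpha_n`` by the
    dual-rate model; ``beta`` belongs to the binary observation model and
    ``phi`` to the continuous one.  ``v0`` is fixed at 0.5 by design.
    """

    alpha: float | None = None
    alpha_p: float | None = None
    alpha_n: float | None = None
    beta: float | None = None
    phi: float | None = None
    v0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_p", "alpha_n"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.beta is not None and self.beta <= 0:
            raise ValueError(f"beta={self.beta} must be positive")
        if self.phi is not None and self.phi <= 0:
            raise ValueError(f"phi={self.phi} must be positive")
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError(f"v0={self.v0} outside [0, 1]")


@dataclass(frozen=True)
class Trajectory:
    """A Rescorla-Wagner prediction trajectory.

    ``v`` has length ``n_trials + 1``: ``v[t]`` is the prediction *before*
    outcome ``t`` is observed and ``v[-1]`` the final post-session belief.
    ``delta[t] = o[t] - v[t]`` is the prediction error (NaN on trials with a
    missing outcome, where ``v`` is carried forward unchanged).
    """

    v: np.ndarray
    delta: np.ndarray

    @property
    def v_pred(self) -> np.ndarray:
        """Per-trial predictions aligned with the outcome sequence."""
        return self.v[:-1]


def _check_rate(alpha: float, name: str = "alpha") -> float:
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"{name}={alpha} outside [0, 1]")
    return alpha


def rw_trajectory(o, alpha: float, v0: float = 0.5) -> Trajectory:
    """Run the single-rate Rescorla-Wagner update over an outcome sequence.

    Missing outcomes (NaN) leave the prediction unchanged.
    """
    alpha = _check_rate(alpha)
    o = np.asarray(o, dtype=float)
    n = o.shape[0]
    v = np.empty(n + 1)
    delta = np.empty(n)
    v[0] = v0
    for t in range(n):
        if np.isnan(o[t]):
            delta[t] = np.nan
            v[t + 1] = v[t]
        else:
            delta[t] = o[t] - v[t]
            v[t + 1] = v[t] + alpha * delta[t]
    return Trajectory(v=v, delta=delta)


def rw_dual_trajectory(
    o, s, alpha_p: float, alpha_n: float, v0: float = 0.5
) -> Trajectory:
    """Valence-conditional Rescorla-Wagner update.

    The learning rate on trial ``t`` is ``alpha_p`` when ``s[t] = 0`` (no
    resistance, positive valence) and ``alpha_n`` when ``s[t] = 1``
    (resistance, negative valence).  With equal rates this reduces exactly to
    :func:`rw_trajectory`.
    """
    alpha_p = _check_rate(alpha_p, "alpha_p")
    alpha_n = _check_rate(alpha_n, "alpha_n")
    o = np.asarray(o, dtype=float)
    s = np.asarray(s)
    if o.shape != s.shape:
        raise ValueError(f"o and s length mismatch: {o.shape} vs {s.shape}")
    n = o.shape[0]
    v = np.empty(n + 1)
    delta = np.empty(n)
    v[0] = v0
    for t in range(n):
        if np.isnan(o[t]):
            delta[t] = np.nan
            v[t + 1] = v[t]
        else:
            delta[t] = o[t] - v[t]
            rate = alpha_n if s[t] == 1 else alpha_p
            v[t + 1] = v[t] + rate * delta[t]
    return Trajectory(v=v, delta=delta)


def softmax_prob(v, beta: float):
    """Probability of the "o = 1" prediction under the softmax rule.

    Computed as ``logistic(beta * (2v - 1))``, which is algebraically equal to
    ``exp(beta*v) / (exp(beta*v) + exp(beta*(1-v)))`` but does not overflow
    for large ``beta``.
    """
    if beta <= 0:
        raise ValueError(f"beta={beta} must be positive")
    v = np.asarray(v, dtype=float)
    out = expit(beta * (2.0 * v - 1.0))
    return out.item() if out.ndim == 0 else out


def binary_loglik(yb, traj: Trajectory, beta: float) -> float:
    """Log-likelihood of binarised responses under the softmax model.

    ``yb`` contains 0/1 responses with NaN marking missed trials (which
    contribute nothing).  Raises if every trial is missing.
    """
    if beta <= 0:
        raise ValueError(f"beta={beta} must be positive")
    yb = np.asarray(yb, dtype=float)
    v = traj.v_pred
    if yb.shape[0] != v.shape[0]:
        raise ValueError("response and trajectory lengths differ")
    mask = ~np.isnan(yb)
    if not mask.any():
        raise ValueError("all responses missing: likelihood undefined")
    x = beta * (2.0 * v[mask] - 1.0)
    y = yb[mask]
    # log p(y=1) = log_expit(x); log p(y=0) = log_expit(-x)
    return float(np.sum(y * log_expit(x) + (1.0 - y) * log_expit(-x)))


def beta_shapes(mu, phi):
    """Mean-dispersion to shape-parameter conversion: ``(mu*phi, (1-mu)*phi)``.

    The resulting Beta(a, b) has mean ``mu`` and concentration ``a + b = phi``.
    """
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        raise ValueError(f"phi={phi} must be positive")
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly inside (0, 1); clip upstream")
    a = mu * phi
    b = (1.0 - mu) * phi
    if a.ndim == 0:
        return a.item(), b.item()
    return a, b


def _beta_logpdf(y, mu, phi):
    """Elementwise beta log-density in the mean-dispersion parameterisation."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def continuous_loglik(
    y, traj: Trajectory, phi: float, eps: float = BOUNDARY_EPS
) -> float:
    """Log-likelihood of continuous slider responses under the beta model.

    Responses and predicted means are clipped to ``[eps, 1 - eps]`` before
    evaluation; NaN responses are missed trials and contribute nothing.
    """
    if phi <= 0:
        raise ValueError(f"phi={phi} must be positive")
    y = np.asarray(y, dtype=float)
    v = traj.v_pred
    if y.shape[0] != v.shape[0]:
        raise ValueError("response and trajectory lengths differ")
    mask = ~np.isnan(y)
    if not mask.any():
        raise ValueError("all responses missing: likelihood undefined")
    yc = np.clip(y[mask], eps, 1.0 - eps)
    mu = np.clip(v[mask], eps, 1.0 - eps)
    return float(np.sum(_beta_logpdf(yc, mu, phi)))


# ---------------------------------------------------------------------------
# Vectorised trajectory kernels with analytic sensitivities.
#
# These power the MAP fits and large simulation studies: alpha may be a
# vector of S subjects sharing one outcome sequence, and the derivative of
# v[t] with respect to each learning rate is propagated alongside the state.
# ---------------------------------------------------------------------------


def rw_traj_grad(o: np.ndarray, alpha: np.ndarray):
    """Trajectories and d(v)/d(alpha) for S subjects on a shared schedule.

    Returns ``(V, DV)`` of shape (S, T): per-trial predictions (pre-outcome)
    and their sensitivities to each subject's learning rate.
    """
    o = np.asarray(o, dtype=float)
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    T, S = o.shape[0], alpha.shape[0]
    V = np.empty((S, T))
    DV = np.empty((S, T))
    v = np.full(S, 0.5)
    dv = np.zeros(S)
    one_minus = 1.0 - alpha
    for t in range(T):
        V[:, t] = v
        DV[:, t] = dv
        delta = o[t] - v
        dv = one_minus * dv + delta
        v = v + alpha * delta
    return V, DV


def rw_dual_traj_grad(
    o: np.ndarray, s: np.ndarray, alpha_p: np.ndarray, alpha_n: np.ndarray
):
    """Dual-rate analogue of :func:`rw_traj_grad`.

    Returns ``(V, DVp, DVn)`` with sensitivities to both learning rates.
    """
    o = np.asarray(o, dtype=float)
    s = np.asarray(s)
    alpha_p = np.atleast_1d(np.asarray(alpha_p, dtype=float))
    alpha_n = np.atleast_1d(np.asarray(alpha_n, dtype=float))
    T, S = o.shape[0], alpha_p.shape[0]
    V = np.empty((S, T))
    DVp = np.empty((S, T))
    DVn = np.empty((S, T))
    v = np.full(S, 0.5)
    dvp = np.zeros(S)
    dvn = np.zeros(S)
    for t in range(T):
        V[:, t] = v
        DVp[:, t] = dvp
        DVn[:, t] = dvn
        delta = o[t] - v
        if s[t] == 1:
            rate = alpha_n
            dvp = (1.0 - rate) * dvp
            dvn = (1.0 - rate) * dvn + delta
        else:
            rate = alpha_p
            dvp = (1.0 - rate) * dvp + delta
            dvn = (1.0 - rate) * dvn
        v = v + rate * delta
    return V, DVp, DVn
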