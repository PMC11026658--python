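"""MAP parameter estimation, null models and model comparison.

Fitting is maximum a posteriori: the log-likelihood from
:mod:`blt.models` is penalised by Gaussian priors specified in native
parameter space (learning rates additionally box-bounded to [0, 1]) and
maximised with single-start L-BFGS-B from the prior means.  Default priors
come from maximum-likelihood fits to a separate pilot cohort of the binary
task: alpha ~ N(0.34, var 0.88) truncated to [0, 1] and beta ~ N(4.21,
var 1.75); the group dispersion phi carries an improper flat prior on
(0, 500] so its estimate is likelihood-driven.

Because subjects are conditionally independent given the shared schedule,
per-subject binary fits are run as one batched L-BFGS-B solve over the
block-separable objective (identical optima, analytic gradients, orders of
magnitude faster than a Python loop of scalar solves); the continuous model
is a genuinely joint fit of all subject learning rates plus the shared phi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, expit, gammaln, log_expit

from .models import BOUNDARY_EPS, rw_dual_traj_grad, rw_traj_grad
from .task import TrialSchedule

__all__ = [
    "PriorSpec",
    "FitResult",
    "DEFAULT_PRIORS",
    "fit_binary",
    "fit_continuous",
    "fit_dual",
    "fit_null",
    "pool_fits",
    "information_criteria",
    "bayes_factor",
]

_OPT_OPTIONS = {"maxiter": 10000, "maxfun": 20000, "ftol": 1e-10,
                "gtol": 1e-6}
_PHI_MAX = 500.0
_PHI_START = 10.0


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior in native space with optional hard bounds.

    ``mean is None`` denotes an improper flat prior over ``(lower, upper)``.
    The truncation constant of a bounded Gaussian is independent of the
    parameter, so it is irrelevant to MAP and omitted.
    """

    mean: float | None
    variance: float | None
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.variance is not None and self.variance <= 0:
            raise ValueError("prior variance must be positive")
        if not self.lower < self.upper:
            raise ValueError("prior bounds must satisfy lower < upper")

    @property
    def flat(self) -> bool:
        return self.mean is None

    def logpdf(self, x):
        if self.flat:
            return np.zeros_like(np.asarray(x, dtype=float))
        return -((np.asarray(x, dtype=float) - self.mean) ** 2) / (
            2.0 * self.variance
        )

    def dlogpdf(self, x):
        if self.flat:
            return np.zeros_like(np.asarray(x, dtype=float))
        return -(np.asarray(x, dtype=float) - self.mean) / self.variance


DEFAULT_PRIORS: dict[str, PriorSpec] = {
    "alpha": PriorSpec(0.34, 0.88, 0.0, 1.0),
    "alpha_p": PriorSpec(0.34, 0.88, 0.0, 1.0),
    "alpha_n": PriorSpec(0.34, 0.88, 0.0, 1.0),
    "beta": PriorSpec(4.21, 1.75, 1e-6, np.inf),
    "phi": PriorSpec(None, None, 1e-6, _PHI_MAX),
}


@dataclass
class FitResult:
    """Outcome of one MAP fit (per subject or group-level).

    ``loglik`` is the maximised log-likelihood (priors excluded),
    ``log_posterior`` the objective actually maximised; ``kappa`` counts the
    free parameters and ``n_obs`` the non-missing modelled responses, from
    which ``bic``/``aic`` follow.
    """

    model_id: str
    estimates: dict
    loglik: float
    log_posterior: float
    kappa: int
    n_obs: int
    bic: float = field(init=False)
    aic: float = field(init=False)
    converged: bool = True
    message: str = ""
    subject_loglik: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bic, self.aic = information_criteria(
            self.loglik, self.kappa, self.n_obs
        )


def information_criteria(loglik: float, kappa: int, n_obs: int):
    """``(BIC, AIC)`` with BIC = -2 lnL + kappa ln(n), AIC = -2 lnL + 2 kappa.

    Smaller is better under this sign convention.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    bic = -2.0 * loglik + math.log(n_obs) * kappa
    aic = -2.0 * loglik + 2.0 * kappa
    return bic, aic


def bayes_factor(score_worse: float, score_better: float) -> float:
    """Approximate Bayes factor from two information-criterion scores.

    ``exp((score_worse - score_better) / 2)``; values above 1 favour the
    better-scoring (smaller-criterion) model.  Differences beyond float
    range return ``inf`` (decisive either way).
    """
    try:
        return math.exp((score_worse - score_better) / 2.0)
    except OverflowError:
        return math.inf


def pool_fits(fits: list[FitResult], model_id: str | None = None) -> FitResult:
    """Combine per-subject fits into one group-level score.

    Log-likelihoods, parameter counts and observation counts are summed so a
    single pooled BIC/AIC per model can be compared across models fit to the
    same data.
    """
    if not fits:
        raise ValueError("no fits to pool")
    return FitResult(
        model_id=model_id or fits[0].model_id,
        estimates={"per_subject": [f.estimates for f in fits]},
        loglik=sum(f.loglik for f in fits),
        log_posterior=sum(f.log_posterior for f in fits),
        kappa=sum(f.kappa for f in fits),
        n_obs=sum(f.n_obs for f in fits),
        converged=all(f.converged for f in fits),
    )


def _as_matrix(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("responses must be a (subjects x trials) array")
    return arr


def _check_responses(Y: np.ndarray, schedule: TrialSchedule) -> np.ndarray:
    if Y.shape[1] != schedule.n_trials:
        raise ValueError(
            f"{Y.shape[1]} response columns vs {schedule.n_trials} trials"
        )
    mask = ~np.isnan(Y)
    if not mask.any(axis=1).all():
        bad = np.where(~mask.any(axis=1))[0]
        raise ValueError(f"subjects {bad.tolist()} have no usable responses")
    return mask


# ---------------------------------------------------------------------------
# Binary (softmax) model
# ---------------------------------------------------------------------------


def fit_binary(
    yb,
    schedule: TrialSchedule,
    priors: dict[str, PriorSpec] | None = None,
    dual: bool = False,
) -> list[FitResult]:
    """MAP fit of the softmax observation model, one result per subject.

    ``yb`` is a (subjects x trials) array (or a single trial vector) of 0/1
    contingency-space responses with NaN for missed trials.  Each subject has
    a learning rate (two for ``dual=True``) and an inverse temperature beta.
    """
    priors = priors or DEFAULT_PRIORS
    YB = _as_matrix(yb)
    mask = _check_responses(YB, schedule)
    S = YB.shape[0]
    o = schedule.o.astype(float)
    Yz = np.where(mask, YB, 0.0)  # masked entries never contribute

    pa, pb = priors["alpha"], priors["beta"]
    if dual:
        pap, pan = priors["alpha_p"], priors["alpha_n"]

    def negobj(x):
        if dual:
            ap, an, beta = x[:S], x[S : 2 * S], x[2 * S :]
            V, DVp, DVn = rw_dual_traj_grad(o, schedule.s, ap, an)
        else:
            alpha, beta = x[:S], x[S:]
            V, DV = rw_traj_grad(o, alpha)
        w = beta[:, None] * (2.0 * V - 1.0)
        p = expit(w)
        ll_elem = Yz * log_expit(w) + (1.0 - Yz) * log_expit(-w)
        ll = np.sum(ll_elem * mask)
        resid = (Yz - p) * mask
        g_beta = np.sum(resid * (2.0 * V - 1.0), axis=1)
        gv = resid * (2.0 * beta[:, None])
        if dual:
            prior_terms = (
                np.sum(pap.logpdf(ap))
                + np.sum(pan.logpdf(an))
                + np.sum(pb.logpdf(beta))
            )
            g = np.concatenate(
                [
                    np.sum(gv * DVp, axis=1) + pap.dlogpdf(ap),
                    np.sum(gv * DVn, axis=1) + pan.dlogpdf(an),
                    g_beta + pb.dlogpdf(beta),
                ]
            )
        else:
            prior_terms = np.sum(pa.logpdf(alpha)) + np.sum(pb.logpdf(beta))
            g = np.concatenate(
                [
                    np.sum(gv * DV, axis=1) + pa.dlogpdf(alpha),
                    g_beta + pb.dlogpdf(beta),
                ]
            )
        return -(ll + prior_terms), -g

    if dual:
        x0 = np.concatenate(
            [np.full(S, pap.mean), np.full(S, pan.mean), np.full(S, pb.mean)]
        )
        bounds = (
            [(pap.lower, pap.upper)] * S
            + [(pan.lower, pan.upper)] * S
            + [(pb.lower, None)] * S
        )
    else:
        x0 = np.concatenate([np.full(S, pa.mean), np.full(S, pb.mean)])
        bounds = [(pa.lower, pa.upper)] * S + [(pb.lower, None)] * S

    res = minimize(
        negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options=_OPT_OPTIONS,
    )

    x = res.x
    if dual:
        ap, an, beta = x[:S], x[S : 2 * S], x[2 * S :]
        V, _, _ = rw_dual_traj_grad(o, schedule.s, ap, an)
    else:
        alpha, beta = x[:S], x[S:]
        V, _ = rw_traj_grad(o, alpha)
    w = beta[:, None] * (2.0 * V - 1.0)
    ll_sub = np.sum(
        mask * (Yz * log_expit(w) + (1.0 - Yz) * log_expit(-w)), axis=1
    )

    fits = []
    for i in range(S):
        if dual:
            est = {"alpha_p": ap[i], "alpha_n": an[i], "beta": beta[i]}
            lp = (
                ll_sub[i]
                + float(pap.logpdf(ap[i]))
                + float(pan.logpdf(an[i]))
                + float(pb.logpdf(beta[i]))
            )
            kappa = 3
        else:
            est = {"alpha": alpha[i], "beta": beta[i]}
            lp = (
                ll_sub[i]
                + float(pa.logpdf(alpha[i]))
                + float(pb.logpdf(beta[i]))
            )
            kappa = 2
        fits.append(
            FitResult(
                model_id="binary_dual" if dual else "binary",
                estimates=est,
                loglik=float(ll_sub[i]),
                log_posterior=lp,
                kappa=kappa,
                n_obs=int(mask[i].sum()),
                converged=bool(res.success),
                message=str(res.message),
            )
        )
    return fits


# ---------------------------------------------------------------------------
# Continuous (beta mean-dispersion) model
# ---------------------------------------------------------------------------


def fit_continuous(
    y,
    schedule: TrialSchedule,
    priors: dict[str, PriorSpec] | None = None,
    dual: bool = False,
    eps: float = BOUNDARY_EPS,
    phi_start: float = _PHI_START,
) -> FitResult:
    """Joint MAP fit of the continuous model across all subjects.

    Estimates one learning rate per subject (two under ``dual=True``) plus a
    single group-level dispersion phi shared by every subject and trial, by
    maximising the summed beta log-likelihood plus log-priors.
    """
    priors = priors or DEFAULT_PRIORS
    Y = _as_matrix(y)
    mask = _check_responses(Y, schedule)
    S = Y.shape[0]
    o = schedule.o.astype(float)
    Yc = np.clip(np.where(mask, Y, 0.5), eps, 1.0 - eps)
    logY = np.log(Yc)
    log1mY = np.log1p(-Yc)
    n_total = int(mask.sum())

    pa = priors["alpha"]
    pphi = priors["phi"]
    if dual:
        pap, pan = priors["alpha_p"], priors["alpha_n"]

    def _ll_terms(V, phi):
        mu = np.clip(V, eps, 1.0 - eps)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll_elem = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * logY
            + (b - 1.0) * log1mY
        )
        dmu = phi * (-digamma(a) + digamma(b) + logY - log1mY)
        dmu *= (V > eps) & (V < 1.0 - eps)  # clipped means have zero slope
        dphi = (
            digamma(phi)
            - mu * digamma(a)
            - (1.0 - mu) * digamma(b)
            + mu * logY
            + (1.0 - mu) * log1mY
        )
        return ll_elem, dmu, dphi

    def negobj(x):
        phi = x[-1]
        if dual:
            ap, an = x[:S], x[S : 2 * S]
            V, DVp, DVn = rw_dual_traj_grad(o, schedule.s, ap, an)
        else:
            alpha = x[:S]
            V, DV = rw_traj_grad(o, alpha)
        ll_elem, dmu, dphi = _ll_terms(V, phi)
        ll = np.sum(ll_elem * mask)
        dmu_m = dmu * mask
        g_phi = np.sum(dphi * mask) + float(pphi.dlogpdf(phi))
        if dual:
            prior_terms = (
                np.sum(pap.logpdf(ap))
                + np.sum(pan.logpdf(an))
                + float(pphi.logpdf(phi))
            )
            g = np.concatenate(
                [
                    np.sum(dmu_m * DVp, axis=1) + pap.dlogpdf(ap),
                    np.sum(dmu_m * DVn, axis=1) + pan.dlogpdf(an),
                    [g_phi],
                ]
            )
        else:
            prior_terms = np.sum(pa.logpdf(alpha)) + float(pphi.logpdf(phi))
            g = np.concatenate(
                [np.sum(dmu_m * DV, axis=1) + pa.dlogpdf(alpha), [g_phi]]
            )
        return -(ll + prior_terms), -g

    if dual:
        x0 = np.concatenate(
            [np.full(S, pap.mean), np.full(S, pan.mean), [phi_start]]
        )
        bounds = (
            [(pap.lower, pap.upper)] * S
            + [(pan.lower, pan.upper)] * S
            + [(pphi.lower, pphi.upper)]
        )
        kappa = 2 * S + 1
    else:
        x0 = np.concatenate([np.full(S, pa.mean), [phi_start]])
        bounds = [(pa.lower, pa.upper)] * S + [(pphi.lower, pphi.upper)]
        kappa = S + 1

    res = minimize(
        negobj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options=_OPT_OPTIONS,
    )

    phi = float(res.x[-1])
    if dual:
        ap, an = res.x[:S], res.x[S : 2 * S]
        V, _, _ = rw_dual_traj_grad(o, schedule.s, ap, an)
        estimates = {"alpha_p": ap.copy(), "alpha_n": an.copy(), "phi": phi}
    else:
        alpha = res.x[:S]
        V, _ = rw_traj_grad(o, alpha)
        estimates = {"alpha": alpha.copy(), "phi": phi}
    ll_elem, _, _ = _ll_terms(V, phi)
    ll_sub = np.sum(ll_elem * mask, axis=1)

    return FitResult(
        model_id="continuous_dual" if dual else "continuous",
        estimates=estimates,
        loglik=float(ll_sub.sum()),
        log_posterior=float(-res.fun),
        kappa=kappa,
        n_obs=n_total,
        converged=bool(res.success),
        message=str(res.message),
        subject_loglik=ll_sub,
    )


def fit_dual(
    data,
    schedule: TrialSchedule,
    model: str = "continuous",
    priors: dict[str, PriorSpec] | None = None,
):
    """Dual-learning-rate fit; dispatches to the binary or continuous fit."""
    if model == "binary":
        return fit_binary(data, schedule, priors=priors, dual=True)
    if model == "continuous":
        return fit_continuous(data, schedule, priors=priors, dual=True)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Null (no-learning) models
# ---------------------------------------------------------------------------


def fit_null(
    data,
    schedule: TrialSchedule,
    model: str,
    priors: dict[str, PriorSpec] | None = None,
    eps: float = BOUNDARY_EPS,
) -> FitResult:
    """Fit the no-learning reference model (alpha clamped at 0, v = 0.5).

    For the binary model the softmax at v = 0.5 yields p = 0.5 whatever beta,
    so the log-likelihood is exactly ``n_obs * ln(0.5)`` and beta's posterior
    is its prior (estimate = prior mean, one formally free parameter per
    subject).  For the continuous model the dispersion phi is still fit by
    1-D bounded optimisation.  Returns a pooled group-level result.
    """
    priors = priors or DEFAULT_PRIORS
    Y = _as_matrix(data)
    mask = _check_responses(Y, schedule)
    S = Y.shape[0]
    n_total = int(mask.sum())

    if model == "binary":
        ll_sub = mask.sum(axis=1) * math.log(0.5)
        return FitResult(
            model_id="binary_null",
            estimates={"alpha": 0.0, "beta": priors["beta"].mean},
            loglik=float(ll_sub.sum()),
            log_posterior=float(ll_sub.sum()),
            kappa=S,
            n_obs=n_total,
            subject_loglik=ll_sub.astype(float),
        )
    if model != "continuous":
        raise ValueError(f"unknown model {model!r}")

    Yc = np.clip(np.where(mask, Y, 0.5), eps, 1.0 - eps)
    # at mu = 0.5 the beta log-density reduces to a 1-D function of phi
    t_sum = float(np.sum((np.log(Yc) + np.log1p(-Yc)) * mask))

    def neg1d(phi):
        return -(
            n_total * (gammaln(phi) - 2.0 * gammaln(phi / 2.0))
            + (phi / 2.0 - 1.0) * t_sum
        )

    pphi = priors["phi"]
    res = minimize_scalar(
        neg1d, bounds=(pphi.lower, pphi.upper), method="bounded",
        options={"xatol": 1e-8},
    )
    phi = float(res.x)
    ll_sub = (
        mask.sum(axis=1) * (gammaln(phi) - 2.0 * gammaln(phi / 2.0))
        + (phi / 2.0 - 1.0)
        * np.sum((np.log(Yc) + np.log1p(-Yc)) * mask, axis=1)
    )
    return FitResult(
        model_id="continuous_null",
        estimates={"alpha": 0.0, "phi": phi},
        loglik=float(-res.fun),
        log_posterior=float(-res.fun),
        kappa=1,
        n_obs=n_total,
        converged=bool(res.success),
        subject_loglik=ll_sub.astype(float),
    )
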