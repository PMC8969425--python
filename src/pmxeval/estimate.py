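"""Individual-level inference with the population parameters held fixed.

Provides population predictions (PRED), empirical-Bayes (MAP) estimates of
each subject's random effects, posterior probabilities of mixture
subpopulation membership, and first-order-conditional weighted residuals
(CWRES).  Nothing here re-estimates any population parameter: the models
under evaluation stay exactly as configured.

Subpopulation posteriors use a Laplace approximation to the marginal
likelihood of each class: the joint density at the MAP eta times the
Gaussian volume factor from the curvature of the negative log joint.  For
subjects with no quantifiable observations the posterior falls back to the
mixing proportions and the MAP eta to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import logsumexp

from .models import PopulationModel, StudyDataset, Subject, individual_parameters
from .profiles import solve_profile

__all__ = [
    "IndividualFit",
    "population_prediction",
    "pred_for_dataset",
    "mixture_posterior",
    "ebe_estimate",
    "fit_dataset",
    "compute_cwres",
]

log = logging.getLogger(__name__)


@dataclass
class IndividualFit:
    """Empirical-Bayes results for one subject."""

    sid: str
    eta: np.ndarray
    subpop_posterior: np.ndarray
    map_subpop: int
    ipred: np.ndarray
    pred: np.ndarray
    converged: bool = True
    objective: float = np.nan
    objective_trace: list = field(default_factory=list)


def _profile_at(model, subject, eta, subpop, times, analytes):
    """Noise-free prediction per observation record (natural scale)."""
    params = individual_parameters(model, subject, eta, subpop)
    utimes, inv = np.unique(np.asarray(times, dtype=float), return_inverse=True)
    prof = solve_profile(
        params, model.structure, subject.dose_times, subject.dose_amounts, utimes
    )
    out = np.empty(len(times))
    for j, name in enumerate(analytes):
        out[j] = prof[model.analyte_by_name(name).role][inv[j]]
    return out


def population_prediction(
    model: PopulationModel,
    subject: Subject,
    times=None,
    analytes=None,
    mixture_handling: str = "weighted",
):
    """PRED per observation record: the eta = 0 population profile.

    For mixture models the default is the mixing-proportion-weighted
    average of the per-subpopulation eta = 0 profiles
    (``mixture_handling="weighted"``); ``"mode"`` uses the most probable
    subpopulation instead.  PRED depends only on the design, never on the
    subject's observed values.
    """
    if times is None:
        times = subject.obs_times
    if analytes is None:
        analytes = subject.obs_analytes
    times = np.asarray(times, dtype=float)
    zero = np.zeros(model.random_effects.n_eta)
    if model.mixture is None:
        return _profile_at(model, subject, zero, None, times, analytes)
    props = model.mixing_proportions
    if mixture_handling == "mode":
        lab = model.mixture.labels[int(np.argmax(props))]
        return _profile_at(model, subject, zero, lab, times, analytes)
    if mixture_handling != "weighted":
        raise ValueError(f"unknown mixture_handling {mixture_handling!r}")
    out = np.zeros(len(times))
    for p, lab in zip(props, model.mixture.labels):
        out += p * _profile_at(model, subject, zero, lab, times, analytes)
    return out


def pred_for_dataset(
    model: PopulationModel, dataset: StudyDataset, mixture_handling: str = "weighted"
) -> np.ndarray:
    """PRED aligned to ``dataset.observation_records()`` order."""
    chunks = [
        population_prediction(model, s, mixture_handling=mixture_handling)
        for s in dataset.subjects
    ]
    return np.concatenate(chunks) if chunks else np.array([])


def mixture_posterior(priors, loglik) -> np.ndarray:
    """Bayes rule over subpopulations from per-class log-likelihoods.

    Stable under large negative log-likelihoods (log-sum-exp) and invariant
    to adding any constant to all of them.
    """
    priors = np.asarray(priors, dtype=float)
    loglik = np.asarray(loglik, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-8:
        raise ValueError("priors must sum to 1")
    if np.all(np.isneginf(loglik)):
        raise ValueError("all class log-likelihoods are -inf: no data support")
    with np.errstate(divide="ignore"):
        logpost = np.log(priors) + loglik
    return np.exp(logpost - logsumexp(logpost))


def _quantifiable_records(model, subject):
    """Indices/targets of quantifiable observations on each analyte's scale."""
    keep = subject.quantifiable()
    times = subject.obs_times[keep]
    analytes = subject.obs_analytes[keep]
    y = subject.obs_values[keep]
    scales = np.array([model.error[a].scale for a in analytes], dtype=object)
    return keep, times, analytes, y, scales


def _residual_loglik(model, analytes, scales, y, f):
    """Gaussian observation log-likelihood on each record's own scale."""
    ll = 0.0
    for j, name in enumerate(analytes):
        spec = model.error[name]
        if scales[j] == "log":
            if f[j] <= 0 or y[j] <= 0:
                return -np.inf
            resid = np.log(y[j]) - np.log(f[j])
            sd = spec.additive
        else:
            resid = y[j] - f[j]
            sd = float(spec.sd(f[j]))
        if sd <= 0:
            return -np.inf if resid != 0 else 0.0
        ll += -0.5 * (resid / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
    return ll


def _ridge_inverse(omega, ridge=1e-10):
    n = omega.shape[0]
    scale = max(np.trace(omega) / max(n, 1), 1.0)
    return np.linalg.inv(omega + ridge * scale * np.eye(n))


def ebe_estimate(
    model: PopulationModel,
    subject: Subject,
    n_starts: int = 3,
    jitter: float = 0.5,
    seed: int = 0,
) -> IndividualFit:
    """MAP random effects and subpopulation posterior for one subject.

    Per candidate subpopulation the penalized log-likelihood
    ``log p(y | eta, class) + log p(eta)`` is maximized by quasi-Newton
    from eta = 0 plus jittered restarts; the class posterior combines the
    mixing proportions with a Laplace-approximate marginal likelihood.
    """
    n_eta = model.random_effects.n_eta
    keep, times, analytes, y, scales = _quantifiable_records(model, subject)
    pred = population_prediction(model, subject)
    labels = model.subpopulation_labels
    priors = model.mixing_proportions

    if len(y) == 0:
        zero = np.zeros(n_eta)
        ipred = _profile_at(
            model,
            subject,
            zero,
            labels[int(np.argmax(priors))] if model.mixture else None,
            subject.obs_times,
            subject.obs_analytes,
        )
        return IndividualFit(
            sid=subject.sid,
            eta=zero,
            subpop_posterior=priors.copy(),
            map_subpop=int(np.argmax(priors)),
            ipred=ipred,
            pred=pred,
        )

    omega_inv = _ridge_inverse(model.random_effects.omega) if n_eta else np.zeros((0, 0))
    rng = np.random.default_rng(seed)

    best_eta, best_obj, log_marg, traces = [], [], [], []
    converged = True
    for lab in labels:
        sub = lab if model.mixture is not None else None
        trace: list[float] = []

        def nll(eta):
            f = _profile_at(model, subject, eta, sub, times, analytes)
            val = -(
                _residual_loglik(model, analytes, scales, y, f)
                - 0.5 * eta @ omega_inv @ eta
            )
            return val if np.isfinite(val) else 1e10

        if n_eta == 0:
            eta_hat, obj = np.zeros(0), nll(np.zeros(0))
        else:
            eta_hat, obj = None, np.inf
            ok = False
            for start in range(n_starts):
                x0 = np.zeros(n_eta)
                if start > 0:
                    x0 = jitter * rng.standard_normal(n_eta)
                res = minimize(
                    nll, x0, method="L-BFGS-B", bounds=[(-20.0, 20.0)] * n_eta
                )
                trace.append(float(res.fun))
                if res.fun < obj:
                    eta_hat, obj = res.x, float(res.fun)
                    ok = ok or res.success
            if not ok:
                converged = False
                log.warning("EBE optimizer did not converge for subject %s", subject.sid)
        best_eta.append(eta_hat)
        best_obj.append(obj)
        traces.append(sorted(trace, reverse=True))
        # Laplace marginal: the (2*pi)^(n/2) volume factors of the prior
        # normalization and the curvature Gaussian cancel, leaving
        # -obj - 0.5 log det(omega) - 0.5 log det(H)
        if n_eta:
            H = _numeric_hessian(nll, eta_hat)
            sign, logdet = np.linalg.slogdet(H)
            if sign <= 0:
                logdet = np.sum(np.log(np.clip(np.diag(H), 1e-12, None)))
            norm = -0.5 * np.linalg.slogdet(
                model.random_effects.omega + 1e-12 * np.eye(n_eta)
            )[1]
            log_marg.append(-obj + norm - 0.5 * logdet)
        else:
            log_marg.append(-obj)

    post = mixture_posterior(priors, np.asarray(log_marg))
    k = int(np.argmax(post))
    eta_map = best_eta[k]
    ipred = _profile_at(
        model,
        subject,
        eta_map,
        labels[k] if model.mixture is not None else None,
        subject.obs_times,
        subject.obs_analytes,
    )
    return IndividualFit(
        sid=subject.sid,
        eta=np.asarray(eta_map),
        subpop_posterior=post,
        map_subpop=k,
        ipred=ipred,
        pred=pred,
        converged=converged,
        objective=best_obj[k],
        objective_trace=traces[k],
    )


def _numeric_hessian(fun, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_dataset(model: PopulationModel, dataset: StudyDataset, seed: int = 0):
    """EBE fits for every subject (list aligned to dataset.subjects)."""
    return [
        ebe_estimate(model, s, seed=seed + i) for i, s in enumerate(dataset.subjects)
    ]


def compute_cwres(
    model: PopulationModel,
    dataset: StudyDataset,
    fits: list[IndividualFit],
    rel_step: float = 1e-4,
) -> np.ndarray:
    """First-order-conditional weighted residuals per quantifiable record.

    Per subject the individual prediction is linearized around the MAP eta
    with finite differences (gradient G); the marginal covariance
    ``G omega G' + diag(residual variance)`` whitens
    ``y - f(eta_hat) + G eta_hat``.  Aligned to
    ``dataset.observation_records()``; NaN for BQL records.  Approximately
    standard normal when the model generated the data.
    """
    if len(fits) != dataset.n_subjects:
        raise ValueError("need one fit per subject")
    omega = model.random_effects.omega
    n_eta = model.random_effects.n_eta
    out = []
    for subject, fit in zip(dataset.subjects, fits):
        res = np.full(subject.n_obs, np.nan)
        keep, times, analytes, y, scales = _quantifiable_records(model, subject)
        if len(y) == 0:
            out.append(res)
            continue
        lab = (
            model.mixture.labels[fit.map_subpop] if model.mixture is not None else None
        )

        def fvec(eta):
            f = _profile_at(model, subject, eta, lab, times, analytes)
            logmask = scales == "log"
            f = f.copy()
            f[logmask] = np.log(np.clip(f[logmask], 1e-300, None))
            return f

        eta = np.asarray(fit.eta, dtype=float)
        f0 = fvec(eta)
        G = np.zeros((len(y), n_eta))
        for j in range(n_eta):
            h = rel_step * max(abs(eta[j]), 1.0)
            ep = eta.copy()
            em = eta.copy()
            ep[j] += h
            em[j] -= h
            G[:, j] = (fvec(ep) - fvec(em)) / (2 * h)

        fnat = _profile_at(model, subject, eta, lab, times, analytes)
        resvar = np.empty(len(y))
        yy = y.astype(float).copy()
        for j, name in enumerate(analytes):
            spec = model.error[name]
            if scales[j] == "log":
                resvar[j] = spec.additive**2
                yy[j] = np.log(yy[j])
            else:
                resvar[j] = float(spec.sd(fnat[j])) ** 2
        cov = G @ omega @ G.T + np.diag(resvar)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            log.warning(
                "singular conditional covariance for subject %s; ridge added",
                subject.sid,
            )
            ridge = 1e-8 * max(np.trace(cov) / len(y), 1e-12)
            L = np.linalg.cholesky(cov + ridge * np.eye(len(y)))
        cw = solve_triangular(L, yy - f0 + G @ eta, lower=True)
        res[keep] = cw
        out.append(res)
    return np.concatenate(out)
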