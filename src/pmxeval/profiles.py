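"""Noise-free concentration-time profiles for linear compartmental models.

All structural models handled here (first-order absorption with optional
lag into a 1- or 2-compartment parent, first-order conversion to a
1-compartment metabolite, first-order elimination throughout) are linear
time-invariant systems.  For a unit bolus into the absorption depot at time
0 the Laplace transform of every compartment amount is a strictly proper
rational function with simple real poles, so each amount is a sum of
exponentials whose coefficients are the residues

    r_i = N(-lam_i) / prod_{j != i} (lam_j - lam_i)

of ``N(s) / prod_i (s + lam_i)``.  Multiple doses superpose, and an
absorption lag simply shifts each dose's entry time.  This closed form is
the default engine: it is exact, vectorizes over whole parameter ensembles,
and costs microseconds per profile.  A general-purpose stiff ODE integrator
(`solve_profile_ode`) is kept behind the same contract as an independent
cross-check.

Rates for the systems solved here:

* ``k10 = CL/V`` parent elimination (total), of which a fraction ``fm``
  forms the metabolite,
* ``k12 = Q/V``, ``k21 = Q/Vp`` distribution to/from the peripheral
  compartment (2-compartment parent only),
* ``km = CLm/Vm`` metabolite elimination.

Near-degenerate rate constants (within 1e-7 relative) are nudged apart so
the simple-pole residue formula stays well conditioned; the error this
introduces is of order ``rate * t * 1e-7`` and only arises for exactly
coincident rates, where the closed form would otherwise need a confluent
(t * exp) term.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .models import ParameterSet, StructuralSpec

__all__ = ["solve_profile", "solve_profile_many", "solve_amounts", "solve_profile_ode"]

_REL_SEP = 1e-7
_ZERO_FLOOR = 1e-12


def _params_to_arrays(params) -> dict[str, np.ndarray]:
    if isinstance(params, ParameterSet):
        params = params.as_dict()
    out = {}
    K = 1
    for k, v in params.items():
        if v is None:
            continue
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        K = max(K, len(arr))
        out[k] = arr
    return {k: np.broadcast_to(v, (K,)).astype(float) for k, v in out.items()}


def _separate_poles(poles: list[np.ndarray]) -> list[np.ndarray]:
    """Floor zero rates and push near-coincident rates apart (in place safe)."""
    m = len(poles)
    lams = [p.copy() for p in poles]
    for i in range(m):
        lams[i] = np.where(lams[i] <= 0, _ZERO_FLOOR * (i + 1), lams[i])
    for _ in range(3):
        for i in range(1, m):
            for j in range(i):
                tol = _REL_SEP * np.maximum(lams[i], lams[j])
                close = np.abs(lams[i] - lams[j]) < tol
                if np.any(close):
                    lams[i] = np.where(close, lams[i] * (1 + 4 * _REL_SEP * (i + 1)), lams[i])
    return lams


def _residues(lams: list[np.ndarray], numerator) -> list[np.ndarray]:
    m = len(lams)
    res = []
    for i in range(m):
        den = np.ones_like(lams[i])
        for j in range(m):
            if j != i:
                den = den * (lams[j] - lams[i])
        res.append(numerator(-lams[i]) / den)
    return res


def _system(params: dict[str, np.ndarray], structure: StructuralSpec):
    """Poles and residues of every compartment amount per unit depot bolus.

    Returns ``(lams, coefs)`` where ``lams`` is a list of (K,) pole arrays
    and ``coefs`` maps compartment name -> list of (K,) residue arrays.
    """
    ka = params["ka"]
    k10 = params["cl"] / params["v"]
    coefs: dict[str, list[np.ndarray]] = {}

    if structure.parent_compartments == 1:
        lams = _separate_poles([ka, k10])
        la, l1 = lams
        coefs["depot"] = _residues([la], lambda s: np.ones_like(s))
        coefs["depot"] = [coefs["depot"][0], np.zeros_like(la)]
        coefs["central"] = _residues(lams, lambda s: la)
        if structure.has_metabolite:
            km = params["clm"] / params["vm"]
            lams_m = _separate_poles([la, l1, km])
            fmk10 = params["fm"] * k10
            coefs["metab"] = _residues(lams_m, lambda s: fmk10 * lams_m[0])
            lams = lams_m
            coefs["depot"] = [coefs["depot"][0], np.zeros_like(la), np.zeros_like(la)]
            coefs["central"] = _residues(lams[:2], lambda s: lams[0]) + [np.zeros_like(la)]
    else:
        k12 = params["q"] / params["v"]
        k21 = params["q"] / params["vp"]
        a1 = k10 + k12 + k21
        disc = np.sqrt(np.maximum(a1 * a1 - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (a1 + disc)
        beta = 0.5 * (a1 - disc)
        lams = _separate_poles([ka, alpha, beta])
        la = lams[0]
        k21a = lams[1] + lams[2] - k10 - k12  # keep k21 consistent with nudged poles
        coefs["depot"] = [np.ones_like(la), np.zeros_like(la), np.zeros_like(la)]
        coefs["central"] = _residues(lams, lambda s: la * (s + k21a))
        coefs["peripheral"] = _residues(lams, lambda s: la * k12)
        if structure.has_metabolite:
            km = params["clm"] / params["vm"]
            lams_m = _separate_poles(lams + [km])
            fmk10 = params["fm"] * k10
            coefs["metab"] = _residues(
                lams_m, lambda s: lams_m[0] * (s + k21a) * fmk10
            )
            pad = np.zeros_like(la)
            lams = lams_m
            coefs["depot"].append(pad)
            coefs["central"] = _residues(lams[:3], lambda s: lams[0] * (s + k21a)) + [pad]
            coefs["peripheral"] = _residues(lams[:3], lambda s: lams[0] * k12) + [pad]

    return lams, coefs


def _dose_superposition(
    lams: list[np.ndarray],
    coefs: list[np.ndarray],
    dose_times: np.ndarray,
    dose_amounts: np.ndarray,
    f: np.ndarray,
    alag: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Sum of exponential responses over doses; returns (K, n_times)."""
    K = len(lams[0])
    n = len(times)
    out = np.zeros((K, n))
    if len(dose_times) == 0:
        return out
    # delta[K, d, n]: time since each dose entered the system
    delta = times[None, None, :] - (dose_times[None, :, None] + alag[:, None, None])
    live = delta >= 0
    delta = np.where(live, delta, 0.0)
    for lam, coef in zip(lams, coefs):
        e = np.exp(-lam[:, None, None] * delta)
        e = np.where(live, e, 0.0)
        out += coef[:, None] * np.einsum("d,kdn->kn", dose_amounts, e)
    return f[:, None] * out


def solve_profile_many(
    params: dict[str, np.ndarray] | ParameterSet,
    structure: StructuralSpec,
    dose_times,
    dose_amounts,
    times,
) -> dict[str, np.ndarray]:
    """Noise-free concentrations for an ensemble of parameter vectors.

    Parameters given as arrays of shape (K,) (scalars broadcast).  Returns
    ``{"parent": (K, n), "metabolite": (K, n)}`` in nmol/mL (metabolite key
    only when the structure has one).
    """
    p = _params_to_arrays(params)
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(dose_times) < 0):
        raise ValueError("doses must be sorted by time")

    lams, coefs = _system(p, structure)
    f = p.get("f", np.ones_like(lams[0]))
    alag = p.get("alag", np.zeros_like(lams[0])) if structure.lag else np.zeros_like(lams[0])

    # concentrations in nmol/mL: amount (nmol) over volume (L -> mL)
    out = {
        "parent": _dose_superposition(
            lams, coefs["central"], dose_times, dose_amounts, f, alag, times
        )
        / (1e3 * p["v"][:, None])
    }
    if structure.has_metabolite:
        out["metabolite"] = _dose_superposition(
            lams, coefs["metab"], dose_times, dose_amounts, f, alag, times
        ) / (1e3 * p["vm"][:, None])
    return out


def solve_profile(
    params: ParameterSet,
    structure: StructuralSpec,
    dose_times,
    dose_amounts,
    times,
) -> dict[str, np.ndarray]:
    """Scalar-parameter convenience wrapper; returns (n,) arrays per analyte."""
    many = solve_profile_many(params, structure, dose_times, dose_amounts, times)
    return {k: v[0] for k, v in many.items()}


def solve_amounts(
    params: ParameterSet,
    structure: StructuralSpec,
    dose_times,
    dose_amounts,
    times,
) -> dict[str, np.ndarray]:
    """Compartment amounts (nmol) over time; used for conservation checks."""
    p = _params_to_arrays(params)
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    lams, coefs = _system(p, structure)
    f = p.get("f", np.ones_like(lams[0]))
    alag = p.get("alag", np.zeros_like(lams[0])) if structure.lag else np.zeros_like(lams[0])
    out = {}
    names = {"depot": "depot", "central": "central", "peripheral": "peripheral", "metab": "metabolite"}
    for key, coef in coefs.items():
        out[names[key]] = _dose_superposition(
            lams, coef, dose_times, dose_amounts, f, alag, times
        )[0]
    return out


def _ode_rhs(structure: StructuralSpec, p: ParameterSet):
    k10 = p.cl / p.v
    two = structure.parent_compartments == 2
    met = structure.has_metabolite
    k12 = (p.q / p.v) if two else 0.0
    k21 = (p.q / p.vp) if two else 0.0
    km = (p.clm / p.vm) if met else 0.0
    fm = p.fm if met else 0.0

    def rhs(t, y):
        # y = [depot, central, peripheral, metabolite]
        dy = np.empty(4)
        dy[0] = -p.ka * y[0]
        dy[1] = p.ka * y[0] - (k10 + k12) * y[1] + k21 * y[2]
        dy[2] = k12 * y[1] - k21 * y[2]
        dy[3] = fm * k10 * y[1] - km * y[3]
        return dy

    return rhs


def solve_profile_ode(
    params: ParameterSet,
    structure: StructuralSpec,
    dose_times,
    dose_amounts,
    times,
    rtol: float = 1e-11,
    atol: float = 1e-14,
) -> dict[str, np.ndarray]:
    """Reference profile via numerical ODE integration (cross-check oracle).

    Same contract as :func:`solve_profile` but integrates the full ODE
    system piecewise between dose events with tight tolerances.
    """
    dose_times = np.asarray(dose_times, dtype=float)
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    times = np.asarray(times, dtype=float)
    alag = params.alag if structure.lag else 0.0
    entry = dose_times + alag
    order = np.argsort(entry, kind="stable")
    entry, amts = entry[order], dose_amounts[order]

    rhs = _ode_rhs(structure, params)
    events = np.concatenate([entry, [np.inf]])
    y = np.zeros(4)
    t_now = 0.0
    sol_t, sol_y = [], []
    # walk through segments delimited by dose-entry times
    i = 0
    t_end = float(max(times.max(initial=0.0), entry.max(initial=0.0)))
    while t_now <= t_end:
        while i < len(entry) and abs(entry[i] - t_now) <= 1e-12:
            y[0] += params.f * amts[i]
            i += 1
        t_next = min(events[i] if i < len(entry) else np.inf, t_end)
        if t_next <= t_now:
            break
        mask = (times > t_now + 1e-12) & (times <= t_next + 1e-12)
        t_eval = np.sort(times[mask])
        sol = solve_ivp(
            rhs,
            (t_now, t_next),
            y,
            t_eval=t_eval if len(t_eval) else None,
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        if len(t_eval):
            sol_t.extend(sol.t)
            sol_y.extend(sol.y.T)
        # restart from segment end
        end = solve_ivp(rhs, (t_now, t_next), y, rtol=rtol, atol=atol, method="LSODA")
        y = end.y[:, -1].copy()
        t_now = t_next
        if i >= len(entry) and t_now >= t_end:
            break

    interp = {t: yy for t, yy in zip(sol_t, sol_y)}
    out_parent = np.zeros_like(times)
    out_met = np.zeros_like(times)
    for j, t in enumerate(times):
        if t in interp:
            out_parent[j] = interp[t][1] / (1e3 * params.v)
            if structure.has_metabolite:
                out_met[j] = interp[t][3] / (1e3 * params.vm)
        else:  # time at or before first entry (state known exactly)
            out_parent[j] = 0.0
            out_met[j] = 0.0
    out = {"parent": out_parent}
    if structure.has_metabolite:
        out["metabolite"] = out_met
    return out
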