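"""Synthetic opportunistic pediatric study cohorts.

Emulates the structure of a standard-of-care (opportunistic) pediatric
sampling study: a wide age range with weight tied to age through a growth
curve, irregular repeated oral dosing with weight-based amounts rounded to
practical increments, very sparse sampling at haphazard times relative to
doses, and censoring of concentrations below the assay's lower limit of
quantitation (LLOQ).  Defaults mirror a 62-subject cohort with ages
0.16-16.8 years, weights 3.64-129 kg, a median of 9 doses per subject
(range 1-43), a median of 1 sample per subject (range 1-7), doses of
0.003-0.068 mg/kg and an LLOQ of 0.100 ng/mL.

Observations are simulated from a user-supplied generating model, and the
true random effects, subpopulation classes and noise-free concentrations
are returned alongside so recovery tests can close the loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import PopulationModel, StudyDataset, Subject, individual_parameters
from .profiles import solve_profile
from .simulate import sample_individual
from .units import conc_to_molar, dose_to_molar

__all__ = ["CohortConfig", "generate_cohort", "bql_filter"]

# piecewise log-linear median weight-for-age (age y -> kg), pediatric range
_GROWTH_KNOTS_AGE = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 13.0, 17.0])
_GROWTH_KNOTS_WT = np.array([3.5, 6.0, 7.5, 9.5, 12.0, 16.0, 20.0, 32.0, 45.0, 62.0])


@dataclass
class CohortConfig:
    """Design of one synthetic opportunistic cohort."""

    n_subjects: int = 62
    age_range: tuple[float, float] = (0.16, 16.8)
    #: probability of falling in each age stratum (<2 y, 2-13 y, 13+ y)
    age_group_probs: tuple[float, float, float] = (0.37, 0.47, 0.16)
    weight_range: tuple[float, float] = (3.64, 129.0)
    weight_log_sd: float = 0.22
    dose_per_kg_median: float = 0.017
    dose_per_kg_log_sd: float = 0.6
    dose_per_kg_range: tuple[float, float] = (0.003, 0.068)
    dose_increment_mg: float = 0.05
    doses_per_subject_median: int = 9
    doses_per_subject_log_sd: float = 0.9
    doses_per_subject_range: tuple[int, int] = (1, 43)
    #: per-subject dosing interval drawn from these (h) with equal odds
    dosing_intervals: tuple[float, ...] = (12.0, 24.0)
    samples_per_subject_probs: tuple[float, ...] = (
        0.60,
        0.20,
        0.10,
        0.05,
        0.03,
        0.015,
        0.005,
    )
    #: log-normal jitter of sampling time after a random dose (h)
    sample_delay_log_mean: float = np.log(6.0)
    sample_delay_log_sd: float = 1.1
    lloq_ng_ml: float = 0.100
    seed: int = 0


def _truncated_lognormal(rng, median, log_sd, lo, hi, size=None):
    """Log-normal around a median, redrawn into [lo, hi] (clip as fallback)."""
    out = np.exp(np.log(median) + log_sd * rng.standard_normal(size))
    for _ in range(20):
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            break
        out = np.where(
            bad, np.exp(np.log(median) + log_sd * rng.standard_normal(size)), out
        )
    return np.clip(out, lo, hi)


def _draw_age(rng, config: CohortConfig) -> float:
    lo, hi = config.age_range
    group = rng.choice(3, p=np.asarray(config.age_group_probs))
    bounds = [(lo, min(2.0, hi)), (max(2.0, lo), min(13.0, hi)), (max(13.0, lo), hi)]
    glo, ghi = bounds[group]
    return float(np.exp(rng.uniform(np.log(glo), np.log(ghi))))


def _weight_for_age(rng, age: float, config: CohortConfig) -> float:
    med = np.exp(
        np.interp(age, _GROWTH_KNOTS_AGE, np.log(_GROWTH_KNOTS_WT))
    )
    lo, hi = config.weight_range
    return float(_truncated_lognormal(rng, med, config.weight_log_sd, lo, hi))


def generate_cohort(
    config: CohortConfig,
    generating_model: PopulationModel,
    seed: int | None = None,
):
    """Generate a StudyDataset plus a truth record.

    Returns ``(dataset, truth)`` where ``truth`` is a dict with a
    ``subjects`` DataFrame (sid, age, wt, subpopulation, etas) and an
    ``observations`` DataFrame (sid, time, analyte, noise-free value,
    observed value, bql flag), both in internal units.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    model = generating_model
    parent = model.parent

    subjects: list[Subject] = []
    truth_subj_rows = []
    truth_obs_rows = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        age = _draw_age(rng, config)
        wt = _weight_for_age(rng, age, config)

        n_dose = int(
            round(
                _truncated_lognormal(
                    rng,
                    config.doses_per_subject_median,
                    config.doses_per_subject_log_sd,
                    *config.doses_per_subject_range,
                )
            )
        )
        interval = float(rng.choice(config.dosing_intervals))
        # irregular clinical dosing: jittered interval, occasional held dose
        gaps = interval * rng.uniform(0.85, 1.25, size=max(n_dose - 1, 0))
        held = rng.random(len(gaps)) < 0.05
        gaps[held] += interval
        dose_times = np.concatenate([[0.0], np.cumsum(gaps)])

        dose_per_kg = _truncated_lognormal(
            rng,
            config.dose_per_kg_median,
            config.dose_per_kg_log_sd,
            *config.dose_per_kg_range,
        )
        dose_mg = max(
            config.dose_increment_mg,
            round(dose_per_kg * wt / config.dose_increment_mg) * config.dose_increment_mg,
        )
        dose_nmol = dose_to_molar(dose_mg, parent)
        dose_amounts = np.full(n_dose, dose_nmol)

        n_samp = 1 + int(
            rng.choice(
                len(config.samples_per_subject_probs),
                p=np.asarray(config.samples_per_subject_probs),
            )
        )
        anchor = rng.integers(0, n_dose, size=n_samp)
        delay = np.exp(
            config.sample_delay_log_mean
            + config.sample_delay_log_sd * rng.standard_normal(n_samp)
        )
        samp_times = np.sort(dose_times[anchor] + delay)

        subject_cov = {"wt": wt, "age": age}
        sub_idx, eta = sample_individual(model, rng)
        lab = model.mixture.labels[sub_idx] if model.mixture is not None else None
        probe = Subject(
            sid=sid,
            covariates=subject_cov,
            dose_times=dose_times,
            dose_amounts=dose_amounts,
            obs_times=samp_times,
            obs_analytes=np.array(["x"] * n_samp, dtype=object),
            obs_values=np.zeros(n_samp),
            obs_bql=np.zeros(n_samp, dtype=bool),
        )
        params = individual_parameters(model, probe, eta, lab)
        prof = solve_profile(
            params, model.structure, dose_times, dose_amounts, samp_times
        )

        obs_times, obs_analytes, obs_values, obs_bql = [], [], [], []
        for analyte in model.analytes:
            f = prof[analyte.role]
            spec = model.error[analyte.name]
            eps = rng.standard_normal(n_samp)
            if spec.scale == "log":
                y = f * np.exp(spec.additive * eps)
            else:
                y = f + spec.sd(f) * eps
            lloq = conc_to_molar(config.lloq_ng_ml, analyte)
            for t, fv, yv in zip(samp_times, f, y):
                # lloq = 0 disables censoring entirely (negative noise
                # excursions are kept, mirroring the simulation engine)
                bql = bool(yv < lloq) if config.lloq_ng_ml > 0 else False
                obs_times.append(t)
                obs_analytes.append(analyte.name)
                obs_values.append(np.nan if bql else yv)
                obs_bql.append(bool(bql))
                truth_obs_rows.append(
                    {
                        "sid": sid,
                        "time": t,
                        "analyte": analyte.name,
                        "noise_free": fv,
                        "value": yv,
                        "bql": bool(bql),
                    }
                )

        order = np.lexsort((obs_analytes, obs_times))
        subjects.append(
            Subject(
                sid=sid,
                covariates=subject_cov,
                dose_times=dose_times,
                dose_amounts=dose_amounts,
                obs_times=np.asarray(obs_times)[order],
                obs_analytes=np.asarray(obs_analytes, dtype=object)[order],
                obs_values=np.asarray(obs_values)[order],
                obs_bql=np.asarray(obs_bql, dtype=bool)[order],
            )
        )
        row = {"sid": sid, "age": age, "wt": wt, "subpopulation": lab or ""}
        row.update(
            {f"eta_{name}": eta[j] for j, name in enumerate(model.random_effects.names)}
        )
        truth_subj_rows.append(row)

    dataset = StudyDataset(subjects=subjects)
    if dataset.n_obs == 0:
        raise ValueError("cohort configuration produced zero observations")
    truth = {
        "subjects": pd.DataFrame(truth_subj_rows),
        "observations": pd.DataFrame(truth_obs_rows),
    }
    return dataset, truth


def bql_filter(dataset: StudyDataset):
    """Drop below-quantification records; report exclusions per analyte.

    Returns ``(filtered_dataset, counts)`` where counts maps analyte name
    to the number of removed records.  Quantifiable records are untouched.
    """
    counts: dict[str, int] = {}
    new_subjects = []
    for s in dataset.subjects:
        keep = ~s.obs_bql
        for name in s.obs_analytes[~keep]:
            counts[name] = counts.get(name, 0) + 1
        new_subjects.append(
            Subject(
                sid=s.sid,
                covariates=dict(s.covariates),
                dose_times=s.dose_times.copy(),
                dose_amounts=s.dose_amounts.copy(),
                obs_times=s.obs_times[keep],
                obs_analytes=s.obs_analytes[keep],
                obs_values=s.obs_values[keep],
                obs_bql=s.obs_bql[keep],
            )
        )
    out = StudyDataset(subjects=new_subjects)
    if out.n_obs == 0 and dataset.n_obs > 0:
        warnings.warn("all records were below the quantification limit", stacklevel=2)
    return out, counts
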