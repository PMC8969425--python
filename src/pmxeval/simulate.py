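"""Population simulation: replicate ensembles over a study design.

Each replicate redraws, for every subject, a mixture subpopulation, a
log-normal random-effect vector, and residual error, then evaluates the
structural model over that subject's own dosing and sampling schedule.
Replicate ``r`` uses its own RNG stream spawned from the master seed, so
extending ``K`` appends new replicates without reshuffling earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import PopulationModel, StudyDataset, individual_parameters_many
from .profiles import solve_profile_many

__all__ = ["SimulationEnsemble", "sample_individual", "simulate_ensemble"]


@dataclass
class SimulationEnsemble:
    """K simulated values for every observation record of a dataset.

    ``values`` has shape (K, n_obs) with columns aligned to
    ``dataset.observation_records()`` order (subject order, record order
    within subject); natural concentration scale (nmol/mL).
    """

    values: np.ndarray
    records: pd.DataFrame
    seed: int
    model_label: str = ""

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def for_analyte(self, analyte: str) -> np.ndarray:
        mask = (self.records["analyte"] == analyte).to_numpy()
        return self.values[:, mask]

    def to_frame(self) -> pd.DataFrame:
        """Long format (replicate, sid, time, analyte, value)."""
        K, n = self.values.shape
        rec = self.records
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(K), n),
                "sid": np.tile(rec["sid"].to_numpy(), K),
                "time": np.tile(rec["time"].to_numpy(), K),
                "analyte": np.tile(rec["analyte"].to_numpy(), K),
                "value": self.values.ravel(),
            }
        )


def sample_individual(model: PopulationModel, rng: np.random.Generator):
    """Draw one (subpopulation index, eta vector) pair from the population."""
    if model.mixture is not None:
        props = np.asarray(model.mixture.proportions)
        sub = int(rng.choice(len(props), p=props))
    else:
        sub = 0
    L = model.random_effects.cholesky_factor()
    eta = L @ rng.standard_normal(model.random_effects.n_eta)
    return sub, eta


def _apply_residual_error(model, analytes, f, eps, truncate_negative=False):
    """Observation-level error per record given noise-free values f (K, n)."""
    y = np.empty_like(f)
    for name in np.unique(analytes):
        spec = model.error[name]
        cols = analytes == name
        if spec.scale == "log":
            y[:, cols] = f[:, cols] * np.exp(spec.additive * eps[:, cols])
        else:
            sd = np.sqrt((f[:, cols] * spec.proportional) ** 2 + spec.additive**2)
            y[:, cols] = f[:, cols] + sd * eps[:, cols]
    if truncate_negative:
        y = np.maximum(y, 0.0)
    return y


def simulate_ensemble(
    model: PopulationModel,
    dataset: StudyDataset,
    K: int,
    seed: int,
    truncate_negative: bool = False,
    include_error: bool = True,
) -> SimulationEnsemble:
    """Simulate K population replicates of the dataset's observations.

    Residual error follows each analyte's :class:`ResidualErrorSpec`
    (combined additive+proportional on the natural scale; additive on the
    log scale).  Negative values under additive natural-scale error are
    kept unless ``truncate_negative``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_obs = dataset.n_obs
    if n_obs == 0:
        raise ValueError("dataset has no observation records")
    S = dataset.n_subjects
    n_eta = model.random_effects.n_eta

    streams = np.random.SeedSequence(seed).spawn(K)
    subpop_all = np.zeros((K, S), dtype=int)
    eta_all = np.zeros((K, S, n_eta))
    eps_all = np.zeros((K, n_obs))
    L = model.random_effects.cholesky_factor()
    props = model.mixing_proportions
    for r in range(K):
        rng = np.random.Generator(np.random.PCG64(streams[r]))
        if model.mixture is not None:
            subpop_all[r] = rng.choice(len(props), size=S, p=props)
        if n_eta:
            eta_all[r] = rng.standard_normal((S, n_eta)) @ L.T
        eps_all[r] = rng.standard_normal(n_obs)

    values = np.empty((K, n_obs))
    col = 0
    for s_idx, subject in enumerate(dataset.subjects):
        n_s = subject.n_obs
        if n_s == 0:
            continue
        params = individual_parameters_many(
            model, subject, eta_all[:, s_idx, :], subpop_all[:, s_idx]
            if model.mixture is not None
            else None,
        )
        # solve once on the subject's unique observation times
        utimes, inv = np.unique(subject.obs_times, return_inverse=True)
        prof = solve_profile_many(
            params, model.structure, subject.dose_times, subject.dose_amounts, utimes
        )
        f = np.empty((K, n_s))
        for j in range(n_s):
            role = model.analyte_by_name(subject.obs_analytes[j]).role
            f[:, j] = prof[role][:, inv[j]]
        if include_error:
            y = _apply_residual_error(
                model,
                subject.obs_analytes,
                f,
                eps_all[:, col : col + n_s],
                truncate_negative,
            )
        else:
            y = f
        values[:, col : col + n_s] = y
        col += n_s

    return SimulationEnsemble(
        values=values,
        records=dataset.observation_records(),
        seed=seed,
        model_label=model.label,
    )
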