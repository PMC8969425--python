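"""Domain types for population pharmacokinetic models and study datasets.

A :class:`PopulationModel` bundles everything needed to simulate or evaluate
one nonlinear mixed-effects model of an orally dosed parent drug and
(optionally) its metabolite: the structural model (1 or 2 parent
compartments, first-order absorption with optional lag, 1-compartment
metabolite), typical parameter values, log-normal inter-individual random
effects, an optional finite-mixture specification for subpopulation
clearances (e.g. CYP2D6 metabolizer classes), covariate effects such as
allometric weight scaling, and per-analyte residual error.

Internal units are nmol for amounts, nmol/mL for concentrations, hours for
time, L and L/h for volumes and clearances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Analyte",
    "StructuralSpec",
    "ParameterSet",
    "MixtureSpec",
    "CovariateTerm",
    "allometric_terms",
    "RandomEffectsSpec",
    "ResidualErrorSpec",
    "PopulationModel",
    "Subject",
    "StudyDataset",
    "individual_parameters",
    "individual_parameters_many",
]

#: molecular weights (g/mol) of the analytes used throughout the examples
RISPERIDONE_MW = 410.485
PALIPERIDONE_MW = 425.91  # 9-OH-risperidone


@dataclass(frozen=True)
class Analyte:
    """One measured chemical species.

    Parameters
    ----------
    name : str
        Label used in datasets and reports (e.g. ``"risperidone"``).
    molecular_weight : float
        Molecular weight in g/mol, used to convert between mass and molar
        units.
    role : {"parent", "metabolite"}
        Position in the metabolic chain.
    """

    name: str
    molecular_weight: float
    role: str

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.role not in ("parent", "metabolite"):
            raise ValueError(f"unknown analyte role {self.role!r}")


@dataclass(frozen=True)
class StructuralSpec:
    """Structural choices: compartment counts, absorption lag, metabolite."""

    parent_compartments: int = 1
    has_metabolite: bool = False
    lag: bool = False

    def __post_init__(self) -> None:
        if self.parent_compartments not in (1, 2):
            raise ValueError("parent_compartments must be 1 or 2")


_POSITIVE_FIELDS = ("cl", "v", "ka", "q", "vp", "clm", "vm")


@dataclass(frozen=True)
class ParameterSet:
    """A complete set of individual (or typical) PK parameters.

    Clearances in L/h, volumes in L, ``ka`` in 1/h, ``alag`` in h.  ``fm``
    is the fraction of parent clearance that forms the metabolite; ``f`` is
    oral bioavailability.  ``q``/``vp`` are only meaningful for
    2-compartment parent models, ``fm``/``clm``/``vm`` only when a
    metabolite is modelled.
    """

    cl: float
    v: float
    ka: float
    f: float = 1.0
    alag: float = 0.0
    q: float | None = None
    vp: float | None = None
    fm: float | None = None
    clm: float | None = None
    vm: float | None = None

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            val = getattr(self, name)
            if val is not None and not np.all(np.asarray(val) > 0):
                if name == "cl" or name == "clm":
                    # zero clearance is allowed (used by conservation checks)
                    if np.all(np.asarray(val) >= 0):
                        continue
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.fm is not None and not np.all(np.asarray(self.fm) <= 1.0):
            raise ValueError("fm must be <= 1")
        if self.alag is not None and np.any(np.asarray(self.alag) < 0):
            raise ValueError("alag must be >= 0")

    def with_updates(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("cl", "v", "ka", "f", "alag", "q", "vp", "fm", "clm", "vm")
            if getattr(self, k) is not None
        }


@dataclass(frozen=True)
class MixtureSpec:
    """Finite mixture of subpopulations with parameter overrides.

    ``overrides[label]`` maps parameter names (usually ``cl`` and ``fm``)
    to the typical value used in that subpopulation; parameters not listed
    fall back to the base :class:`ParameterSet`.
    """

    labels: tuple[str, ...]
    proportions: tuple[float, ...]
    overrides: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.proportions):
            raise ValueError("labels and proportions must have equal length")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("mixing proportions must be non-negative")
        for lab in self.overrides:
            if lab not in self.labels:
                raise ValueError(f"override for unknown subpopulation {lab!r}")

    @property
    def n_subpopulations(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown subpopulation {label!r}; expected one of {self.labels}"
            ) from None


@dataclass(frozen=True)
class CovariateTerm:
    """One multiplicative covariate effect on a parameter.

    ``power`` form multiplies the parameter by ``(x / reference) **
    exponent``; ``linear`` form by ``1 + exponent * (x - reference)``.
    """

    parameter: str
    covariate: str
    form: str = "power"
    reference: float = 70.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("power", "linear"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    def factor(self, value):
        x = np.asarray(value, dtype=float)
        if self.form == "power":
            return (x / self.reference) ** self.exponent
        return 1.0 + self.exponent * (x - self.reference)


def allometric_terms(
    clearances: Sequence[str] = ("cl", "q", "clm"),
    volumes: Sequence[str] = ("v", "vp", "vm"),
    covariate: str = "wt",
    reference: float = 70.0,
) -> tuple[CovariateTerm, ...]:
    """Standard allometric preset: weight^0.75 on clearances, weight^1 on volumes."""
    terms = [
        CovariateTerm(p, covariate, "power", reference, 0.75) for p in clearances
    ]
    terms += [CovariateTerm(p, covariate, "power", reference, 1.0) for p in volumes]
    return tuple(terms)


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Log-normal inter-individual random effects.

    ``names`` lists the parameter each eta multiplies (as ``exp(eta)``);
    ``omega`` is their covariance matrix (same order).
    """

    names: tuple[str, ...]
    omega: np.ndarray

    def __post_init__(self) -> None:
        om = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if om.shape != (len(self.names), len(self.names)):
            raise ValueError("omega shape must match number of eta names")
        if not np.allclose(om, om.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        if len(self.names) and np.linalg.eigvalsh(om).min() < -1e-10:
            raise ValueError("omega must be positive semidefinite")
        object.__setattr__(self, "omega", om)

    @property
    def n_eta(self) -> int:
        return len(self.names)

    def cholesky_factor(self) -> np.ndarray:
        """A matrix L with L L^T = omega, valid for singular omega too."""
        if self.n_eta == 0:
            return np.zeros((0, 0))
        w, v = np.linalg.eigh(self.omega)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual unexplained variability for one analyte.

    On the natural scale the observation model is
    ``y = f + sqrt((f * proportional)**2 + additive**2) * eps`` with
    ``eps ~ N(0, 1)`` (a combined additive+proportional error).  On the log
    scale it is ``log y = log f + additive * eps``, i.e. the additive sd is
    interpreted on the log scale.
    """

    additive: float = 0.0
    proportional: float = 0.0
    scale: str = "natural"

    def __post_init__(self) -> None:
        if self.additive < 0 or self.proportional < 0:
            raise ValueError("error components must be >= 0")
        if self.additive == 0 and self.proportional == 0:
            raise ValueError("at least one of additive/proportional must be > 0")
        if self.scale not in ("natural", "log"):
            raise ValueError(f"unknown error scale {self.scale!r}")
        if self.scale == "log" and self.proportional > 0:
            raise ValueError("log-scale error uses the additive component only")

    def sd(self, f):
        """Standard deviation of the observation given noise-free value f."""
        f = np.asarray(f, dtype=float)
        if self.scale == "log":
            return np.full_like(f, self.additive)
        return np.sqrt((f * self.proportional) ** 2 + self.additive**2)


@dataclass(frozen=True)
class PopulationModel:
    """One complete population PK model ready for simulation or evaluation."""

    label: str
    analytes: tuple[Analyte, ...]
    structure: StructuralSpec
    theta: ParameterSet
    random_effects: RandomEffectsSpec
    error: Mapping[str, ResidualErrorSpec]
    mixture: MixtureSpec | None = None
    covariates: tuple[CovariateTerm, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        roles = [a.role for a in self.analytes]
        if roles.count("parent") != 1:
            raise ValueError("exactly one parent analyte is required")
        if roles.count("metabolite") > 1:
            raise ValueError("at most one metabolite analyte")
        if self.structure.has_metabolite != ("metabolite" in roles):
            raise ValueError("structure.has_metabolite inconsistent with analytes")
        if self.structure.has_metabolite and (
            self.theta.fm is None or self.theta.clm is None or self.theta.vm is None
        ):
            raise ValueError("metabolite model requires fm, clm and vm")
        if self.structure.parent_compartments == 2 and (
            self.theta.q is None or self.theta.vp is None
        ):
            raise ValueError("2-compartment parent requires q and vp")
        known = set(self.theta.as_dict())
        for name in self.random_effects.names:
            if name not in known:
                raise ValueError(f"eta on unknown parameter {name!r}")
        for term in self.covariates:
            if term.parameter not in known:
                raise ValueError(f"covariate on unknown parameter {term.parameter!r}")
        if self.mixture is not None:
            for ov in self.mixture.overrides.values():
                for name in ov:
                    if name not in known:
                        raise ValueError(f"mixture override on unknown parameter {name!r}")
        for name in self.error:
            if name not in {a.name for a in self.analytes}:
                raise ValueError(f"error spec for unknown analyte {name!r}")

    @property
    def parent(self) -> Analyte:
        return next(a for a in self.analytes if a.role == "parent")

    @property
    def metabolite(self) -> Analyte | None:
        return next((a for a in self.analytes if a.role == "metabolite"), None)

    def analyte_by_name(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(f"unknown analyte {name!r}")

    @property
    def subpopulation_labels(self) -> tuple[str, ...]:
        return self.mixture.labels if self.mixture is not None else ("",)

    @property
    def mixing_proportions(self) -> np.ndarray:
        if self.mixture is None:
            return np.array([1.0])
        return np.asarray(self.mixture.proportions, dtype=float)


@dataclass
class Subject:
    """Longitudinal records for one individual (internal units).

    Dose amounts are in nmol, observation values in nmol/mL; times are hours
    after the first recorded dose.  ``obs_values`` is NaN where the sample
    was below the quantification limit (``obs_bql`` True).
    """

    sid: str
    covariates: dict[str, float]
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    obs_analytes: np.ndarray
    obs_values: np.ndarray
    obs_bql: np.ndarray

    def __post_init__(self) -> None:
        self.dose_times = np.asarray(self.dose_times, dtype=float)
        self.dose_amounts = np.asarray(self.dose_amounts, dtype=float)
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_analytes = np.asarray(self.obs_analytes, dtype=object)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        self.obs_bql = np.asarray(self.obs_bql, dtype=bool)
        if np.any(self.dose_times < 0) or np.any(self.obs_times < 0):
            raise ValueError(f"subject {self.sid}: negative event time")
        if np.any(np.diff(self.dose_times) < 0):
            raise ValueError(f"subject {self.sid}: dose times must be sorted")
        if np.any(self.dose_amounts <= 0):
            raise ValueError(f"subject {self.sid}: dose amounts must be > 0")

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)

    def quantifiable(self) -> np.ndarray:
        return ~self.obs_bql


@dataclass
class StudyDataset:
    """A collection of subjects; observation records keep subject order."""

    subjects: list[Subject] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def subset_analytes(self, names) -> "StudyDataset":
        """Dataset restricted to observation records of the given analytes."""
        names = set(names)
        subjects = []
        for s in self.subjects:
            keep = np.array([a in names for a in s.obs_analytes], dtype=bool)
            subjects.append(
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
        return StudyDataset(subjects=subjects)

    def observation_records(self):
        """Long-format view of all observation records (one row per sample)."""
        import pandas as pd

        rows = []
        for s in self.subjects:
            for i in range(s.n_obs):
                rows.append(
                    {
                        "sid": s.sid,
                        "time": s.obs_times[i],
                        "analyte": s.obs_analytes[i],
                        "value": s.obs_values[i],
                        "bql": bool(s.obs_bql[i]),
                    }
                )
        return pd.DataFrame(
            rows, columns=["sid", "time", "analyte", "value", "bql"]
        )


def _covariate_factors(
    model: PopulationModel, subject_covariates: Mapping[str, float]
) -> dict[str, float]:
    factors: dict[str, float] = {}
    for term in model.covariates:
        if term.covariate not in subject_covariates:
            raise KeyError(
                f"covariate {term.covariate!r} required by the model is missing"
            )
        f = float(term.factor(subject_covariates[term.covariate]))
        factors[term.parameter] = factors.get(term.parameter, 1.0) * f
    return factors


def individual_parameters(
    model: PopulationModel,
    subject: Subject,
    eta: np.ndarray | None = None,
    subpop: str | None = None,
) -> ParameterSet:
    """Individual parameters: mixture override, then covariates, then exp(eta).

    ``subpop`` selects the mixture subpopulation (ignored for non-mixture
    models); ``eta=None`` means all random effects at zero.
    """
    many = individual_parameters_many(
        model,
        subject,
        None if eta is None else np.asarray(eta, dtype=float)[None, :],
        None if subpop is None and model.mixture is None else subpop,
    )
    return model.theta.with_updates(**{k: float(v[0]) for k, v in many.items()})


def individual_parameters_many(
    model: PopulationModel,
    subject: Subject,
    etas: np.ndarray | None = None,
    subpops=None,
) -> dict[str, np.ndarray]:
    """Vectorized individual parameters for many (eta, subpop) draws.

    Parameters
    ----------
    etas : (K, n_eta) array or None
        Random-effect draws; None means eta = 0.
    subpops : (K,) integer array, str label, or None
        Subpopulation per draw.  A single label applies to every draw.

    Returns
    -------
    dict mapping parameter name to (K,) array.
    """
    if etas is None:
        etas = np.zeros((1, model.random_effects.n_eta))
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    if etas.shape[1] != model.random_effects.n_eta:
        raise ValueError("eta length does not match omega dimension")
    K = etas.shape[0]

    base = model.theta.as_dict()
    out = {k: np.full(K, float(v)) for k, v in base.items()}

    if model.mixture is not None:
        mix = model.mixture
        if subpops is None:
            raise ValueError("mixture model requires a subpopulation")
        if isinstance(subpops, str):
            idx = np.full(K, mix.index(subpops))
        else:
            idx = np.asarray(subpops, dtype=int)
            if idx.min() < 0 or idx.max() >= mix.n_subpopulations:
                raise KeyError("subpopulation index out of range")
        for pname in {p for ov in mix.overrides.values() for p in ov}:
            table = np.array(
                [
                    float(mix.overrides.get(lab, {}).get(pname, base[pname]))
                    for lab in mix.labels
                ]
            )
            out[pname] = table[idx]
    elif isinstance(subpops, str) and subpops:
        raise KeyError(f"model {model.label!r} has no mixture subpopulations")

    for pname, fac in _covariate_factors(model, subject.covariates).items():
        out[pname] = out[pname] * fac

    for j, pname in enumerate(model.random_effects.names):
        out[pname] = out[pname] * np.exp(etas[:, j])

    return out
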