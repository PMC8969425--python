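"""Dataset and model-configuration readers/writers.

Datasets use a NONMEM-style longitudinal event CSV: one row per dose
(``evid=1``) or observation (``evid=0``), columns ``id, time, evid, amt,
analyte, dv, bql, wt, age`` (extra covariate columns pass through).  The
missing-value marker is ``"."``.  Common NONMEM aliases (``ID, TIME, EVID,
AMT, DV, MDV, WT/WEIGHT, AGE``) are accepted case-insensitively, so
translated NONMEM datasets load unchanged.

External units are mg (doses) and ng/mL (concentrations); internally the
package works in nmol and nmol/mL, converting through each analyte's
molecular weight.

Model configuration files are YAML with keys ``label, analytes, structure,
theta, omega (lower triangle), mixture, covariates, error, scale``.  A
small library of representative model configurations ships with the
package (see :func:`available_models`).
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings

import numpy as np
import pandas as pd
import yaml

from .models import (
    Analyte,
    CovariateTerm,
    MixtureSpec,
    ParameterSet,
    PopulationModel,
    RandomEffectsSpec,
    ResidualErrorSpec,
    StructuralSpec,
    StudyDataset,
    Subject,
    allometric_terms,
)
from .units import conc_to_mass, conc_to_molar, dose_to_mass, dose_to_molar

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_model",
    "save_model",
    "available_models",
]

log = logging.getLogger(__name__)

_ALIASES = {
    "id": "id",
    "time": "time",
    "evid": "evid",
    "amt": "amt",
    "dv": "dv",
    "analyte": "analyte",
    "bql": "bql",
    "mdv": "mdv",
    "wt": "wt",
    "weight": "wt",
    "age": "age",
}

_CORE = {"id", "time", "evid", "amt", "dv", "analyte", "bql", "mdv"}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    ren = {}
    for c in df.columns:
        key = c.strip().lower()
        ren[c] = _ALIASES.get(key, key)
    return df.rename(columns=ren)


def read_dataset(
    path,
    analytes: dict[str, Analyte] | list[Analyte],
    units: str = "external",
) -> StudyDataset:
    """Read an event CSV into a StudyDataset (internal units).

    ``analytes`` supplies the molecular weights for unit conversion (a list
    or a name->Analyte mapping); the parent analyte converts dose amounts.
    ``units="internal"`` skips conversion.
    """
    if isinstance(analytes, list):
        analytes = {a.name: a for a in analytes}
    parent = next(a for a in analytes.values() if a.role == "parent")

    df = pd.read_csv(path, na_values=["."], dtype={"analyte": "object"})
    df = _normalize_columns(df)
    for req in ("id", "time", "evid"):
        if req not in df.columns:
            raise ValueError(f"dataset is missing required column {req!r}")

    problems = []
    if (df["time"] < 0).any():
        problems.append(f"negative time at rows {df.index[df['time'] < 0].tolist()}")
    obs = df[df["evid"] == 0]
    unknown = obs["analyte"].dropna()[~obs["analyte"].dropna().isin(analytes)]
    if len(unknown):
        problems.append(
            f"unknown analyte(s) {sorted(set(unknown))} at rows {unknown.index.tolist()}"
        )
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))

    covariate_cols = [
        c for c in df.columns if c not in _CORE and df[c].dtype != object
    ]

    subjects = []
    for sid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("time", kind="stable")
        doses = grp[grp["evid"] == 1]
        obs = grp[grp["evid"] == 0]
        if "mdv" in grp.columns:
            obs = obs[(obs["mdv"].fillna(0) == 0) | obs.get("bql", 0).fillna(0).astype(bool)]
        if len(doses) and len(obs) and obs["time"].min() < doses["time"].min():
            warnings.warn(
                f"subject {sid}: observation before any dose (pre-dose sample kept)",
                stacklevel=2,
            )
        cov = {}
        for c in covariate_cols:
            vals = grp[c].dropna()
            if len(vals):
                cov[c] = float(vals.iloc[0])

        amt = doses["amt"].to_numpy(dtype=float)
        if np.isnan(amt).any():
            raise ValueError(f"subject {sid}: dose row without an amount")
        if units == "external":
            amt = dose_to_molar(amt, parent)

        bql = (
            obs["bql"].fillna(0).to_numpy(dtype=float).astype(bool)
            if "bql" in obs.columns
            else np.zeros(len(obs), dtype=bool)
        )
        dv = obs["dv"].to_numpy(dtype=float) if "dv" in obs.columns else np.full(len(obs), np.nan)
        missing_value = np.isnan(dv) & ~bql
        if missing_value.any():
            raise ValueError(
                f"subject {sid}: observation rows without a value and not flagged BQL"
            )
        values = dv.copy()
        if units == "external":
            for name, a in analytes.items():
                m = (obs["analyte"] == name).to_numpy() & ~bql
                values[m] = conc_to_molar(dv[m], a)
        values[bql] = np.nan

        subjects.append(
            Subject(
                sid=str(sid),
                covariates=cov,
                dose_times=doses["time"].to_numpy(dtype=float),
                dose_amounts=amt,
                obs_times=obs["time"].to_numpy(dtype=float),
                obs_analytes=obs["analyte"].to_numpy(dtype=object),
                obs_values=values,
                obs_bql=bql,
            )
        )
    ds = StudyDataset(subjects=subjects)
    log.info(
        "read %d subjects, %d observations from %s", ds.n_subjects, ds.n_obs, path
    )
    return ds


def write_dataset(
    dataset: StudyDataset,
    path,
    analytes: dict[str, Analyte] | list[Analyte],
    units: str = "external",
) -> None:
    """Write a StudyDataset to the event CSV dialect (default external units)."""
    if isinstance(analytes, list):
        analytes = {a.name: a for a in analytes}
    parent = next(a for a in analytes.values() if a.role == "parent")
    rows = []
    for s in dataset.subjects:
        cov = {k: s.covariates.get(k, np.nan) for k in ("wt", "age")}
        for t, amt in zip(s.dose_times, s.dose_amounts):
            a = dose_to_mass(amt, parent) if units == "external" else amt
            rows.append(
                {"id": s.sid, "time": t, "evid": 1, "amt": a, "analyte": np.nan,
                 "dv": np.nan, "bql": 0, **cov}
            )
        for i in range(s.n_obs):
            if s.obs_bql[i]:
                dv = np.nan
            elif units == "external":
                dv = conc_to_mass(s.obs_values[i], analytes[s.obs_analytes[i]])
            else:
                dv = s.obs_values[i]
            rows.append(
                {"id": s.sid, "time": s.obs_times[i], "evid": 0, "amt": np.nan,
                 "analyte": s.obs_analytes[i], "dv": dv,
                 "bql": int(s.obs_bql[i]), **cov}
            )
    df = pd.DataFrame(rows, columns=["id", "time", "evid", "amt", "analyte", "dv", "bql", "wt", "age"])
    df.to_csv(path, index=False, na_rep=".", float_format="%.10g")


# ---------------------------------------------------------------------------
# model configuration files


def _omega_from_lower(rows) -> np.ndarray:
    n = len(rows)
    om = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise ValueError("omega must be given as lower-triangle rows")
        for j, v in enumerate(row):
            om[i, j] = om[j, i] = float(v)
    return om


def model_from_dict(cfg: dict) -> PopulationModel:
    analytes = tuple(
        Analyte(a["name"], float(a["molecular_weight"]), a["role"])
        for a in cfg["analytes"]
    )
    st = cfg.get("structure", {})
    structure = StructuralSpec(
        parent_compartments=int(st.get("parent_compartments", 1)),
        has_metabolite=bool(st.get("has_metabolite", False)),
        lag=bool(st.get("lag", False)),
    )
    theta = ParameterSet(**{k: float(v) for k, v in cfg["theta"].items()})
    re_cfg = cfg.get("random_effects", {"names": [], "omega": []})
    random_effects = RandomEffectsSpec(
        names=tuple(re_cfg.get("names", [])),
        omega=_omega_from_lower(re_cfg.get("omega", [])),
    )
    mixture = None
    if cfg.get("mixture"):
        m = cfg["mixture"]
        mixture = MixtureSpec(
            labels=tuple(m["labels"]),
            proportions=tuple(float(p) for p in m["proportions"]),
            overrides={
                lab: {k: float(v) for k, v in ov.items()}
                for lab, ov in m.get("overrides", {}).items()
            },
        )
    cov_cfg = cfg.get("covariates", [])
    terms: list[CovariateTerm] = []
    if cov_cfg == "allometric" or (
        isinstance(cov_cfg, dict) and "allometric" in cov_cfg
    ):
        spec = cov_cfg.get("allometric", {}) if isinstance(cov_cfg, dict) else {}
        present = set(theta.as_dict())
        terms = list(
            allometric_terms(
                clearances=spec.get(
                    "clearances", [p for p in ("cl", "q", "clm") if p in present]
                ),
                volumes=spec.get(
                    "volumes", [p for p in ("v", "vp", "vm") if p in present]
                ),
                covariate=spec.get("covariate", "wt"),
                reference=float(spec.get("reference", 70.0)),
            )
        )
    else:
        for t in cov_cfg:
            terms.append(
                CovariateTerm(
                    parameter=t["parameter"],
                    covariate=t["covariate"],
                    form=t.get("form", "power"),
                    reference=float(t.get("reference", 70.0)),
                    exponent=float(t.get("exponent", t.get("slope", 1.0))),
                )
            )
    error = {
        name: ResidualErrorSpec(
            additive=float(e.get("additive", 0.0)),
            proportional=float(e.get("proportional", 0.0)),
            scale=e.get("scale", "natural"),
        )
        for name, e in cfg["error"].items()
    }
    return PopulationModel(
        label=cfg.get("label", "model"),
        analytes=analytes,
        structure=structure,
        theta=theta,
        random_effects=random_effects,
        error=error,
        mixture=mixture,
        covariates=tuple(terms),
        description=cfg.get("description", ""),
    )


def model_to_dict(model: PopulationModel) -> dict:
    om = model.random_effects.omega
    cfg = {
        "label": model.label,
        "description": model.description,
        "analytes": [
            {"name": a.name, "molecular_weight": a.molecular_weight, "role": a.role}
            for a in model.analytes
        ],
        "structure": {
            "parent_compartments": model.structure.parent_compartments,
            "has_metabolite": model.structure.has_metabolite,
            "lag": model.structure.lag,
        },
        "theta": model.theta.as_dict(),
        "random_effects": {
            "names": list(model.random_effects.names),
            "omega": [[float(om[i, j]) for j in range(i + 1)] for i in range(om.shape[0])],
        },
        "covariates": [
            {
                "parameter": t.parameter,
                "covariate": t.covariate,
                "form": t.form,
                "reference": t.reference,
                "exponent": t.exponent,
            }
            for t in model.covariates
        ],
        "error": {
            name: {
                "additive": e.additive,
                "proportional": e.proportional,
                "scale": e.scale,
            }
            for name, e in model.error.items()
        },
    }
    if model.mixture is not None:
        cfg["mixture"] = {
            "labels": list(model.mixture.labels),
            "proportions": [float(p) for p in model.mixture.proportions],
            "overrides": {k: dict(v) for k, v in model.mixture.overrides.items()},
        }
    return cfg


def available_models() -> list[str]:
    """Names of the representative model configurations shipped in modellib."""
    root = importlib.resources.files("pmxeval") / "modellib"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_model(source) -> PopulationModel:
    """Load a model config from a path, or by name from the shipped library."""
    name = str(source)
    if name in available_models():
        text = (importlib.resources.files("pmxeval") / "modellib" / f"{name}.yaml").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    return model_from_dict(yaml.safe_load(text))


def save_model(model: PopulationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
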