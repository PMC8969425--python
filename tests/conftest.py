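import numpy as np
import pytest

from pmxeval.models import (
    Analyte,
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

RISP = Analyte("risperidone", 410.485, "parent")
PALI = Analyte("9-OH-risperidone", 425.91, "metabolite")


def make_subject(
    sid="S1",
    wt=70.0,
    age=10.0,
    dose_times=(0.0,),
    dose_amounts=(1000.0,),
    obs_times=(6.0,),
    analytes=None,
    values=None,
    bql=None,
):
    obs_times = np.asarray(obs_times, dtype=float)
    n = len(obs_times)
    analytes = (
        np.asarray(analytes, dtype=object)
        if analytes is not None
        else np.array(["risperidone"] * n, dtype=object)
    )
    values = np.asarray(values, dtype=float) if values is not None else np.zeros(n)
    bql = np.asarray(bql, dtype=bool) if bql is not None else np.zeros(n, dtype=bool)
    return Subject(
        sid=sid,
        covariates={"wt": wt, "age": age},
        dose_times=np.asarray(dose_times, dtype=float),
        dose_amounts=np.asarray(dose_amounts, dtype=float),
        obs_times=obs_times,
        obs_analytes=analytes,
        obs_values=values,
        obs_bql=bql,
    )


@pytest.fixture
def simple_model():
    """1-compartment parent-only model, no mixture, no covariates."""
    return PopulationModel(
        label="simple",
        analytes=(RISP,),
        structure=StructuralSpec(1, False, False),
        theta=ParameterSet(cl=10.0, v=100.0, ka=1.2),
        random_effects=RandomEffectsSpec(("cl", "v"), np.diag([0.2, 0.15])),
        error={"risperidone": ResidualErrorSpec(additive=1e-6, proportional=0.2)},
    )


@pytest.fixture
def allometric_model():
    """Same structure with the allometric weight preset."""
    return PopulationModel(
        label="allo",
        analytes=(RISP,),
        structure=StructuralSpec(1, False, False),
        theta=ParameterSet(cl=10.0, v=100.0, ka=1.2),
        random_effects=RandomEffectsSpec(("cl",), np.array([[0.2]])),
        error={"risperidone": ResidualErrorSpec(proportional=0.2)},
        covariates=allometric_terms(clearances=("cl",), volumes=("v",)),
    )


@pytest.fixture
def parent_met_model():
    """Joint 1-compartment parent + metabolite model."""
    return PopulationModel(
        label="pm",
        analytes=(RISP, PALI),
        structure=StructuralSpec(1, True, False),
        theta=ParameterSet(cl=12.0, v=120.0, ka=1.0, fm=0.6, clm=5.0, vm=100.0),
        random_effects=RandomEffectsSpec(("cl", "v", "clm"), np.diag([0.3, 0.2, 0.2])),
        error={
            "risperidone": ResidualErrorSpec(additive=1e-6, proportional=0.25),
            "9-OH-risperidone": ResidualErrorSpec(additive=1e-6, proportional=0.25),
        },
    )


@pytest.fixture
def mixture_model():
    """Two metabolizer subpopulations with 5-fold separated clearances."""
    return PopulationModel(
        label="mix2",
        analytes=(RISP,),
        structure=StructuralSpec(1, False, False),
        theta=ParameterSet(cl=20.0, v=150.0, ka=1.0),
        random_effects=RandomEffectsSpec(("cl", "v"), np.diag([0.1, 0.1])),
        error={"risperidone": ResidualErrorSpec(additive=1e-6, proportional=0.15)},
        mixture=MixtureSpec(
            ("poor", "normal"),
            (0.3, 0.7),
            {"poor": {"cl": 4.0}, "normal": {"cl": 20.0}},
        ),
    )


@pytest.fixture
def small_dataset(simple_model):
    """Three-subject dataset with fixed values for deterministic checks."""
    subs = [
        make_subject("A", obs_times=(2.0, 8.0), values=(0.004, 0.002)),
        make_subject("B", dose_times=(0.0, 12.0), dose_amounts=(800.0, 800.0),
                     obs_times=(6.0, 18.0), values=(0.003, 0.0035)),
        make_subject("C", obs_times=(4.0,), values=(0.0025,)),
    ]
    return StudyDataset(subjects=subs)
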