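import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmxeval.models import ParameterSet, StructuralSpec
from pmxeval.profiles import (
    solve_amounts,
    solve_profile,
    solve_profile_many,
    solve_profile_ode,
)

ST_1CPT = StructuralSpec(1, False, False)
ST_1CPT_MET = StructuralSpec(1, True, False)
ST_2CPT_LAG = StructuralSpec(2, False, True)
ST_2CPT_MET_LAG = StructuralSpec(2, True, True)

P_2CPT_MET = ParameterSet(
    cl=12.0, v=110.0, ka=1.2, alag=0.35, q=18.0, vp=350.0, fm=0.7, clm=5.0, vm=120.0
)


def bateman(t, D, cl, v, ka, f=1.0):
    """Independent closed-form oracle for 1-cpt oral absorption (nmol/mL)."""
    k10 = cl / v
    return f * D * ka / (1e3 * v * (ka - k10)) * (np.exp(-k10 * t) - np.exp(-ka * t))


def test_causality_zero_before_first_dose_plus_lag():
    t = np.array([0.0, 1.0, 2.0, 2.34])
    prof = solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [2.0], [500.0], t)
    # first dose at 2 h, lag 0.35 h: nothing before 2.35 h
    assert np.all(prof["parent"] == 0.0)
    assert np.all(prof["metabolite"] == 0.0)


def test_superposition_of_two_doses():
    t = np.linspace(0, 48, 97)
    both = solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [0.0, 12.0], [400.0, 400.0], t)
    d1 = solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [0.0], [400.0], t)
    d2 = solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [12.0], [400.0], t)
    for k in both:
        assert np.allclose(both[k], d1[k] + d2[k], rtol=1e-12, atol=1e-18)


def test_matches_bateman_closed_form():
    p = ParameterSet(cl=10.0, v=100.0, ka=1.2, f=0.8)
    t = np.linspace(0.25, 48, 50)
    got = solve_profile(p, ST_1CPT, [0.0], [1000.0], t)["parent"]
    want = bateman(t, 1000.0, p.cl, p.v, p.ka, p.f)
    assert np.max(np.abs(got - want) / want) < 1e-6


def test_dose_proportionality_is_exact():
    t = np.linspace(0.5, 36, 20)
    one = solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [0.0, 10.0], [300.0, 300.0], t)
    two = solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [0.0, 10.0], [600.0, 600.0], t)
    for k in one:
        assert np.array_equal(two[k], 2.0 * one[k])


def test_mass_balance_with_zero_elimination():
    # no elimination anywhere and F = 1: compartments hold the dosed amount
    p = ParameterSet(
        cl=0.0, v=110.0, ka=1.2, alag=0.1, q=18.0, vp=350.0, fm=1.0, clm=0.0, vm=120.0
    )
    t = np.array([0.5, 2.0, 13.0, 40.0, 120.0])
    am = solve_amounts(p, ST_2CPT_MET_LAG, [0.0, 12.0], [500.0, 500.0], t)
    total = sum(am.values())
    cumdose = np.where(t >= 12.0 + p.alag, 1000.0, 500.0)
    assert np.max(np.abs(total - cumdose) / cumdose) < 1e-8


@pytest.mark.parametrize(
    "params, structure",
    [
        (ParameterSet(cl=10.0, v=100.0, ka=1.2), ST_1CPT),
        (ParameterSet(cl=24.0, v=260.0, ka=1.4, alag=0.25, q=25.0, vp=440.0), ST_2CPT_LAG),
        (
            ParameterSet(cl=12.0, v=120.0, ka=1.0, fm=0.6, clm=5.0, vm=100.0),
            ST_1CPT_MET,
        ),
        (P_2CPT_MET, ST_2CPT_MET_LAG),
    ],
    ids=["1cpt", "2cpt-lag", "parent-metabolite", "2cpt-metabolite-lag"],
)
def test_closed_form_agrees_with_ode_integrator(params, structure):
    t = np.linspace(0.5, 48, 25)
    doses_t, doses_a = [0.0, 12.0, 24.0], [600.0, 600.0, 600.0]
    a = solve_profile(params, structure, doses_t, doses_a, t)
    b = solve_profile_ode(params, structure, doses_t, doses_a, t)
    for k in a:
        rel = np.abs(a[k] - b[k]) / np.maximum(np.abs(b[k]), 1e-15)
        assert np.max(rel) < 1e-6


def test_vectorized_matches_scalar():
    rng = np.random.default_rng(0)
    cls = 10.0 * np.exp(0.3 * rng.standard_normal(8))
    t = np.linspace(0.5, 24, 10)
    many = solve_profile_many(
        {"cl": cls, "v": 100.0, "ka": 1.2, "f": 1.0},
        ST_1CPT,
        [0.0],
        [1000.0],
        t,
    )["parent"]
    for i, cl in enumerate(cls):
        one = solve_profile(ParameterSet(cl=cl, v=100.0, ka=1.2), ST_1CPT, [0.0], [1000.0], t)
        assert np.allclose(many[i], one["parent"], rtol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    cl=st.floats(0.5, 80.0),
    v=st.floats(20.0, 600.0),
    ka=st.floats(0.1, 5.0),
    fm=st.floats(0.05, 1.0),
    clm=st.floats(0.5, 40.0),
)
def test_profiles_finite_and_nonnegative(cl, v, ka, fm, clm):
    p = ParameterSet(cl=cl, v=v, ka=ka, fm=fm, clm=clm, vm=150.0)
    t = np.linspace(0.0, 96, 30)
    prof = solve_profile(p, ST_1CPT_MET, [0.0, 24.0], [500.0, 500.0], t)
    for series in prof.values():
        assert np.all(np.isfinite(series))
        assert np.all(series >= -1e-12)


def test_negative_times_rejected():
    with pytest.raises(ValueError):
        solve_profile(P_2CPT_MET, ST_2CPT_MET_LAG, [0.0], [100.0], [-1.0])
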