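import numpy as np
import pytest

from pmxeval.estimate import (
    compute_cwres,
    ebe_estimate,
    fit_dataset,
    mixture_posterior,
    population_prediction,
)
from pmxeval.models import (
    MixtureSpec,
    ParameterSet,
    PopulationModel,
    RandomEffectsSpec,
    ResidualErrorSpec,
    StructuralSpec,
    StudyDataset,
    individual_parameters,
)
from pmxeval.profiles import solve_profile
from pmxeval.simulate import simulate_ensemble

from conftest import RISP, make_subject


class TestMixturePosterior:
    def test_equal_likelihoods_return_priors(self):
        post = mixture_posterior([0.8, 0.2], [-3.0, -3.0])
        assert np.allclose(post, [0.8, 0.2])

    def test_hand_bayes(self):
        # prior odds 4:1 exactly cancelled by likelihood ratio 1:4
        post = mixture_posterior([0.8, 0.2], [0.0, np.log(4.0)])
        assert np.allclose(post, [0.5, 0.5], atol=1e-12)

    def test_invariant_to_constant_shift(self):
        a = mixture_posterior([0.3, 0.7], [-10.0, -12.0])
        b = mixture_posterior([0.3, 0.7], [-1010.0, -1012.0])
        assert np.allclose(a, b)

    def test_all_minus_inf_rejected(self):
        with pytest.raises(ValueError):
            mixture_posterior([0.5, 0.5], [-np.inf, -np.inf])


class TestPopulationPrediction:
    def test_no_mixture_equals_eta_zero_profile(self, simple_model):
        sub = make_subject(obs_times=(2.0, 8.0))
        pred = population_prediction(simple_model, sub)
        prof = solve_profile(
            simple_model.theta, simple_model.structure, sub.dose_times,
            sub.dose_amounts, sub.obs_times,
        )["parent"]
        assert np.allclose(pred, prof)

    def test_weighted_average_of_subpopulations(self, mixture_model):
        sub = make_subject(obs_times=(4.0, 10.0))
        pred = population_prediction(mixture_model, sub)
        parts = []
        for lab in mixture_model.mixture.labels:
            p = individual_parameters(mixture_model, sub, np.zeros(2), lab)
            parts.append(
                solve_profile(p, mixture_model.structure, sub.dose_times,
                              sub.dose_amounts, sub.obs_times)["parent"]
            )
        want = 0.3 * parts[0] + 0.7 * parts[1]
        assert np.allclose(pred, want)

    def test_degenerate_mixture_equals_single_subpop(self):
        model = PopulationModel(
            label="deg",
            analytes=(RISP,),
            structure=StructuralSpec(1, False, False),
            theta=ParameterSet(cl=20.0, v=150.0, ka=1.0),
            random_effects=RandomEffectsSpec(("cl",), np.array([[0.1]])),
            error={"risperidone": ResidualErrorSpec(proportional=0.1)},
            mixture=MixtureSpec(("a", "b"), (1.0, 0.0), {"a": {"cl": 5.0}, "b": {"cl": 20.0}}),
        )
        sub = make_subject(obs_times=(4.0,))
        pred = population_prediction(model, sub)
        p = individual_parameters(model, sub, np.zeros(1), "a")
        want = solve_profile(p, model.structure, sub.dose_times, sub.dose_amounts,
                             sub.obs_times)["parent"]
        assert np.allclose(pred, want)

    def test_pred_ignores_observed_values(self, simple_model):
        a = make_subject(obs_times=(3.0, 9.0), values=(0.001, 0.002))
        b = make_subject(obs_times=(3.0, 9.0), values=(5.0, 9.0))
        assert np.array_equal(
            population_prediction(simple_model, a), population_prediction(simple_model, b)
        )


class TestEbe:
    def test_tiny_omega_pins_eta_at_zero(self):
        model = PopulationModel(
            label="tight",
            analytes=(RISP,),
            structure=StructuralSpec(1, False, False),
            theta=ParameterSet(cl=10.0, v=100.0, ka=1.2),
            random_effects=RandomEffectsSpec(("cl",), np.array([[1e-8]])),
            error={"risperidone": ResidualErrorSpec(proportional=0.2)},
        )
        sub = make_subject(obs_times=(4.0, 9.0), values=(0.01, 0.02))
        fit = ebe_estimate(model, sub)
        assert np.all(np.abs(fit.eta) < 1e-3)

    def test_no_observations_returns_priors_and_zero_eta(self, mixture_model):
        sub = make_subject(obs_times=(4.0,), values=(np.nan,), bql=(True,))
        fit = ebe_estimate(mixture_model, sub)
        assert np.allclose(fit.subpop_posterior, [0.3, 0.7])
        assert np.all(fit.eta == 0.0)

    def test_recovers_known_eta_from_rich_low_noise_data(self, simple_model):
        eta_true = np.array([0.4, -0.2])
        times = np.linspace(0.5, 30, 12)
        sub = make_subject(obs_times=times)
        model = PopulationModel(
            label="lownoise",
            analytes=simple_model.analytes,
            structure=simple_model.structure,
            theta=simple_model.theta,
            random_effects=simple_model.random_effects,
            error={"risperidone": ResidualErrorSpec(proportional=1e-6)},
        )
        p = individual_parameters(model, sub, eta_true)
        f = solve_profile(p, model.structure, sub.dose_times, sub.dose_amounts, times)
        sub.obs_values = f["parent"]
        fit = ebe_estimate(model, sub)
        assert np.max(np.abs(fit.eta - eta_true)) < 1e-2

    def test_objective_trace_non_increasing_to_best(self, simple_model):
        sub = make_subject(obs_times=(2.0, 10.0), values=(0.005, 0.003))
        fit = ebe_estimate(simple_model, sub)
        # the recorded multi-start objectives are sorted towards the optimum
        assert fit.objective == pytest.approx(min(fit.objective_trace))
        assert all(a >= b for a, b in zip(fit.objective_trace, fit.objective_trace[1:]))


class TestCwres:
    def test_no_random_effects_gives_exact_standardization(self):
        model = PopulationModel(
            label="fixed",
            analytes=(RISP,),
            structure=StructuralSpec(1, False, False),
            theta=ParameterSet(cl=10.0, v=100.0, ka=1.2),
            random_effects=RandomEffectsSpec((), np.zeros((0, 0))),
            error={"risperidone": ResidualErrorSpec(additive=0.001)},
        )
        sub = make_subject(obs_times=(6.0,), values=(0.005,))
        ds = StudyDataset([sub])
        fits = fit_dataset(model, ds)
        cw = compute_cwres(model, ds, fits)
        pred = population_prediction(model, sub)[0]
        assert cw[0] == pytest.approx((0.005 - pred) / 0.001, rel=1e-8)

    def test_gross_overprediction_flagged(self, simple_model):
        sub = make_subject(obs_times=(6.0,))
        pred = population_prediction(simple_model, sub)[0]
        sub.obs_values = np.array([10.0 * pred])
        ds = StudyDataset([sub])
        cw = compute_cwres(simple_model, ds, fit_dataset(simple_model, ds))
        assert cw[0] > 2.0

    def test_null_calibration(self, simple_model):
        """CWRES from self-simulated data are approximately standard normal."""
        rng = np.random.default_rng(21)
        n_subj = 250
        subjects = []
        for i in range(n_subj):
            t = np.sort(rng.uniform(1.0, 24.0, 2))
            subjects.append(make_subject(f"S{i}", obs_times=t))
        ds = StudyDataset(subjects)
        ens = simulate_ensemble(simple_model, ds, K=1, seed=100)
        col = 0
        for s in ds.subjects:
            s.obs_values = ens.values[0, col : col + s.n_obs]
            col += s.n_obs
        cw = compute_cwres(simple_model, ds, fit_dataset(simple_model, ds, seed=1))
        assert abs(np.mean(cw)) < 0.1
        assert 0.9 < np.std(cw, ddof=1) < 1.1
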