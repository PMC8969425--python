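# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `pmxeval`. Everything stated here is computed by the
package's test suite or by `scripts/acceptance.py`; no external results
are quoted.

## Structural models and the closed-form engine

All supported population PK models are linear, time-invariant compartment
systems: a first-order absorption depot (optional lag time) feeding a 1-
or 2-compartment parent drug, with a fraction `fm` of the parent
elimination clearance `CL` forming a 1-compartment metabolite eliminated
with clearance `CLm`. For a unit bolus into the depot, the Laplace
transform of every compartment amount is a strictly proper rational
function with simple real poles (the rate constants `ka`, the 2-compartment
hybrid rates α/β, and `CLm/Vm`). Each amount is therefore a sum of
exponentials whose coefficients are partial-fraction residues; multiple
doses superpose and a lag time shifts every dose's entry. This is exact,
vectorizes across whole parameter ensembles (a K-replicate simulation of a
subject is a single array operation), and underlies all simulation,
prediction and estimation code.

Numerical choices:

- Exactly coincident rate constants would need confluent (t·e^{−λt})
  terms; instead, rates closer than 1e-7 relative are nudged apart, which
  bounds the error by roughly `rate · t · 1e-7`. Zero rates (used by
  mass-conservation checks) are floored at distinct values near 1e-12.
- An independent piecewise ODE integration (`solve_profile_ode`,
  scipy LSODA at rtol 1e-11) ships behind the same interface as a
  cross-check oracle; agreement is enforced at 1e-6 relative error in the
  test suite for 1-compartment, 2-compartment and parent→metabolite
  systems.
- Internal units: nmol amounts, nmol/mL concentrations, hours, L, L/h.
  Time zero is each subject's first recorded dose.

Individual parameters are assembled in a fixed order: mixture-class
overrides of the typical values, then multiplicative covariate factors
(the allometric preset uses weight/70 kg with fixed exponents 0.75 on
clearances and 1 on volumes), then `exp(eta)` for the log-normal random
effects. A covariate at its reference value therefore changes nothing, and
all enteral administration routes map to the single first-order absorption
pathway (none of the supported model structures distinguishes routes).

## Residual error

Per analyte, either a combined model on the natural scale,
`y = f + sqrt((f·σ_prop)² + σ_add²)·ε`, or an additive model on the log
scale, `log y = log f + σ_add·ε`, with `ε ~ N(0,1)`. The combined form is
the single-draw equivalent of separate additive and proportional noise
terms (their variances add). Negative simulated concentrations under the
natural-scale model are kept by default (they carry information for
rank-based diagnostics); a switch truncates at zero.

## Simulation ensembles

`simulate_ensemble` redraws, per replicate and subject, a mixture class
from the fixed mixing proportions, an eta vector from N(0, Ω), and
residual noise, then evaluates the profile on the subject's own dosing and
sampling schedule. One RNG stream per replicate is spawned from the master
seed, so enlarging K appends replicates without reshuffling earlier ones —
ensembles are bit-reproducible and prefix-stable. Fixed effects carry no
uncertainty: the models under evaluation stay exactly as configured.
Below-quantification censoring is never applied to simulated values; BQL
handling is an observed-data concern (BQL records are excluded from every
diagnostic, with counts reported).

## Prediction-based statistics

PE and RMSE (nmol/mL) and MPE and MAPE (%) pool all quantifiable
observations, indexed directly without per-subject averaging. The sign
convention is PRED − OBS throughout: positive values mean over-prediction.
Note that MPE is not centered at zero even for a correct model: with
log-normal variability the expectation of (PRED − OBS)/OBS is positive, so
large positive MPE values arise partly from skew and partly from bias —
MAPE and the simulation-based diagnostics disambiguate. On the log scale
(used for models whose residual error is log-additive) the difference of
logs is itself a relative error, so MPE/MAPE are defined as
100·mean(log PRED − log OBS) and its absolute counterpart.

For mixture models, PRED defaults to the mixing-proportion-weighted
average of the per-class eta = 0 profiles (the marginal mean at eta = 0);
a switch selects the most-probable class instead. Both conventions exist
in practice and the choice is reported rather than asserted.

## Empirical-Bayes estimation, class posteriors, CWRES

With population parameters fixed, each subject's MAP eta maximizes
`log p(y | eta, class) + log p(eta)` per candidate class (L-BFGS-B from
eta = 0 plus two jittered restarts, bounds ±20 to keep exponentials
finite). Class posteriors combine the mixing proportions with a Laplace
approximation of each class's marginal likelihood (joint density at the
MAP times the curvature volume from a finite-difference Hessian); a
subject with no quantifiable observations keeps the prior proportions and
eta = 0. CWRES linearize the individual prediction around the MAP eta with
central finite differences (relative step 1e-4), whiten
`y − f(η̂) + G·η̂` with the Cholesky factor of `G Ω Gᵀ + diag(residual
variance)`, and are approximately standard normal when the evaluated model
generated the data (checked by a 250-subject null calibration in the test
suite). Singular covariances are ridge-regularized with a warning.

## Prediction-corrected VPC

Observations and simulated values are binned on time after first dose
(default 8 quantile bins; ties at a cut point go to the lower bin; with
fewer distinct times than bins, bins merge with a warning) and rescaled by
bin-median PRED over record PRED. The 95% prediction band per bin is the
2.5th–97.5th percentile of the pooled corrected simulated values — a
prediction interval for concentrations, matching how such bands are
usually drawn for sparse data; the confidence-interval-around-percentiles
variant is available behind a flag. An observation is outside if its
corrected value falls strictly outside its bin's band; percentages are
rounded half away from zero to one decimal (so 11.65% prints as 11.7%).
With homogeneous designs the correction is the identity and coverage is
nominal (~5% outside under self-evaluation, verified in the acceptance
suite); with strongly heterogeneous designs the pooled band retains
between-record variability and coverage is conservative. A very late
sample can be excluded from binning and counting via `max_time`; both
inclusion modes are supported.

## NPDE

Per subject, observed and simulated vectors are centered on the simulated
mean and whitened with the inverse lower Cholesky factor of the empirical
simulation covariance (decorrelation in record order; single-record
subjects take a scalar path). The pde of a record is the rank of the
whitened observation among the whitened replicates divided by K, with ties
counting one half and clamping to [1/(2K), 1 − 1/(2K)] so the
standard-normal quantile (the npde) stays finite. Adequacy is probed with
a t-test of mean 0, a two-sided variance test ((n−1)s² against
chi-square(n−1)), and Shapiro–Wilk normality, combined by Bonferroni
(reject if min p < α/3).

Calibration, measured in the acceptance suite over 200 synthetic
50-subject datasets at K = 500: with the non-mixture joint
parent–metabolite model the global rejection rate is ~3.5% at α = 0.05
and the pooled npde mean is within ±0.01. Known limitation: under
finite-mixture models the within-subject joint distribution is multimodal,
and linear decorrelation cannot remove its nonlinear dependence; the
variance test then over-rejects (~11–13% measured under the
3-subpopulation mixture; 24% with decorrelation disabled, so whitening
helps but is not exact). This is a property of the npde construction
itself, shared with its standard implementations, and worth remembering
when reading npde tests of mixture models. Power is high where it matters:
halving the generating clearances is detected in >95% of 60-subject
datasets, with the npde mean pushed positive (observations above
simulations).

## Synthetic cohort generator

The generator emulates an opportunistic pediatric study, not any real
dataset: ages are drawn in three strata (37% below 2 y, 47% 2–13 y, 16%
13 y and above, log-uniform within each) over 0.16–16.8 y; weight follows
a piecewise log-linear growth curve with 0.22 log-sd individual spread
truncated to 3.64–129 kg, preserving the age–weight correlation that
allometric models need. Dosing is weight-based (median 0.017 mg/kg,
log-normal, bounded 0.003–0.068, rounded to 0.05 mg increments), repeated
at q12h or q24h intervals with ±25% jitter and occasional held doses,
with a log-normal number of doses (median 9, range 1–43). Sampling is
sparse (1–7 samples per subject, median 1) at a log-normal delay after a
randomly chosen dose, yielding a mix of trough-like and haphazard times.
Both analytes are measured at each draw. Observations below the LLOQ
(0.100 ng/mL by default, converted per analyte to nmol/mL) are flagged
BQL and their values withheld; LLOQ = 0 disables censoring entirely. The
true classes, etas and noise-free concentrations are returned for
recovery tests.

What the generator does not emulate: assay differences between studies,
ECMO or drug-interaction physiology, CYP2D6 ontogeny, dropout, or dose
titration over time. Passing diagnostics on synthetic cohorts therefore
demonstrate the correctness and calibration of the evaluation machinery
under known truth — not that any particular published model generalizes to
real pediatric data.

## Pipeline scale and determinism

The default end-to-end run (62 subjects, 5 models, K = 1000) completes in
about a minute on one CPU and writes byte-identical CSV reports when
re-run with the same seed. One model's failure is recorded and skipped
without aborting the rest. Cross-model comparisons (ranking by RMSE and
|MPE|) are descriptive; no multiplicity adjustment is applied across
models. Test-suite problem sizes (e.g., 200 calibration datasets of 50
subjects at K = 500, 100 power datasets, 250-subject CWRES null) were
chosen to keep Monte-Carlo error well below the asserted margins while
running in minutes.

## Model configuration library

The five shipped YAML configurations reproduce the *structures* of the
five model families the package targets — a pediatric 2-compartment
parent + metabolite model with lag; a pediatric and an adult
1-compartment parent + metabolite three-class mixture (the adult one with
and without allometric rescaling); and a 2-compartment parent-only
two-class mixture evaluated on the log scale. Their numeric values are
representative placeholders chosen for realistic concentration ranges;
they are clearly labelled as such and are not the published estimates,
which users should transcribe into their own config files from the source
publications.
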