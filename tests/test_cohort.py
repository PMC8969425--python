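import io

import numpy as np
import pytest

from pmxeval.cohort import CohortConfig, bql_filter, generate_cohort
from pmxeval.io import load_model, write_dataset
from pmxeval.models import StudyDataset
from pmxeval.units import conc_to_molar

from conftest import RISP, make_subject


@pytest.fixture(scope="module")
def model_b():
    return load_model("model_b")


@pytest.fixture(scope="module")
def default_cohort(model_b):
    return generate_cohort(CohortConfig(n_subjects=62, seed=123), model_b)


class TestGeneration:
    def test_covariates_within_configured_ranges(self, default_cohort):
        ds, _ = default_cohort
        ages = np.array([s.covariates["age"] for s in ds.subjects])
        wts = np.array([s.covariates["wt"] for s in ds.subjects])
        assert ages.min() >= 0.16 and ages.max() <= 16.8
        assert wts.min() >= 3.64 and wts.max() <= 129.0

    def test_design_shapes(self, default_cohort):
        ds, _ = default_cohort
        ndoses = [len(s.dose_times) for s in ds.subjects]
        assert min(ndoses) >= 1 and max(ndoses) <= 43
        nsamp = [len(np.unique(s.obs_times)) for s in ds.subjects]
        assert min(nsamp) >= 1 and max(nsamp) <= 7

    def test_quantifiable_values_above_lloq(self, default_cohort, model_b):
        ds, _ = default_cohort
        for s in ds.subjects:
            for analyte, val, bql in zip(s.obs_analytes, s.obs_values, s.obs_bql):
                if not bql:
                    lloq = conc_to_molar(0.100, model_b.analyte_by_name(analyte))
                    assert val >= lloq

    def test_lloq_conversion_bound(self):
        assert conc_to_molar(0.100, RISP) == pytest.approx(2.4361e-4, rel=1e-4)

    def test_zero_lloq_means_no_censoring(self, model_b):
        ds, _ = generate_cohort(CohortConfig(n_subjects=30, lloq_ng_ml=0.0, seed=5), model_b)
        assert sum(s.obs_bql.sum() for s in ds.subjects) == 0

    def test_truth_record_complete(self, default_cohort):
        ds, truth = default_cohort
        assert len(truth["subjects"]) == ds.n_subjects
        assert set(truth["subjects"]["subpopulation"]).issubset(
            {"poor", "intermediate", "normal"}
        )
        assert len(truth["observations"]) == ds.n_obs
        assert np.all(np.isfinite(truth["observations"]["noise_free"]))

    def test_same_seed_byte_identical(self, model_b):
        bufs = []
        for _ in range(2):
            ds, _ = generate_cohort(CohortConfig(n_subjects=20, seed=77), model_b)
            buf = io.StringIO()
            write_dataset(ds, buf, list(model_b.analytes))
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_marginal_medians_match_configuration(self, model_b):
        # disable dose rounding so the configured continuous distribution
        # medians are directly checkable
        cfg = CohortConfig(n_subjects=5000, seed=9, dose_increment_mg=1e-9)
        ds, _ = generate_cohort(cfg, model_b)
        n_samp = np.array([len(np.unique(s.obs_times)) for s in ds.subjects])
        assert np.median(n_samp) == 1
        dose_per_kg = np.array(
            [
                s.dose_amounts[0] * 410.485 / 1e6 / s.covariates["wt"]
                for s in ds.subjects
            ]
        )
        assert np.median(dose_per_kg) == pytest.approx(cfg.dose_per_kg_median, rel=0.05)
        ndoses = np.array([len(s.dose_times) for s in ds.subjects])
        assert np.median(ndoses) == pytest.approx(cfg.doses_per_subject_median, abs=1)

    def test_doses_rounded_to_practical_increments(self, default_cohort):
        ds, _ = default_cohort
        for s in ds.subjects:
            mg = s.dose_amounts[0] * 410.485 / 1e6
            assert mg >= 0.05 - 1e-9
            assert abs(mg / 0.05 - round(mg / 0.05)) < 1e-6


class TestBqlFilter:
    def _dataset_with_flags(self, n_total, n_bql):
        subs = []
        for i in range(n_total):
            subs.append(
                make_subject(
                    f"S{i}",
                    obs_times=(6.0,),
                    values=(np.nan if i < n_bql else 0.001,),
                    bql=(i < n_bql,),
                )
            )
        return StudyDataset(subs)

    def test_counts_reported(self):
        ds = self._dataset_with_flags(113, 10)
        out, counts = bql_filter(ds)
        assert counts == {"risperidone": 10}
        assert out.n_obs == 103

    def test_identity_when_no_bql(self):
        ds = self._dataset_with_flags(5, 0)
        out, counts = bql_filter(ds)
        assert counts == {}
        assert out.n_obs == ds.n_obs

    def test_all_bql_warns_and_empties(self):
        ds = self._dataset_with_flags(4, 4)
        with pytest.warns(UserWarning):
            out, counts = bql_filter(ds)
        assert out.n_obs == 0
        assert counts["risperidone"] == 4
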