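import numpy as np
import pytest

from pmxeval.estimate import pred_for_dataset
from pmxeval.models import StudyDataset
from pmxeval.simulate import simulate_ensemble
from pmxeval.vpc import (
    assign_bins,
    outside_percentage,
    prediction_correct,
    round_half_away,
    vpc_bands,
)

from conftest import make_subject


class TestBinning:
    def test_single_bin(self):
        labels, cuts = assign_bins([1.0, 5.0, 9.0], n_bins=1)
        assert len(cuts) == 0
        assert np.all(labels == 0)

    def test_uniform_times_fill_bins_evenly(self):
        times = np.arange(16.0)
        labels, _ = assign_bins(times, n_bins=8)
        counts = np.bincount(labels, minlength=8)
        assert np.all(counts == 2)

    def test_tie_at_edge_goes_to_lower_bin(self):
        labels, _ = assign_bins([0.0, 1.0, 1.0, 2.0], strategy="fixed-edges", edges=[1.0])
        assert labels.tolist() == [0, 0, 0, 1]

    def test_few_distinct_times_merge_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            labels, cuts = assign_bins([1.0, 1.0, 2.0], n_bins=4)
        assert len(cuts) < 3


class TestPredictionCorrection:
    def test_constant_pred_is_identity(self):
        vals = np.array([1.0, 2.0, 3.0])
        pred = np.array([2.0, 2.0, 2.0])
        out = prediction_correct(vals, pred, np.zeros(3, dtype=int))
        assert np.array_equal(out, vals)

    def test_hand_example(self):
        # record PRED 2.0 in a bin with median PRED 1.0: 4.0 -> 2.0
        vals = np.array([4.0, 1.0, 1.0])
        pred = np.array([2.0, 1.0, 0.5])
        out = prediction_correct(vals, pred, np.zeros(3, dtype=int))
        assert out[0] == pytest.approx(4.0 * 1.0 / 2.0)

    def test_replicate_order_preserved(self):
        sims = np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 3.0]])
        pred = np.array([2.0, 3.0])
        out = prediction_correct(sims, pred, np.zeros(2, dtype=int))
        for j in range(2):
            assert np.array_equal(np.argsort(out[:, j]), np.argsort(sims[:, j]))

    def test_zero_pred_rejected(self):
        with pytest.raises(ValueError):
            prediction_correct(np.ones(2), np.array([1.0, 0.0]), np.zeros(2, dtype=int))


class TestRounding:
    @pytest.mark.parametrize(
        "x, want", [(11.65, 11.7), (4.85, 4.9), (-11.65, -11.7), (0.04, 0.0), (0.05, 0.1)]
    )
    def test_half_away_from_zero(self, x, want):
        assert round_half_away(x, 1) == want

    def test_outside_percentage_bounds(self):
        with pytest.raises(ValueError):
            outside_percentage(5, 0)
        with pytest.raises(ValueError):
            outside_percentage(7, 5)


class TestBands:
    def test_degenerate_ensemble_flags_everything(self, simple_model):
        # no IIV, no residual error: every replicate equals PRED exactly,
        # the band collapses onto PRED and any obs != PRED is outside
        ds = StudyDataset([make_subject(obs_times=(2.0, 9.0))])
        pred = pred_for_dataset(simple_model, ds)
        sims = np.tile(pred, (10, 1))
        obs = pred * 1.5
        res = vpc_bands(obs, ds.subjects[0].obs_times, pred, sims, n_bins=1)
        assert res.n_outside == 2
        res2 = vpc_bands(pred, ds.subjects[0].obs_times, pred, sims, n_bins=1)
        assert res2.n_outside == 0

    def test_correction_disabled_equals_plain_vpc_when_homogeneous(self, simple_model):
        # identical design and covariates: correction factor is exactly 1
        subs = [make_subject(f"S{i}", obs_times=(3.0, 12.0)) for i in range(10)]
        ds = StudyDataset(subs)
        ens = simulate_ensemble(simple_model, ds, K=200, seed=4)
        pred = pred_for_dataset(simple_model, ds)
        rec = ds.observation_records()
        obs = ens.values[0]
        a = vpc_bands(obs, rec["time"].to_numpy(), pred, ens.values, n_bins=2, correct=True)
        b = vpc_bands(obs, rec["time"].to_numpy(), pred, ens.values, n_bins=2, correct=False)
        assert np.array_equal(a.outside, b.outside)
        assert np.allclose(
            a.bin_table[["sim_lo", "sim_hi"]], b.bin_table[["sim_lo", "sim_hi"]]
        )

    def test_band_ordering_invariant(self, parent_met_model):
        subs = [
            make_subject(
                f"S{i}",
                obs_times=(2.0, 8.0),
                analytes=("risperidone", "risperidone"),
            )
            for i in range(6)
        ]
        ds = StudyDataset(subs)
        ens = simulate_ensemble(parent_met_model, ds, K=100, seed=6)
        pred = pred_for_dataset(parent_met_model, ds)
        rec = ds.observation_records()
        res = vpc_bands(ens.values[3], rec["time"].to_numpy(), pred, ens.values, n_bins=2)
        assert np.all(res.bin_table["sim_lo"] <= res.bin_table["sim_hi"])
        # permuting replicates leaves the bands unchanged
        perm = np.random.default_rng(0).permutation(100)
        res2 = vpc_bands(ens.values[3], rec["time"].to_numpy(), pred, ens.values[perm], n_bins=2)
        assert np.allclose(res.bin_table["sim_lo"], res2.bin_table["sim_lo"])
        assert res.n_outside == res2.n_outside

    def test_max_time_drops_late_sample(self, simple_model):
        sub = make_subject(obs_times=(2.0, 8.0, 1200.0))
        ds = StudyDataset([sub])
        ens = simulate_ensemble(simple_model, ds, K=50, seed=2)
        pred = pred_for_dataset(simple_model, ds)
        res = vpc_bands(
            ens.values[0], sub.obs_times, pred, ens.values, n_bins=1, max_time=1000.0
        )
        assert res.n_total == 2
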