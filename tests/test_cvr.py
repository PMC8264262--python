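"""CVR mapping: regressor alignment, voxelwise OLS against an independent
normal-equations oracle, percent-normalization invariances, ROI means and
PET percent differences."""

import dataclasses

import numpy as np
import pytest

from diaschisis.cvr import (
    BoldSeries,
    CO2Trace,
    CvrMap,
    align_co2_to_bold,
    compute_cvr_map,
    pet_percent_difference,
    roi_mean_cvr,
)
from diaschisis.errors import (
    AlignmentError,
    DegenerateStimulusError,
    EmptyRegionError,
    UndefinedRatioError,
)
from diaschisis.phantom import Co2Protocol, realize_subject, render_co2_trace
from diaschisis.regions import REGION_IDS, LabelAtlas

from conftest import TINY_GEOMETRY, tiny_subject_spec


def _series(data, tr_s=2.0):
    return BoldSeries(data=np.asarray(data, dtype=float), tr_s=tr_s, voxel_dims_mm=(3, 3, 3))


def _flat_series(ts):
    return _series(np.asarray(ts, dtype=float)[None, None, None, :])


class TestAlignment:
    def test_identity_resampling_on_shared_time_base(self):
        trace = render_co2_trace(Co2Protocol())
        series = _series(np.zeros((1, 1, 1, 180)))
        reg = align_co2_to_bold(trace, series, delay_s=0.0)
        assert np.array_equal(reg, trace.values_mmHg)

    def test_constant_trace_constant_regressor_any_delay(self):
        trace = CO2Trace(times_s=np.arange(-20.0, 400.0, 2.0), values_mmHg=np.full(210, 40.0))
        series = _series(np.zeros((1, 1, 1, 100)))
        for delay in (-5.0, 0.0, 9.0):
            assert np.all(align_co2_to_bold(trace, series, delay) == 40.0)

    def test_delayed_piecewise_linear_interpolation_matches_hand_values(self):
        # hand interpolation of the shifted trace at volume midpoints
        trace = CO2Trace(
            times_s=np.array([-10.0, 0.0, 10.0, 20.0]),
            values_mmHg=np.array([38.0, 40.0, 46.0, 44.0]),
        )
        series = _series(np.zeros((1, 1, 1, 5)), tr_s=4.0)  # midpoints 2,6,10,14,18
        reg = align_co2_to_bold(trace, series, delay_s=6.0)  # query -4,0,4,8,12
        assert reg == pytest.approx([39.2, 40.0, 42.4, 44.8, 45.6], abs=1e-12)

    def test_coverage_gap_raises(self):
        trace = render_co2_trace(Co2Protocol())
        series = _series(np.zeros((1, 1, 1, 200)))  # longer than the protocol
        with pytest.raises(AlignmentError):
            align_co2_to_bold(trace, series)


class TestComputeCvrMap:
    def test_noiseless_phantom_recovers_true_cvr(self):
        spec = tiny_subject_spec(cvr=0.20, noise_sd=0.0)
        data = realize_subject(spec, TINY_GEOMETRY)
        reg = align_co2_to_bold(data.co2, data.bold)
        cvr = compute_cvr_map(data.bold, reg)
        sel = data.bold_atlas.data > 0
        assert np.all(cvr.valid_mask[sel])
        assert np.max(np.abs(cvr.data[sel] - 0.20)) < 1e-6

    def test_constant_series_gives_zero_cvr(self):
        series = _flat_series(np.full(20, 500.0))
        reg = np.linspace(38, 48, 20)
        cvr = compute_cvr_map(series, reg, background_floor_frac=0.0)
        assert cvr.data[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_gain_invariance(self, rng):
        data = 1000.0 + rng.normal(0, 10, size=(3, 3, 2, 40))
        reg = np.tile([38.0, 48.0], 20)
        a = compute_cvr_map(_series(data), reg)
        b = compute_cvr_map(_series(10.0 * data), reg)
        assert np.allclose(a.data, b.data, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        # brute-force per-voxel least squares on a <=100-voxel instance
        data = 800.0 + rng.normal(0, 25, size=(5, 5, 4, 30))
        reg = 38.0 + 9.4 * (np.arange(30) % 3 == 1) + rng.normal(0, 0.5, 30)
        cvr = compute_cvr_map(_series(data), reg, background_floor_frac=0.0)
        X = np.column_stack([np.ones(30), reg])
        for i in range(5):
            for j in range(5):
                for k in range(4):
                    beta = np.linalg.solve(X.T @ X, X.T @ data[i, j, k])
                    expected = 100.0 * beta[1] / data[i, j, k].mean()
                    assert cvr.data[i, j, k] == pytest.approx(expected, rel=1e-10)

    def test_baseline_epoch_normalization(self):
        # normalizing by the baseline-epoch mean rescales the estimate by the
        # closed-form ratio of baseline-epoch to whole-series signal level
        spec = tiny_subject_spec(cvr=0.20, noise_sd=0.0)
        data = realize_subject(spec, TINY_GEOMETRY)
        reg = align_co2_to_bold(data.co2, data.bold)
        cvr = compute_cvr_map(data.bold, reg, baseline_epoch_s=(0.0, 120.0))
        sel_t = data.bold.volume_midpoints_s() <= 120.0
        expected = 0.20 / (1.0 + 0.20 / 100.0 * (reg[sel_t].mean() - reg.mean()))
        voxels = data.bold_atlas.data > 0
        assert np.max(np.abs(cvr.data[voxels] - expected)) < 1e-9
        # the full-duration epoch reproduces the default normalization
        full = compute_cvr_map(data.bold, reg, baseline_epoch_s=(0.0, 360.0))
        default = compute_cvr_map(data.bold, reg)
        assert np.allclose(full.data, default.data, atol=1e-12)

    def test_zero_variance_regressor_raises(self):
        series = _flat_series(np.arange(10.0))
        with pytest.raises(DegenerateStimulusError):
            compute_cvr_map(series, np.full(10, 40.0))

    def test_background_voxels_masked(self):
        data = np.zeros((2, 1, 1, 10))
        data[0] = 1000.0  # one bright voxel, one background voxel
        reg = np.tile([38.0, 47.0], 5)
        cvr = compute_cvr_map(_series(data), reg)
        assert cvr.valid_mask[0, 0, 0]
        assert not cvr.valid_mask[1, 0, 0]

    def test_roi_mean_unbiased_at_default_noise(self):
        # 50-replicate check: ROI-mean CVR bias under the default noise model
        spec = tiny_subject_spec(cvr=0.20, noise_sd=10.0)
        estimates = []
        for seed in range(50):
            data = realize_subject(dataclasses.replace(spec, seed=seed), TINY_GEOMETRY)
            reg = align_co2_to_bold(data.co2, data.bold)
            cvr = compute_cvr_map(data.bold, reg)
            value, n = roi_mean_cvr(cvr, data.bold_atlas, REGION_IDS["thalamus_L"])
            assert n >= 50
            estimates.append(value)
        assert abs(np.mean(estimates) - 0.20) <= 0.01


class TestRoiMean:
    def _uniform_map(self, value=0.19, shape=(4, 4, 2)):
        return CvrMap(data=np.full(shape, value), valid_mask=np.ones(shape, bool))

    def test_uniform_region(self):
        atlas = LabelAtlas(data=np.ones((4, 4, 2), np.int16), voxel_dims_mm=(3, 3, 3))
        value, n = roi_mean_cvr(self._uniform_map(0.19), atlas, 1)
        assert value == pytest.approx(0.19)
        assert n == 32

    def test_checkerboard_averages_exactly(self):
        data = np.zeros((4, 4, 2))
        data[::2] = 0.1
        data[1::2] = 0.3
        cvr = CvrMap(data=data, valid_mask=np.ones_like(data, bool))
        atlas = LabelAtlas(data=np.ones((4, 4, 2), np.int16), voxel_dims_mm=(3, 3, 3))
        assert roi_mean_cvr(cvr, atlas, 1)[0] == pytest.approx(0.2)

    def test_fully_masked_region_raises(self):
        cvr = CvrMap(data=np.zeros((2, 2, 2)), valid_mask=np.zeros((2, 2, 2), bool))
        atlas = LabelAtlas(data=np.ones((2, 2, 2), np.int16), voxel_dims_mm=(3, 3, 3))
        with pytest.raises(EmptyRegionError):
            roi_mean_cvr(cvr, atlas, 1)


class TestPetPercentDifference:
    def _atlas(self):
        labels = np.zeros((4, 4, 2), np.int16)
        labels[:2] = 3
        return LabelAtlas(data=labels, voxel_dims_mm=(3, 3, 3))

    def test_identical_maps_give_zero(self, rng):
        base = rng.uniform(40, 60, size=(4, 4, 2))
        assert pet_percent_difference(base, base, self._atlas(), 3) == pytest.approx(0.0)

    def test_twenty_percent_increase(self, rng):
        base = rng.uniform(40, 60, size=(4, 4, 2))
        assert pet_percent_difference(base, 1.2 * base, self._atlas(), 3) == pytest.approx(20.0)

    def test_locality_outside_voxels_ignored(self, rng):
        base = rng.uniform(40, 60, size=(4, 4, 2))
        diamox = 1.1 * base
        before = pet_percent_difference(base, diamox, self._atlas(), 3)
        base2, diamox2 = base.copy(), diamox.copy()
        base2[3] = 999.0
        diamox2[3] = -5.0
        assert pet_percent_difference(base2, diamox2, self._atlas(), 3) == pytest.approx(before)

    def test_non_positive_baseline_raises(self):
        base = np.zeros((4, 4, 2))
        with pytest.raises(UndefinedRatioError):
            pet_percent_difference(base, base + 1, self._atlas(), 3)
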