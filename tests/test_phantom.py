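"""Phantom generator: CO2 protocol rendering, rasterization fidelity,
signal-model consistency, cohort composition and determinism."""

import dataclasses
import warnings

import numpy as np
import pytest

from diaschisis.cvr import resample_trace
from diaschisis.errors import GenerationError, InvalidProtocolError, SpecError
from diaschisis.phantom import (
    Co2Protocol,
    CohortSpec,
    RegionSpec,
    SubjectPhantomSpec,
    generate_cohort_specs,
    default_cohort_spec,
    rasterize_atlas,
    rasterize_stroke_mask,
    realize_subject,
    render_co2_trace,
    simulate_bold,
    simulate_perfusion_pair,
)
from diaschisis.regions import REGION_IDS, region_volume, volume_asymmetry_index

from conftest import TINY_GEOMETRY, tiny_subject_spec


class TestCo2Protocol:
    def test_block_protocol_renders_nominal_levels(self):
        # 120 s baseline / 120 s hypercapnia / 120 s baseline at 2 s sampling
        trace = render_co2_trace(Co2Protocol(baseline_mmHg=37.8, step_mmHg=9.4))
        assert trace.times_s.size == 180
        hyper = trace.values_mmHg[(trace.times_s > 120) & (trace.times_s < 240)]
        assert hyper == pytest.approx(47.2)
        assert trace.values_mmHg.min() == pytest.approx(37.8)

    def test_zero_step_gives_constant_trace(self):
        trace = render_co2_trace(Co2Protocol(step_mmHg=0.0))
        assert np.all(trace.values_mmHg == pytest.approx(37.8))

    @pytest.mark.parametrize(
        "blocks",
        [
            (("baseline", 60.0), ("hypercapnia", 120.0)),
            (("baseline", 80.0), ("hypercapnia", 40.0), ("baseline", 100.0)),
            ((35.0, 60.0), (52.0, 30.0)),
        ],
    )
    def test_trace_mean_is_duration_weighted_mean_of_levels(self, blocks):
        proto = Co2Protocol(block_durations_s=blocks, sampling_interval_s=2.0)
        trace = render_co2_trace(proto)
        levels = np.array([proto.level_mmHg(lv) for lv, _ in blocks])
        durations = np.array([d for _, d in blocks])
        expected = float(levels @ durations / durations.sum())
        assert trace.mean() == pytest.approx(expected, abs=1e-12)

    def test_exponential_transition_smoothing_lags_the_step(self):
        sharp = render_co2_trace(Co2Protocol())
        smooth = render_co2_trace(Co2Protocol(transition_tau_s=10.0))
        i = np.searchsorted(sharp.times_s, 121.0)
        assert smooth.values_mmHg[i] < sharp.values_mmHg[i]
        assert smooth.values_mmHg[i + 20] == pytest.approx(47.2, abs=0.2)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(InvalidProtocolError):
            Co2Protocol(sampling_interval_s=0.0)
        with pytest.raises(InvalidProtocolError):
            Co2Protocol(baseline_mmHg=-1.0)
        with pytest.raises(InvalidProtocolError):
            Co2Protocol(block_durations_s=())


class TestRasterization:
    def test_volume_recovered_within_one_voxel_for_random_specs(self, rng):
        # brute-force voxel counting over 50 random ellipsoid specs
        stems = ["peduncle", "thalamus", "cerebellum", "hemisphere"]
        for _ in range(50):
            vol = float(rng.uniform(0.05, 2.5))
            name = f"{stems[rng.integers(4)]}_L"
            centroid = tuple(rng.uniform(25, 45, size=3))
            region = RegionSpec(
                region_id=5, name=name, target_volume_cm3=vol, centroid_mm=centroid
            )
            labels = np.zeros((36, 36, 24), dtype=np.int16)
            from diaschisis.phantom import _select_region_voxels

            idx = _select_region_voxels(region, (36, 36, 24), (2.0, 2.0, 2.0))
            labels[idx] = 5
            voxvol = 8.0 / 1000.0
            recovered = int((labels == 5).sum()) * voxvol
            assert abs(recovered - vol) <= voxvol + 1e-12

    def test_single_voxel_region(self):
        region = RegionSpec(
            region_id=1, name="thalamus_L", target_volume_cm3=0.008, centroid_mm=(30, 30, 20)
        )
        from diaschisis.phantom import _select_region_voxels

        idx = _select_region_voxels(region, (36, 36, 24), (2.0, 2.0, 2.0))
        assert len(idx[0]) == 1

    def test_peduncle_volume_target_at_1mm(self, fixture_specs):
        # healthy left peduncles rasterize to target +/- one 1 mm^3 voxel
        spec = next(s for s in fixture_specs if s.group == "healthy")
        atlas = rasterize_atlas(spec)
        target = spec.region("peduncle_L").target_volume_cm3
        assert abs(region_volume(atlas, REGION_IDS["peduncle_L"]) - target) <= 0.001 + 1e-12

    def test_labels_do_not_overlap_and_stroke_is_separate(self, fixture_specs):
        spec = next(s for s in fixture_specs if s.group == "chronic" and s.has_stroke())
        atlas = rasterize_atlas(spec)
        stroke = rasterize_stroke_mask(spec)
        # one label per voxel by construction; stroke may overlap labels
        assert atlas.data.max() <= max(REGION_IDS.values())
        assert stroke.sum() > 0

    def test_out_of_grid_centroid_raises(self):
        region = RegionSpec(
            region_id=1, name="thalamus_L", target_volume_cm3=0.1, centroid_mm=(500, 30, 20)
        )
        from diaschisis.phantom import _select_region_voxels

        with pytest.raises(GenerationError):
            _select_region_voxels(region, (36, 36, 24), (2.0, 2.0, 2.0))


class TestSimulateBold:
    def test_noiseless_step_gives_exact_fractional_increase(self):
        # cvr 0.2 %/mmHg and a 10 mmHg step -> 2% signal increase base->hyper
        spec = tiny_subject_spec(cvr=0.2, noise_sd=0.0, co2=Co2Protocol(step_mmHg=10.0))
        data = realize_subject(spec, TINY_GEOMETRY)
        sel = data.bold_atlas.mask("thalamus_L")
        ts = data.bold.data[sel][0]
        base = ts[:60].mean()
        hyper = ts[60:120].mean()
        assert (hyper - base) / spec.s0 == pytest.approx(0.02, abs=1e-12)

    def test_zero_cvr_gives_constant_series(self):
        spec = tiny_subject_spec(cvr=0.0, noise_sd=0.0)
        data = realize_subject(spec, TINY_GEOMETRY)
        assert np.ptp(data.bold.data, axis=-1).max() == 0.0  # flat in time everywhere

    def test_same_seed_bit_identical(self):
        spec = tiny_subject_spec(noise_sd=10.0, seed=7)
        a = realize_subject(spec, TINY_GEOMETRY)
        b = realize_subject(spec, TINY_GEOMETRY)
        assert np.array_equal(a.bold.data, b.bold.data)
        assert np.array_equal(a.anat_atlas.data, b.anat_atlas.data)
        assert np.array_equal(a.pet_baseline, b.pet_baseline)

    def test_linear_drift_added_per_volume(self):
        spec = tiny_subject_spec(cvr=0.0, noise_sd=0.0, drift_per_volume=0.5)
        data = realize_subject(spec, TINY_GEOMETRY)
        sel = data.bold_atlas.mask("thalamus_L")
        ts = data.bold.data[sel][0]
        assert np.allclose(np.diff(ts), 0.5, atol=1e-9)


class TestSimulatePerfusion:
    def test_noiseless_unsmoothed_region_mean_is_exact(self):
        spec = tiny_subject_spec(cbf=(50.0, 60.0))
        atlas = rasterize_atlas(spec, TINY_GEOMETRY.anat_shape, TINY_GEOMETRY.anat_voxel_mm)
        base, diamox = simulate_perfusion_pair(atlas, spec, noise_sd=0.0, smoothing_fwhm_mm=0.0)
        sel = atlas.mask("cerebellum_R")
        assert base[sel].mean() == pytest.approx(50.0, abs=1e-12)
        assert diamox[sel].mean() == pytest.approx(60.0, abs=1e-12)

    def test_smoothing_reduces_between_region_contrast_monotonically(self):
        cvrs = {"thalamus_L": 0.2}
        spec = tiny_subject_spec(cvr=cvrs)
        spec = dataclasses.replace(
            spec,
            regions=tuple(
                dataclasses.replace(r, true_cbf_baseline=80.0 if r.name == "thalamus_L" else 20.0)
                for r in spec.regions
            ),
        )
        atlas = rasterize_atlas(spec, TINY_GEOMETRY.anat_shape, TINY_GEOMETRY.anat_voxel_mm)
        gaps = []
        for fwhm in (2.0, 8.0):
            base, _ = simulate_perfusion_pair(atlas, spec, noise_sd=0.0, smoothing_fwhm_mm=fwhm)
            gaps.append(base[atlas.mask("thalamus_L")].mean() - base[atlas.mask("thalamus_R")].mean())
        assert gaps[1] < gaps[0]

    def test_negative_perfusion_rejected(self):
        with pytest.raises(SpecError):
            RegionSpec(
                region_id=3,
                name="thalamus_L",
                target_volume_cm3=0.4,
                centroid_mm=(18, 32, 12),
                true_cbf_baseline=-1.0,
            )


class TestCohortGeneration:
    def test_default_fixture_composition(self, fixture_specs):
        chronic = [s for s in fixture_specs if s.group == "chronic"]
        assert len(chronic) == 17
        assert sum(s.wd_true for s in chronic) == 8
        assert sum(s.itd_true for s in chronic) == 9
        assert sum(s.ccd_true for s in chronic) == 7
        assert sum(s.cst_involved_true for s in chronic if s.wd_true) == 8
        assert len([s for s in fixture_specs if s.group == "acute"]) == 13
        assert len([s for s in fixture_specs if s.group == "healthy"]) == 17

    def test_group_constraints_hold_for_every_subject(self, fixture_specs):
        for s in fixture_specs:
            if s.group == "healthy":
                assert s.stroke_side == "none"
                assert not (s.wd_true or s.itd_true or s.ccd_true)
                assert not s.has_stroke()
            else:
                assert s.stroke_side in ("left", "right")
                assert s.has_stroke()
            if s.wd_true:
                ipsi = "L" if s.stroke_side == "left" else "R"
                contra = "R" if ipsi == "L" else "L"
                ai = volume_asymmetry_index(
                    s.region(f"peduncle_{ipsi}").target_volume_cm3,
                    s.region(f"peduncle_{contra}").target_volume_cm3,
                )
                assert ai < -11.0

    def test_healthy_reference_moments_are_exact(self, fixture_specs):
        # healthy peduncular volume AI has sample mean 1.0 and SD 5.0 exactly
        ais = []
        for s in fixture_specs:
            if s.group == "healthy":
                ais.append(
                    volume_asymmetry_index(
                        s.region("peduncle_L").target_volume_cm3,
                        s.region("peduncle_R").target_volume_cm3,
                    )
                )
        ais = np.array(ais)
        assert ais.mean() == pytest.approx(1.0, abs=1e-9)
        assert ais.std(ddof=1) == pytest.approx(5.0, abs=1e-9)

    def test_empty_chronic_group(self):
        cohort = CohortSpec(n_chronic=0, n_acute=0, n_healthy=4, seed=1)
        specs = generate_cohort_specs(cohort)
        assert len(specs) == 4
        assert all(s.group == "healthy" for s in specs)

    def test_atrophy_coupling_correlation_at_large_n(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cohort = CohortSpec(n_chronic=500, n_acute=0, n_healthy=0, seed=3)
            specs = generate_cohort_specs(cohort)
        ped, thal = [], []
        for s in specs:
            ipsi = "L" if s.stroke_side == "left" else "R"
            contra = "R" if ipsi == "L" else "L"
            ped.append(
                volume_asymmetry_index(
                    s.region(f"peduncle_{ipsi}").target_volume_cm3,
                    s.region(f"peduncle_{contra}").target_volume_cm3,
                )
            )
            thal.append(
                volume_asymmetry_index(
                    s.region(f"thalamus_{ipsi}").target_volume_cm3,
                    s.region(f"thalamus_{contra}").target_volume_cm3,
                )
            )
        r = np.corrcoef(ped, thal)[0, 1]
        assert abs(r - 0.77) <= 0.05

    def test_spec_generation_is_deterministic(self):
        a = generate_cohort_specs(default_cohort_spec())
        b = generate_cohort_specs(default_cohort_spec())
        assert a == b

    def test_non_integer_wd_count_warns(self):
        with pytest.warns(UserWarning):
            generate_cohort_specs(
                CohortSpec(n_chronic=3, n_acute=0, n_healthy=2, wd_fraction=0.5, seed=1)
            )

    def test_healthy_subject_with_stroke_flags_rejected(self):
        spec = tiny_subject_spec()
        with pytest.raises(SpecError):
            dataclasses.replace(spec, wd_true=True)
        with pytest.raises(SpecError):
            dataclasses.replace(spec, stroke_side="left")
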