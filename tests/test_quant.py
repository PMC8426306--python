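"""Unit tests for PET quantification: decay, %ID/g, SUV, LTBR, MLV, HLV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibropet import (VolumeGrid, decay_correct, default_scan_meta,
                      density_gated_uptake, hypoxic_lung_volume,
                      lung_to_background_ratio, metabolic_lung_volume,
                      mlv_threshold, percent_id_per_g, suv, suv_map)
from fibropet.meta import F18_HALF_LIFE_MIN
from fibropet.segmentation import partition_density


def _pet(data, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(data, dtype=np.float32), spacing, "PET")


def _meta(tracer="FDG", dose=5.0, weight=20.0, uptake_min=0.0):
    from datetime import datetime, timedelta
    t0 = datetime(2020, 1, 1, 9, 0)
    from fibropet import ScanMeta
    return ScanMeta("m1", "NaCl", 0, tracer, dose, t0,
                    t0 + timedelta(minutes=uptake_min), weight_g=weight)


class TestDecay:
    @pytest.mark.parametrize("activity,elapsed,half_life,expected", [
        (1.0, F18_HALF_LIFE_MIN, F18_HALF_LIFE_MIN, 2.0),   # one half-life
        (1.0, 0.0, F18_HALF_LIFE_MIN, 1.0),                  # identity
        (4.0, 2 * F18_HALF_LIFE_MIN, F18_HALF_LIFE_MIN, 16.0),  # two half-lives
    ])
    def test_known_values(self, activity, elapsed, half_life, expected):
        assert decay_correct(activity, elapsed, half_life) == pytest.approx(expected, rel=1e-12)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            decay_correct(1.0, -1.0, F18_HALF_LIFE_MIN)
        with pytest.raises(ValueError):
            decay_correct(1.0, 1.0, 0.0)

    @given(st.floats(0.0, 500.0), st.floats(1.0, 500.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_multiplicative_composition(self, t, hl):
        # correcting in two steps equals one step over the summed interval
        one = decay_correct(decay_correct(1.0, t, hl), t, hl)
        assert one == pytest.approx(decay_correct(1.0, 2 * t, hl), rel=1e-9)


class TestPercentIdPerG:
    def test_known_voxel(self):
        # 250 kBq/mL at injection reference, 5 MBq dose -> 5 %ID/g
        pet = _pet(np.full((2, 2, 2), 250.0))
        pid = percent_id_per_g(pet, _meta(dose=5.0, uptake_min=0.0))
        assert pid == pytest.approx(5.0)

    def test_decay_correction_applied(self):
        # measured one half-life after injection: concentration is halved,
        # %ID/g must refer back to injection
        pet = _pet(np.full((2, 2, 2), 125.0))
        pid = percent_id_per_g(pet, _meta(dose=5.0, uptake_min=F18_HALF_LIFE_MIN))
        assert pid == pytest.approx(5.0, rel=1e-6)

    def test_uniform_lung_mean_is_voxel_value(self, rng):
        pet = _pet(np.full((4, 4, 4), 100.0))
        mask = rng.random((4, 4, 4)) > 0.5
        pid = percent_id_per_g(pet, _meta())
        assert pid[mask].mean() == pytest.approx(pid[0, 0, 0])


class TestSUV:
    def test_known_voxel(self):
        # 250 kBq/mL, 5 MBq, 20 g -> SUV 1.0
        pet = _pet(np.full((2, 2, 2), 250.0))
        smap = suv_map(pet, _meta(dose=5.0, weight=20.0))
        assert smap == pytest.approx(1.0)

    def test_algebraic_identity_with_pid(self, rng):
        # SUV = %ID/g * weight / 100 on every voxel, any uptake time
        pet = _pet(rng.random((6, 6, 6)) * 400.0)
        meta = _meta(dose=7.3, weight=23.0, uptake_min=45.0)
        pid = percent_id_per_g(pet, meta)
        smap = suv_map(pet, meta)
        np.testing.assert_allclose(smap, pid * meta.weight_g / 100.0, rtol=1e-6)

    def test_suv_max(self):
        # lung SUVs {0.5, 1.2, 0.9} -> SUVmax 1.2
        pet = _pet(np.array([[[0.5, 1.2, 0.9]]]) * 250.0)
        mask = np.ones((1, 1, 3), dtype=bool)
        _, suv_mean, suv_max = suv(pet, _meta(dose=5.0, weight=20.0), mask)
        assert suv_max == pytest.approx(1.2)
        assert suv_max >= suv_mean >= 0


class TestLTBR:
    def test_known_ratio(self):
        vals = np.zeros((1, 1, 4))
        vals[0, 0, :2] = 2.0
        vals[0, 0, 2:] = 1.0
        lung = np.array([[[True, True, False, False]]])
        bg = ~lung
        assert lung_to_background_ratio(vals, lung, bg) == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        vals = rng.random((4, 4, 4)) + 0.5
        lung = np.zeros((4, 4, 4), bool); lung[:2] = True
        bg = np.zeros((4, 4, 4), bool); bg[3] = True
        r1 = lung_to_background_ratio(vals, lung, bg)
        r2 = lung_to_background_ratio(vals * 37.2, lung, bg)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_errors(self):
        vals = np.ones((2, 2, 2))
        lung = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            lung_to_background_ratio(vals, lung, np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):  # overlap
            lung_to_background_ratio(vals, lung, lung)


class TestMLV:
    def test_threshold_across_animals(self):
        thr = mlv_threshold([0.4, 0.5, 0.6], sd_scope="animal")
        assert thr.baseline_sd == pytest.approx(0.1)
        assert thr.value == pytest.approx(0.7)

    def test_threshold_degenerate_sd(self):
        thr = mlv_threshold([0.5, 0.5], sd_scope="animal")
        assert thr.value == pytest.approx(0.5)

    def test_threshold_needs_two_scans(self):
        with pytest.raises(ValueError):
            mlv_threshold([0.5])

    def test_volume_counting(self):
        suvs = np.array([[[0.5, 0.8, 1.0]]])
        lung = np.ones((1, 1, 3), bool)
        ml, pct = metabolic_lung_volume(suvs, lung, 0.7, voxel_volume_ml=0.008)
        assert ml == pytest.approx(0.016)   # 2 voxels strictly above 0.7
        assert pct == pytest.approx(200.0 / 3.0)

    def test_zero_above_max(self):
        suvs = np.full((2, 2, 2), 0.3)
        ml, pct = metabolic_lung_volume(suvs, np.ones((2, 2, 2), bool), 0.7, 0.008)
        assert ml == 0.0 and pct == 0.0

    @given(st.lists(st.floats(0.0, 3.0), min_size=4, max_size=40))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, vals):
        suvs = np.asarray(vals, dtype=float).reshape(1, 1, -1)
        lung = np.ones_like(suvs, dtype=bool)
        vols = [metabolic_lung_volume(suvs, lung, t, 0.01)[0] for t in (0.5, 1.0, 1.5)]
        assert vols[0] >= vols[1] >= vols[2]


class TestHLV:
    def test_known_ratio_counting(self):
        pet = _pet(np.array([[[1.0, 1.5, 2.0, 1.0, 1.0]]]))
        lung = np.array([[[True, True, True, False, False]]])
        bg = np.array([[[False, False, False, True, True]]])
        ml, pct = hypoxic_lung_volume(pet, _meta(tracer="FMISO"), lung, bg,
                                      multiplier=1.4, voxel_volume_ml=0.001)
        assert ml == pytest.approx(0.002)   # 1.5 and 2.0 are >= 1.4 x background
        assert pct == pytest.approx(200.0 / 3.0)

    def test_uniform_equals_background_is_zero(self):
        pet = _pet(np.ones((2, 2, 4)))
        lung = np.zeros((2, 2, 4), bool); lung[..., :2] = True
        bg = np.zeros((2, 2, 4), bool); bg[..., 2:] = True
        ml, _ = hypoxic_lung_volume(pet, _meta(tracer="FMISO"), lung, bg)
        assert ml == 0.0

    def test_rejected_on_fdg(self):
        pet = _pet(np.ones((2, 2, 2)))
        m = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError, match="FMISO"):
            hypoxic_lung_volume(pet, _meta(tracer="FDG"), m, ~m)

    def test_monotone_in_multiplier(self, rng):
        pet = _pet(rng.random((4, 4, 4)) * 3 + 0.5)
        lung = np.zeros((4, 4, 4), bool); lung[:2] = True
        bg = np.zeros((4, 4, 4), bool); bg[3] = True
        meta = _meta(tracer="FMISO")
        vols = [hypoxic_lung_volume(pet, meta, lung, bg, multiplier=m)[0]
                for m in (1.0, 1.4, 2.0)]
        assert vols[0] >= vols[1] >= vols[2]


class TestDensityGated:
    def test_class_means(self):
        hu = np.array([[[-450.0, -450.0, -50.0, 500.0]]])
        ct = VolumeGrid(hu, (1, 1, 1), "CT")
        mask = np.ones((1, 1, 4), bool)
        part = partition_density(ct, mask)
        pid = np.array([[[1.0, 1.0, 3.0, 9.0]]])
        aer, dense = density_gated_uptake(pid, part)
        assert aer == pytest.approx(1.0)
        assert dense == pytest.approx(3.0)   # 500 HU voxel is out of band

    def test_absent_class_is_missing_not_zero(self):
        hu = np.full((1, 1, 3), -450.0)
        ct = VolumeGrid(hu, (1, 1, 1), "CT")
        part = partition_density(ct, np.ones((1, 1, 3), bool))
        aer, dense = density_gated_uptake(np.ones((1, 1, 3)), part)
        assert aer == pytest.approx(1.0)
        assert dense is None

    def test_grid_mismatch_rejected(self):
        hu = np.full((2, 2, 2), -450.0)
        ct = VolumeGrid(hu, (1, 1, 1), "CT")
        part = partition_density(ct, np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            density_gated_uptake(np.ones((3, 3, 3)), part)
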