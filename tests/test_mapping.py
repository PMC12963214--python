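from collections import deque

import numpy as np
import pytest

from spectherm import (
    Channel,
    ExpansionParams,
    ProbeGeometry,
    SpectralVolume,
    VoxelMask,
    edw_forward,
    fit_polynomial,
    invert_edw,
    segment_zone,
    temperature_map,
    zone_metrics,
)
from spectherm.calibration import expansion_fit_summary


def bfs_flood_fill(binary, seed):
    """Independent 26-neighbourhood flood fill oracle."""
    out = np.zeros_like(binary, dtype=bool)
    if not binary[seed]:
        return out
    q = deque([seed])
    out[seed] = True
    shape = binary.shape
    while q:
        i, j, k = q.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (0 <= ni < shape[0] and 0 <= nj < shape[1]
                            and 0 <= nk < shape[2] and binary[ni, nj, nk]
                            and not out[ni, nj, nk]):
                        out[ni, nj, nk] = True
                        q.append((ni, nj, nk))
    return out


def linear_calibration(slope=-10.9, intercept=1188.0):
    """Exact order-1 calibration via a noiseless fit."""
    edw = np.linspace(98.0, 106.0, 30)
    return fit_polynomial(edw, intercept + slope * edw, 1)


class TestInvertEdw:
    def test_round_trips_forward_model(self, liver_params):
        for T in (37.0, 50.0, 77.0, 99.0):
            edw = edw_forward(liver_params, T)
            assert invert_edw(liver_params, edw) == pytest.approx(T, abs=1e-6)

    def test_out_of_range_edw_is_nan(self, liver_params):
        assert np.isnan(invert_edw(liver_params, 200.0))


class TestTemperatureMap:
    def test_recovers_known_field_through_linear_relation(self, rng):
        field = 37.0 + 60.0 * rng.random((12, 12, 12))
        slope, intercept = -10.9, 1188.0
        edw_data = (field - intercept) / slope  # exact inverse of calibration
        vol = SpectralVolume(Channel.EDW, edw_data, (1, 1, 1))
        mask = VoxelMask(np.ones((12, 12, 12), bool), (1, 1, 1))
        fit = linear_calibration(slope, intercept)
        tmap = temperature_map(vol, fit, mask, extrapolation_margin=10.0)
        np.testing.assert_allclose(tmap.data[tmap.valid], field[tmap.valid], atol=1e-6)
        assert tmap.valid.all()

    def test_edw_103_maps_to_60c(self):
        # linear relation pinned to the treatment-isotherm correspondence
        edw = np.linspace(98.0, 106.0, 20)
        temp = 60.0 - 10.0 * (edw - 103.0)  # EDW 103 % <-> 60 degC
        fit = fit_polynomial(edw, temp, 1)
        vol = SpectralVolume(Channel.EDW, np.full((3, 3, 3), 103.0), (1, 1, 1))
        mask = VoxelMask(np.ones((3, 3, 3), bool), (1, 1, 1))
        tmap = temperature_map(vol, fit, mask)
        assert np.allclose(tmap.data, 60.0, atol=1e-9)

    def test_masked_voxels_are_invalid_nan(self):
        vol = SpectralVolume(Channel.EDW, np.full((4, 4, 4), 103.0), (1, 1, 1))
        mdata = np.ones((4, 4, 4), bool)
        mdata[0, 0, 0] = False
        tmap = temperature_map(vol, linear_calibration(), VoxelMask(mdata, (1, 1, 1)))
        assert np.isnan(tmap.data[0, 0, 0]) and not tmap.valid[0, 0, 0]
        assert np.isfinite(tmap.data[1:]).all()

    def test_out_of_calibration_range_withheld(self):
        data = np.full((3, 3, 3), 103.0)
        data[1, 1, 1] = 90.0  # far below any training EDW
        vol = SpectralVolume(Channel.EDW, data, (1, 1, 1))
        mask = VoxelMask(np.ones((3, 3, 3), bool), (1, 1, 1))
        tmap = temperature_map(vol, linear_calibration(), mask)
        assert not tmap.valid[1, 1, 1]

    def test_expansion_fit_rejected_with_guidance(self, liver_params):
        fit = expansion_fit_summary(liver_params, np.linspace(37, 99, 10),
                                    edw_forward(liver_params, np.linspace(37, 99, 10)))
        vol = SpectralVolume(Channel.EDW, np.full((2, 2, 2), 103.0), (1, 1, 1))
        mask = VoxelMask(np.ones((2, 2, 2), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="invert_edw"):
            temperature_map(vol, fit, mask)


class TestSegmentZone:
    def _vol(self, data, spacing=(1.0, 1.0, 1.0)):
        return SpectralVolume(Channel.EDW, np.asarray(data, float), spacing)

    def test_single_hot_sphere_recovered(self):
        data = np.zeros((15, 15, 15))
        ii, jj, kk = np.indices(data.shape)
        sphere = (ii - 7) ** 2 + (jj - 7) ** 2 + (kk - 7) ** 2 <= 9
        data[sphere] = 80.0
        zone = segment_zone(self._vol(data), 60.0, (7, 7, 7), above=True)
        np.testing.assert_array_equal(zone.data, sphere)

    def test_disjoint_blob_not_included(self):
        data = np.zeros((20, 10, 10))
        data[2:4, 2:4, 2:4] = 80.0
        data[15:18, 2:4, 2:4] = 80.0
        zone = segment_zone(self._vol(data), 60.0, (3, 3, 3), above=True)
        assert zone.data[2:4, 2:4, 2:4].all()
        assert not zone.data[15:18].any()

    def test_matches_bfs_oracle_on_random_fields(self, rng):
        for _ in range(20):
            data = rng.random((10, 10, 10))
            seed_idx = tuple(rng.integers(0, 10, 3))
            thr = 0.5
            zone = segment_zone(self._vol(data), thr, np.array(seed_idx, float),
                                above=True)
            oracle = bfs_flood_fill(data >= thr, seed_idx)
            np.testing.assert_array_equal(zone.data, oracle)

    def test_idempotent_resegmentation(self, rng):
        data = rng.random((10, 10, 10))
        zone = segment_zone(self._vol(data), 0.4, (5.0, 5.0, 5.0), above=True)
        if zone.data.any():
            seed = tuple(np.argwhere(zone.data)[0].astype(float))
            again = segment_zone(self._vol(zone.data.astype(float)), 0.5, seed, above=True)
            np.testing.assert_array_equal(again.data, zone.data)

    def test_monotone_in_threshold(self, rng):
        data = rng.random((10, 10, 10)) + 1.0
        seed = (5.0, 5.0, 5.0)
        strict = segment_zone(self._vol(data), 1.7, seed, above=True)
        loose = segment_zone(self._vol(data), 1.2, seed, above=True)
        if strict.data.any():
            assert np.all(loose.data >= strict.data)

    def test_below_mode_for_edw_thresholding(self):
        data = np.full((8, 8, 8), 105.0)
        data[2:6, 2:6, 2:6] = 100.0  # hot = low electron density
        zone = segment_zone(self._vol(data), 103.0, (3.0, 3.0, 3.0), above=False)
        assert zone.data[2:6, 2:6, 2:6].all() and zone.data.sum() == 64

    def test_cold_seed_warns_and_returns_empty(self):
        data = np.zeros((5, 5, 5))
        with pytest.warns(UserWarning, match="threshold"):
            zone = segment_zone(self._vol(data), 60.0, (2.0, 2.0, 2.0), above=True)
        assert not zone.data.any()

    def test_seed_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            segment_zone(self._vol(np.zeros((5, 5, 5))), 0.0, (50.0, 0.0, 0.0))


class TestZoneMetrics:
    def _probe(self):
        return ProbeGeometry(tip_mm=(20.0, 12.5, 12.5), direction=(1.0, 0.0, 0.0),
                             emitting_offset_mm=0.0)

    def test_single_voxel_volume_conversion(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        zm = zone_metrics(VoxelMask(mask, (1, 1, 1)), None,
                          ProbeGeometry((2, 2, 2), (0, 0, 1), 0.0))
        assert zm.volume_cm3 == pytest.approx(0.001)

    def test_digital_ellipsoid_metrics(self):
        # semi-axes 20 x 12.5 x 12.5 mm at 0.5 mm spacing, probe along x
        spacing = (0.5, 0.5, 0.5)
        shape = (101, 61, 61)
        ii, jj, kk = np.indices(shape)
        x = ii * 0.5 - 25.0
        y = jj * 0.5 - 15.0
        z = kk * 0.5 - 15.0
        ell = (x / 20.0) ** 2 + (y / 12.5) ** 2 + (z / 12.5) ** 2 <= 1.0
        probe = ProbeGeometry(tip_mm=(25.0, 15.0, 15.0), direction=(1, 0, 0),
                              emitting_offset_mm=0.0)
        zm = zone_metrics(VoxelMask(ell, spacing), None, probe)
        analytic_cm3 = 4.0 / 3.0 * np.pi * 20.0 * 12.5**2 / 1000.0
        assert abs(zm.volume_cm3 - analytic_cm3) / analytic_cm3 < 0.03
        assert zm.long_axis_cm == pytest.approx(4.0, abs=0.1)
        assert zm.short_axis_cm == pytest.approx(2.5, abs=0.1)

    def test_sphere_axes_agree_within_a_voxel(self):
        shape = (41, 41, 41)
        ii, jj, kk = np.indices(shape)
        sph = (ii - 20) ** 2 + (jj - 20) ** 2 + (kk - 20) ** 2 <= 15**2
        probe = ProbeGeometry(tip_mm=(20, 20, 20), direction=(0, 0, 1),
                              emitting_offset_mm=0.0)
        zm = zone_metrics(VoxelMask(sph, (1, 1, 1)), None, probe)
        assert abs(zm.long_axis_cm - zm.short_axis_cm) <= 0.1

    def test_mean_hu_within_zone(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:3, 1:3, 1:3] = True
        hu = SpectralVolume(Channel.CONVENTIONAL_HU,
                            np.where(mask, 80.0, 0.0), (1, 1, 1))
        zm = zone_metrics(VoxelMask(mask, (1, 1, 1)), hu,
                          ProbeGeometry((2, 2, 2), (0, 0, 1), 0.0))
        assert zm.mean_hu == pytest.approx(80.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            zone_metrics(VoxelMask(np.zeros((3, 3, 3), bool), (1, 1, 1)), None,
                         ProbeGeometry((0, 0, 0), (0, 0, 1), 0.0))
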