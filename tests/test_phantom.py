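import dataclasses

import numpy as np
import pytest

from spectherm import Channel, PhantomConfig
from spectherm.phantom import (
    artifact_masks,
    generate_study,
    sample_thermocouples,
    simulate_temperature_field,
    subject_configs,
    synthesize_spectral_volumes,
    temperature_at_points,
)


class TestTemperatureField:
    def test_peak_at_emitting_point_end_of_heating(self, small_config):
        emit = small_config.probe.emitting_point_mm
        t_end = small_config.heat_duration_s
        assert temperature_at_points(small_config, emit, t_end)[0] == pytest.approx(
            small_config.t_peak_c
        )

    def test_baseline_far_from_source(self, small_config):
        far = small_config.probe.emitting_point_mm + np.array([500.0, 0, 0])
        t = temperature_at_points(small_config, far, small_config.heat_duration_s)[0]
        assert t == pytest.approx(small_config.t_body_c, abs=1e-9)

    def test_linear_ramp_midpoint(self):
        cfg = PhantomConfig(t_peak_c=99.0, t_body_c=37.0, heat_duration_s=300.0)
        emit = cfg.probe.emitting_point_mm
        assert temperature_at_points(cfg, emit, 150.0)[0] == pytest.approx(68.0)

    def test_negative_time_rejected(self, small_config):
        with pytest.raises(ValueError, match=">= 0"):
            simulate_temperature_field(small_config, -1.0)

    def test_decay_after_heating(self, small_config):
        emit = small_config.probe.emitting_point_mm
        t_end = small_config.heat_duration_s
        later = [temperature_at_points(small_config, emit, t_end + dt)[0]
                 for dt in (0.0, 60.0, 300.0)]
        assert later[0] > later[1] > later[2] > small_config.t_body_c

    def test_radially_non_increasing_along_rays(self, small_config, rng):
        emit = small_config.probe.emitting_point_mm
        for _ in range(10):
            ray = rng.normal(size=3)
            ray /= np.linalg.norm(ray)
            radii = np.linspace(0.0, 20.0, 30)
            pts = emit[None, :] + radii[:, None] * ray[None, :]
            temps = temperature_at_points(small_config, pts, 200.0)
            assert np.all(np.diff(temps) <= 1e-12)

    def test_field_bounds_and_grid(self, small_config):
        fld = simulate_temperature_field(small_config, 200.0)
        assert fld.shape == small_config.shape
        assert fld.data.min() >= small_config.t_body_c - 1e-9
        assert fld.data.max() <= small_config.t_peak_c + 1e-9


class TestThermocoupleSampling:
    def test_sensor_at_emitting_point_reads_peak(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            thermocouple_tips_mm=(tuple(small_config.probe.emitting_point_mm),),
        )
        tracks = sample_thermocouples(cfg, [cfg.heat_duration_s], noise_sd_c=0.0)
        assert tracks[0].temps_c[0] == pytest.approx(cfg.t_peak_c)

    def test_symmetric_sensors_read_identically(self, small_config):
        emit = small_config.probe.emitting_point_mm
        cfg = dataclasses.replace(
            small_config,
            thermocouple_tips_mm=(
                tuple(emit + np.array([5.0, 0, 0])),
                tuple(emit - np.array([5.0, 0, 0])),
            ),
        )
        tracks = sample_thermocouples(cfg, np.arange(0.0, 360.0, 60.0), noise_sd_c=0.0)
        np.testing.assert_allclose(tracks[0].temps_c, tracks[1].temps_c)

    def test_distant_sensor_stays_cool(self):
        # 24 mm from the shaft, as the coolest placement in the study design
        cfg = PhantomConfig()
        tracks = sample_thermocouples(cfg, np.arange(0.0, 960.0, 60.0), noise_sd_c=0.0)
        far = tracks[3]  # (36, 12, 35): 24 mm from the shaft
        assert far.temps_c.max() < 50.0

    def test_sensor_outside_grid_named_in_error(self, small_config):
        cfg = dataclasses.replace(
            small_config, thermocouple_tips_mm=((500.0, 0.0, 0.0),)
        )
        with pytest.raises(ValueError, match="tc1"):
            sample_thermocouples(cfg, [0.0])


class TestSpectralSynthesis:
    def _noiseless(self, config):
        return dataclasses.replace(
            config, noise_sd_edw=0, noise_sd_hu=0, noise_sd_zeff=0, noise_sd_vmi=0,
            smooth_sd_edw=0, smooth_sd_hu=0, smooth_sd_zeff=0, gas_bubble_count=0,
        )

    def test_uniform_reference_field_gives_constant_edw(self, small_config):
        cfg = self._noiseless(small_config)
        fld = simulate_temperature_field(cfg, 0.0)  # everything at T_body = T0
        vols = synthesize_spectral_volumes(fld, cfg)
        edw = vols[Channel.EDW].data
        metal, _ = artifact_masks(cfg, fld, np.random.default_rng(0))
        assert np.allclose(edw[~metal], cfg.expansion.edw_t0, atol=1e-5)

    def test_edw_matches_forward_model_at_77c(self, small_config, liver_params):
        # a voxel at 77 degC must read the quadrature value of the expansion model
        cfg = dataclasses.replace(self._noiseless(small_config), expansion=liver_params)
        fld = simulate_temperature_field(cfg, cfg.heat_duration_s)
        fld.data[:] = 77.0
        vols = synthesize_spectral_volumes(fld, cfg)
        metal, _ = artifact_masks(cfg, fld, np.random.default_rng(0))
        got = vols[Channel.EDW].data[~metal]
        assert np.allclose(got, 101.776, atol=5e-3)

    def test_edw_strictly_decreasing_in_temperature(self, small_config):
        cfg = self._noiseless(small_config)
        fld = simulate_temperature_field(cfg, cfg.heat_duration_s)
        vols = synthesize_spectral_volumes(fld, cfg)
        metal, _ = artifact_masks(cfg, fld, np.random.default_rng(0))
        T = fld.data[~metal].ravel()
        E = vols[Channel.EDW].data[~metal].ravel()
        order = np.argsort(T)
        # strictly decreasing wherever temperature strictly increases
        # (threshold clears float32 storage quantisation of the EDW channel)
        dT, dE = np.diff(T[order]), np.diff(E[order].astype(float))
        assert np.all(dE[dT > 1e-2] < 0)

    def test_probe_tube_reads_metal_on_vmi(self, small_config):
        fld = simulate_temperature_field(small_config, 120.0)
        vols = synthesize_spectral_volumes(fld, small_config)
        metal, _ = artifact_masks(small_config, fld, np.random.default_rng(0))
        assert metal.any()
        assert np.all(vols[Channel.VMI70].data[metal] > 80.0)

    def test_mismatched_grids_rejected(self, small_config):
        fld = simulate_temperature_field(small_config, 60.0)
        bad = dataclasses.replace(small_config, shape=(16, 16, 16))
        with pytest.raises(ValueError, match="grid"):
            synthesize_spectral_volumes(fld, bad)

    def test_determinism_under_fixed_seed(self, small_config):
        fld = simulate_temperature_field(small_config, 180.0)
        a = synthesize_spectral_volumes(fld, small_config, np.random.default_rng(5))
        b = synthesize_spectral_volumes(fld, small_config, np.random.default_rng(5))
        for ch in Channel:
            np.testing.assert_array_equal(a[ch].data, b[ch].data)


class TestStudyGeneration:
    def test_default_study_counts(self, small_config):
        # 3 subjects x 16 scans x 4 sensors = 192 candidate pairs
        cfgs = subject_configs(PhantomConfig(), n_subjects=3, seed=0)
        n = sum(len(c.scan_times_s) * len(c.thermocouple_tips_mm) for c in cfgs)
        assert n == 192

    def test_tiny_study_layout_and_pair_count(self, small_config, tmp_path):
        cfg = dataclasses.replace(
            small_config,
            scan_times_s=(0.0, 60.0),
            thermocouple_tips_mm=small_config.thermocouple_tips_mm[:1],
        )
        manifest = generate_study(tmp_path / "s", base_config=cfg, n_subjects=1, seed=3)
        files = sorted(p.name for p in (tmp_path / "s").glob("*.nii.gz"))
        assert len(files) == 2 * 4  # 2 scans x 4 channels
        assert len(manifest["subjects"]["01"]["thermocouple_tips_mm"]) == 1
        n_pairs = len(manifest["subjects"]["01"]["scan_times_s"]) * 1
        assert n_pairs == 2

    def test_same_seed_gives_byte_identical_logs(self, small_config, tmp_path):
        cfg = dataclasses.replace(small_config, scan_times_s=(0.0, 60.0))
        generate_study(tmp_path / "a", base_config=cfg, n_subjects=1, seed=11)
        generate_study(tmp_path / "b", base_config=cfg, n_subjects=1, seed=11)
        la = (tmp_path / "a" / "sub-01_thermolog.csv").read_bytes()
        lb = (tmp_path / "b" / "sub-01_thermolog.csv").read_bytes()
        assert la == lb


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spacing": (1.0, -1.0, 1.0)},
            {"t_peak_c": 30.0},  # below body temperature
            {"heat_duration_s": 0.0},
            {"emitting_offset_mm": -1.0},
            {"noise_sd_edw": -0.5},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs)
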