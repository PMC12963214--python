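"""Synthetic microwave-ablation phantom.

Generates temperature fields, 1 Hz thermocouple logs and co-registered
spectral image stacks with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any acquisition:

* The temperature field is an anisotropic Gaussian centred on the probe's
  emitting point (15 mm proximal to the tip), stretched along the shaft. The
  amplitude ramps linearly to ``T_peak - T_body`` during heating and decays
  exponentially afterwards; the radial width grows linearly while power is
  on. This is deliberately not a bioheat PDE — it is the simplest field with
  the right qualitative shape (hot core, monotone radial falloff, ramp then
  decay) and an exactly evaluable closed form for oracle tests.

* EDW is synthesised voxelwise from the thermal-expansion forward model at
  the local temperature; conventional HU falls weakly (and noisily) with
  temperature; Z-eff rises weakly. Each channel carries white voxel noise
  plus a smooth correlated noise field — the latter is what survives ROI
  averaging, and it is tuned so the rank-correlation ordering
  |rho(EDW)| > |rho(HU)| > rho(Zeff) > 0 emerges rather than being asserted.

* Artifacts: metal-level HU (>> 80) in tubes around the probe shaft and each
  thermocouple wire, and gas-level HU (< 0) bubbles seeded where tissue
  exceeds the vaporisation threshold. Artifact voxels also corrupt the other
  channels, so masking genuinely matters downstream.

Default study: 3 subjects x 16 scans at 1-min intervals x 4 thermocouples
= 192 candidate (sample, temperature) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import io as sio
from .calibration import ExpansionParams, edw_forward
from .core import (
    Channel,
    ProbeGeometry,
    SpectralVolume,
    ThermocoupleTrack,
    grid_bounding_box,
    voxel_centers,
)

DEFAULT_EXPANSION = ExpansionParams(edw_t0=104.0, t0=37.0, b=0.0, c=7.9e-6, d=9.6e-5)

# four sensors spanning the 2.5-24 mm shaft-distance range of a typical
# placement, near the emitting plane (probe tip (36,36,20), shaft +z down)
_DEFAULT_TC = (
    (39.0, 36.0, 35.0),   # 3 mm from shaft
    (36.0, 42.0, 35.0),   # 6 mm
    (48.0, 36.0, 33.0),   # ~12.2 mm
    (36.0, 12.0, 35.0),   # 24 mm
)


@dataclass
class PhantomConfig:
    """Everything needed to generate one subject's synthetic ablation study."""

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.75, 0.75, 1.0)  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    t_body_c: float = 37.0
    t_peak_c: float = 99.0
    heat_duration_s: float = 300.0
    decay_tau_s: float = 240.0
    sigma0_mm: float = 4.0            # radial width at ablation start
    sigma_growth_mm_per_s: float = 0.01
    axial_elongation: float = 1.6     # zone is longer along the shaft
    probe_tip_mm: tuple[float, float, float] = (36.0, 36.0, 20.0)
    probe_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    emitting_offset_mm: float = 15.0
    thermocouple_tips_mm: tuple = _DEFAULT_TC
    scan_times_s: tuple = tuple(60.0 * i for i in range(16))
    expansion: ExpansionParams = field(default_factory=lambda: DEFAULT_EXPANSION)
    sensor_noise_sd_c: float = 1.0    # from the +/-2 degC calibration tolerance
    # voxel-level white noise per channel
    noise_sd_edw: float = 1.5
    noise_sd_hu: float = 12.0
    noise_sd_zeff: float = 0.3
    noise_sd_vmi: float = 8.0
    # smooth correlated noise (survives ROI averaging); SD after filtering
    smooth_sd_edw: float = 0.5
    smooth_sd_hu: float = 10.0
    smooth_sd_zeff: float = 0.15
    smooth_sigma_vox: float = 6.0
    # channel baselines / temperature sensitivities
    hu_baseline: float = 55.0
    hu_slope_per_c: float = -0.25
    zeff_baseline: float = 7.8
    zeff_slope_per_c: float = 0.002
    vmi_baseline_hu: float = 55.0
    # artifacts
    metal_radius_mm: float = 1.5
    metal_hu: float = 900.0
    tc_wire_length_mm: float = 12.0
    tc_wire_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gas_bubble_count: int = 5
    gas_bubble_radius_mm: float = 1.5
    gas_hu: float = -400.0
    gas_seed_threshold_c: float = 90.0  # vaporisation happens near the probe
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive on all axes")
        if self.t_peak_c <= self.t_body_c:
            raise ValueError("T_peak must exceed T_body")
        if self.heat_duration_s <= 0:
            raise ValueError("heating duration must be positive")
        if self.emitting_offset_mm < 0:
            raise ValueError("emitting-point offset must be >= 0")
        for name in ("sensor_noise_sd_c", "noise_sd_edw", "noise_sd_hu",
                     "noise_sd_zeff", "noise_sd_vmi", "smooth_sd_edw",
                     "smooth_sd_hu", "smooth_sd_zeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def probe(self) -> ProbeGeometry:
        d = np.asarray(self.probe_direction, float)
        return ProbeGeometry(
            tip_mm=np.asarray(self.probe_tip_mm, float),
            direction=d / np.linalg.norm(d),
            emitting_offset_mm=self.emitting_offset_mm,
        )


@dataclass
class TemperatureField:
    """A simulated temperature grid at one instant."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    time_s: float

    @property
    def shape(self):
        return self.data.shape


def _delta_t(config: PhantomConfig, t: float) -> float:
    amp = config.t_peak_c - config.t_body_c
    if t <= config.heat_duration_s:
        return amp * t / config.heat_duration_s
    return amp * float(np.exp(-(t - config.heat_duration_s) / config.decay_tau_s))


def _sigma(config: PhantomConfig, t: float) -> float:
    return config.sigma0_mm + config.sigma_growth_mm_per_s * min(t, config.heat_duration_s)


def temperature_at_points(config: PhantomConfig, points_mm: np.ndarray, t: float) -> np.ndarray:
    """Exact field value at arbitrary world points (mm) at time t (s)."""
    if t < 0:
        raise ValueError("time must be >= 0")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    probe = config.probe
    v = pts - probe.emitting_point_mm
    axial = v @ probe.direction
    perp2 = np.einsum("ij,ij->i", v, v) - axial**2
    rho2 = perp2 + (axial / config.axial_elongation) ** 2
    sig = _sigma(config, t)
    return config.t_body_c + _delta_t(config, t) * np.exp(-rho2 / (2.0 * sig**2))


def simulate_temperature_field(config: PhantomConfig, t: float) -> TemperatureField:
    """Deterministic anisotropic-Gaussian temperature field at time t."""
    if t < 0:
        raise ValueError("time must be >= 0")
    xs, ys, zs = voxel_centers(config.shape, config.spacing, config.origin)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    temps = temperature_at_points(config, pts, t).reshape(config.shape)
    return TemperatureField(
        data=temps, spacing=config.spacing, origin=config.origin, time_s=t
    )


def sample_thermocouples(config: PhantomConfig, times_s, rng=None,
                         noise_sd_c: float | None = None) -> list[ThermocoupleTrack]:
    """Thermocouple logs: exact field value at each tip plus sensor noise.

    Sensor noise defaults to the configured SD (1 degC, from the +/- 2 degC
    calibration tolerance); pass ``noise_sd_c=0`` for noiseless logs.
    """
    times = np.asarray(times_s, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = config.sensor_noise_sd_c if noise_sd_c is None else noise_sd_c
    lo, hi = grid_bounding_box(config.shape, config.spacing, config.origin)
    tracks = []
    for i, tip in enumerate(config.thermocouple_tips_mm):
        tip = np.asarray(tip, float)
        if np.any(tip < lo) or np.any(tip > hi):
            raise ValueError(f"thermocouple tc{i + 1} tip {tuple(tip)} lies outside the grid")
        temps = np.array([temperature_at_points(config, tip, t)[0] for t in times])
        if sd > 0:
            temps = temps + rng.normal(0.0, sd, size=temps.shape)
        temps = np.clip(temps, 0.0, 120.0)
        tracks.append(
            ThermocoupleTrack(sensor_id=f"tc{i + 1}", tip_mm=tip,
                              times_s=times, temps_c=temps)
        )
    return tracks


def _smooth_noise(rng, shape, sigma_vox, sd) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    s = raw.std()
    return raw * (sd / s) if s > 0 else raw


def _tube_mask(shape, spacing, origin, p0, direction, length, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0 + s*direction, s in [0, length]."""
    xs, ys, zs = voxel_centers(shape, spacing, origin)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    v = np.stack([gx - p0[0], gy - p0[1], gz - p0[2]], axis=-1)
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    s = v @ u
    s_cl = np.clip(s, 0.0, length)
    d2 = np.einsum("...i,...i->...", v, v) - 2 * s_cl * s + s_cl**2
    return d2 <= radius**2


def artifact_masks(config: PhantomConfig, field: TemperatureField, rng):
    """Metal tube(s) and gas-bubble voxel masks for one timepoint."""
    probe = config.probe
    # probe shaft: from the tip back toward the entry, long enough to exit the grid
    shaft_len = float(np.linalg.norm(np.asarray(config.shape) * np.asarray(config.spacing)))
    metal = _tube_mask(field.shape, field.spacing, field.origin,
                       probe.tip_mm, -probe.direction, shaft_len, config.metal_radius_mm)
    for tip in config.thermocouple_tips_mm:
        metal |= _tube_mask(field.shape, field.spacing, field.origin,
                            np.asarray(tip, float), config.tc_wire_direction,
                            config.tc_wire_length_mm, config.metal_radius_mm)
    gas = np.zeros(field.shape, dtype=bool)
    hot = np.argwhere(field.data > config.gas_seed_threshold_c)
    if hot.size and config.gas_bubble_count > 0:
        picks = hot[rng.integers(0, hot.shape[0], size=config.gas_bubble_count)]
        xs, ys, zs = voxel_centers(field.shape, field.spacing, field.origin)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        for idx in picks:
            c = np.array([xs[idx[0]], ys[idx[1]], zs[idx[2]]])
            d2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
            gas |= d2 <= config.gas_bubble_radius_mm**2
    return metal, gas


def synthesize_spectral_volumes(field: TemperatureField, config: PhantomConfig,
                                rng=None, scan_index: int = 0) -> dict:
    """Four co-registered spectral channels for one temperature field.

    Returns ``{Channel: SpectralVolume}`` sharing the field's geometry.
    """
    if tuple(field.shape) != tuple(config.shape) or tuple(field.spacing) != tuple(config.spacing):
        raise ValueError("temperature field grid does not match the phantom config grid")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = field.data
    dT = T - config.t_body_c
    shape = field.shape

    edw = edw_forward(config.expansion, T)
    edw = edw + _smooth_noise(rng, shape, config.smooth_sigma_vox, config.smooth_sd_edw)
    if config.noise_sd_edw > 0:
        edw = edw + rng.normal(0.0, config.noise_sd_edw, shape)

    hu = config.hu_baseline + config.hu_slope_per_c * dT
    hu = hu + _smooth_noise(rng, shape, config.smooth_sigma_vox, config.smooth_sd_hu)
    if config.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, config.noise_sd_hu, shape)

    zeff = config.zeff_baseline + config.zeff_slope_per_c * dT
    zeff = zeff + _smooth_noise(rng, shape, config.smooth_sigma_vox, config.smooth_sd_zeff)
    if config.noise_sd_zeff > 0:
        zeff = zeff + rng.normal(0.0, config.noise_sd_zeff, shape)

    vmi = np.full(shape, config.vmi_baseline_hu, dtype=float)
    if config.noise_sd_vmi > 0:
        vmi = vmi + rng.normal(0.0, config.noise_sd_vmi, shape)

    metal, gas = artifact_masks(config, field, rng)
    vmi[metal] = config.metal_hu
    vmi[gas] = config.gas_hu
    # artifacts corrupt the quantitative channels too — that is why masking exists
    edw[metal] += 8.0
    edw[gas] -= 8.0
    hu[metal] += 300.0
    hu[gas] -= 200.0
    zeff[metal] += 2.0
    zeff[gas] -= 1.0

    common = dict(spacing=config.spacing, origin=config.origin,
                  scan_index=scan_index, scan_time_s=field.time_s)
    f32 = np.float32  # storage dtype: ample for HU/EDW dynamic range
    return {
        Channel.VMI70: SpectralVolume(channel=Channel.VMI70, data=vmi.astype(f32), **common),
        Channel.CONVENTIONAL_HU: SpectralVolume(
            channel=Channel.CONVENTIONAL_HU, data=hu.astype(f32), **common),
        Channel.ZEFF: SpectralVolume(channel=Channel.ZEFF, data=zeff.astype(f32), **common),
        Channel.EDW: SpectralVolume(channel=Channel.EDW, data=edw.astype(f32), **common),
    }


@dataclass
class SubjectData:
    """In-memory result of generating one subject."""

    subject: str
    config: PhantomConfig
    scans: list  # list of {Channel: SpectralVolume}, one per scan time
    tracks: list


def generate_subject(config: PhantomConfig, subject: str = "01",
                     rng=None) -> SubjectData:
    """Generate one subject's scans and logs in memory (deterministic per rng)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    log_times = np.arange(0.0, max(config.scan_times_s) + 1.0, 1.0)
    tracks = sample_thermocouples(config, log_times, rng=rng)
    scans = []
    for i, t in enumerate(config.scan_times_s):
        fld = simulate_temperature_field(config, t)
        scans.append(synthesize_spectral_volumes(fld, config, rng=rng, scan_index=i))
    return SubjectData(subject=subject, config=config, scans=scans, tracks=tracks)


def subject_configs(base: PhantomConfig, n_subjects: int = 3, seed: int = 0) -> list[PhantomConfig]:
    """Per-subject configs: thermocouple placements jittered a little, as in a
    real study where sensors never land in identical spots twice."""
    rng = np.random.default_rng(seed)
    configs = []
    for s in range(n_subjects):
        jitter = rng.uniform(-1.5, 1.5, size=(len(base.thermocouple_tips_mm), 3))
        tips = tuple(
            tuple(np.asarray(tip, float) + jitter[i])
            for i, tip in enumerate(base.thermocouple_tips_mm)
        )
        configs.append(replace(base, thermocouple_tips_mm=tips, seed=int(seed) + s))
    return configs


def generate_study(out_dir, base_config: PhantomConfig | None = None,
                   n_subjects: int = 3, seed: int = 0) -> dict:
    """Write a full synthetic study to disk; returns the manifest.

    Per subject: one NIfTI per (scan, channel) named
    ``sub-<s>_scan-<t>_<channel>.nii.gz``, a thermocouple CSV log, and a YAML
    manifest recording geometry, scan times, seed and generation parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_config or PhantomConfig()
    configs = subject_configs(base, n_subjects=n_subjects, seed=seed)
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    manifest = {"seed": int(seed), "n_subjects": n_subjects, "subjects": {}}
    for s, (cfg, ss) in enumerate(zip(configs, children), start=1):
        sid = f"{s:02d}"
        data = generate_subject(cfg, subject=sid, rng=np.random.default_rng(ss))
        for scans in data.scans:
            for ch, vol in scans.items():
                sio.write_volume(vol, out_dir / sio.volume_filename(sid, vol.scan_index, ch))
        sio.write_thermolog(data.tracks, out_dir / f"sub-{sid}_thermolog.csv")
        probe = cfg.probe
        manifest["subjects"][sid] = {
            "scan_times_s": [float(t) for t in cfg.scan_times_s],
            "thermocouple_tips_mm": {
                tr.sensor_id: [float(v) for v in tr.tip_mm] for tr in data.tracks
            },
            "probe_tip_mm": [float(v) for v in probe.tip_mm],
            "probe_direction": [float(v) for v in probe.direction],
            "emitting_offset_mm": float(probe.emitting_offset_mm),
            "heat_duration_s": float(cfg.heat_duration_s),
            "t_body_c": float(cfg.t_body_c),
            "t_peak_c": float(cfg.t_peak_c),
            "grid_shape": [int(v) for v in cfg.shape],
            "spacing_mm": [float(v) for v in cfg.spacing],
            "origin_mm": [float(v) for v in cfg.origin],
        }
    sio.write_manifest(manifest, out_dir / "manifest.yaml")
    return manifest
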