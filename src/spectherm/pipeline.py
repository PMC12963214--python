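"""End-to-end run: generate/load -> mask -> extract -> calibrate -> diagnose -> map.

A run is reproducible from (config, seed): the top-level seed fans out into
per-stage child seeds through ``numpy.random.SeedSequence`` so stages can be
re-run in isolation, and every output file records the seed it came from.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .calibration import (
    expansion_fit_summary,
    fit_expansion,
    fit_polynomial,
    kfold_rmse,
    spearman,
)
from .core import Channel, ProbeGeometry, SpectralVolume
from .diagnostics import breusch_pagan, probe_distances, raw_errors
from .masking import MaskConfig, validity_mask
from .mapping import masked_smooth, segment_zone, temperature_map, zone_metrics
from .phantom import PhantomConfig, generate_study
from .roi import extract_roi_sample, pair_samples

log = logging.getLogger("spectherm")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "from-files"
    data_dir: str | None = None  # required in from-files mode
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_subjects: int = 3
    mask: MaskConfig = field(default_factory=MaskConfig)
    roi_radius_mm: float = 3.0
    poly_orders: tuple = (1, 2, 3, 4)
    cv_folds: int = 5
    seed: int = 0
    out_dir: str = "run_out"
    write_maps: bool = True
    map_scan_time_s: float = 300.0  # scan used for zone segmentation (end of heating)
    zone_threshold_c: float = 60.0  # irreversible-damage isotherm
    zone_seed_offset_mm: float = 4.0  # radial offset of the segmentation seed
                                      # (the emitting point itself is metal-masked)
    map_smooth_sigma_mm: float = 2.0  # mask-aware EDW smoothing before mapping

    def __post_init__(self):
        if self.mode not in ("synthetic", "from-files"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "from-files" and not self.data_dir:
            raise ValueError("from-files mode needs data_dir")


def _load_study(data_dir: Path):
    """Read a study directory (manifest + volumes + logs) into memory."""
    manifest = sio.read_manifest(data_dir / "manifest.yaml")
    study = {}
    for sid, meta in manifest["subjects"].items():
        tips = {k: np.asarray(v, float) for k, v in meta["thermocouple_tips_mm"].items()}
        tracks = sio.read_thermolog(data_dir / f"sub-{sid}_thermolog.csv", tip_positions=tips)
        scans = []
        for i, t in enumerate(meta["scan_times_s"]):
            chans = {}
            for ch in Channel:
                p = data_dir / sio.volume_filename(sid, i, ch)
                if not p.exists():
                    raise FileNotFoundError(
                        f"subject {sid}, scan {i}: missing channel file {p.name}"
                    )
                chans[ch] = sio.read_volume(p, channel=ch, scan_index=i, scan_time_s=float(t))
            scans.append(chans)
        probe = ProbeGeometry(
            tip_mm=np.asarray(meta["probe_tip_mm"], float),
            direction=np.asarray(meta["probe_direction"], float),
            emitting_offset_mm=float(meta["emitting_offset_mm"]),
        )
        study[sid] = {"meta": meta, "tracks": tracks, "scans": scans, "probe": probe}
    return manifest, study


def extract_samples(study, mask_config: MaskConfig, roi_radius_mm: float) -> pd.DataFrame:
    """Mask every scan, extract per-sensor ROIs and pair with temperatures."""
    frames = []
    n_excluded = 0
    for sid, sub in study.items():
        dists = probe_distances(
            {tr.sensor_id: tr.tip_mm for tr in sub["tracks"]}, sub["probe"]
        )
        samples = []
        for chans in sub["scans"]:
            mask = validity_mask(chans[Channel.VMI70], mask_config)
            for tr in sub["tracks"]:
                s = extract_roi_sample(chans, mask, tr.tip_mm, roi_radius_mm,
                                       tr.sensor_id, chans[Channel.VMI70].scan_index)
                s.subject = sid
                s.d_shaft_mm = float(dists.loc[tr.sensor_id, "d_shaft_mm"])
                s.d_emit_mm = float(dists.loc[tr.sensor_id, "d_emit_mm"])
                s.d_tip_mm = float(dists.loc[tr.sensor_id, "d_tip_mm"])
                samples.append(s)
        n_excluded += sum(s.excluded for s in samples)
        frames.append(pair_samples(samples, sub["tracks"]))
    df = pd.concat(frames, ignore_index=True)
    df.attrs["n_candidates"] = int(df.shape[0] + n_excluded)
    df.attrs["n_excluded"] = int(n_excluded)
    return df


def calibrate(df: pd.DataFrame, poly_orders=(1, 2, 3, 4), cv_folds: int = 5,
              seed: int = 0, t0_c: float = 37.0) -> dict:
    """Correlations, polynomial fits (+CV) and the expansion-model fit."""
    temp = df["temp_c"].to_numpy()
    edw = df["edw_mean"].to_numpy()
    out = {
        "correlations": {
            "edw": spearman(temp, edw),
            "zeff": spearman(temp, df["zeff_mean"].to_numpy()),
            "hu": spearman(temp, df["hu_mean"].to_numpy()),
        },
        "poly_fits": {},
        "cv_rmse_c": {},
    }
    for order in poly_orders:
        out["poly_fits"][order] = fit_polynomial(edw, temp, order)
        out["cv_rmse_c"][order] = kfold_rmse(edw, temp, order, k=cv_folds, seed=seed)
    params = fit_expansion(temp, edw, t0=t0_c, fix_b=True)
    out["expansion"] = expansion_fit_summary(params, temp, edw)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write outputs under ``config.out_dir``; return report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"seed": int(config.seed), "mode": config.mode, "stages": {}}
    t_start = time.perf_counter()

    def stage(name):
        report["stages"][name] = {"t_s": round(time.perf_counter() - t_start, 3)}
        log.info("stage %s done at %.1fs", name, time.perf_counter() - t_start)

    # --- generate or load -------------------------------------------------
    if config.mode == "synthetic":
        data_dir = out / "data"
        generate_study(data_dir, base_config=config.phantom,
                       n_subjects=config.n_subjects, seed=config.seed)
    else:
        data_dir = Path(config.data_dir)
    manifest, study = _load_study(data_dir)
    stage("generate/load")

    # --- mask + extract + pair -------------------------------------------
    df = extract_samples(study, config.mask, config.roi_radius_mm)
    df.to_csv(out / "samples.csv", index=False)
    report["n_candidates"] = df.attrs["n_candidates"]
    report["n_excluded"] = df.attrs["n_excluded"]
    report["n_paired"] = int(df.shape[0])
    report["mean_roi_edw"] = float(df["edw_mean"].mean())
    report["mean_roi_voxels"] = float(df["n_voxels"].mean())
    report["mean_roi_vol_mm3"] = float(df["vol_mm3"].mean())
    stage("extract")

    # --- calibrate --------------------------------------------------------
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    cal = calibrate(df, poly_orders=config.poly_orders, cv_folds=config.cv_folds,
                    seed=int(seeds[0] % (2**31)),
                    t0_c=config.phantom.t_body_c)
    report["correlations"] = {
        k: {"rho": v.rho, "p": v.p_value, "ci": [v.ci_low, v.ci_high], "n": v.n}
        for k, v in cal["correlations"].items()
    }
    report["poly_fits"] = {k: f.to_dict() for k, f in cal["poly_fits"].items()}
    report["cv_rmse_c"] = {k: float(v) for k, v in cal["cv_rmse_c"].items()}
    report["expansion_fit"] = cal["expansion"].to_dict()
    with open(out / "fits.yaml", "w") as fh:
        yaml.safe_dump({"seed": int(config.seed),
                        "poly_fits": report["poly_fits"],
                        "cv_rmse_c": report["cv_rmse_c"],
                        "expansion_fit": report["expansion_fit"]},
                       fh, sort_keys=True)
    stage("calibrate")

    # --- residual diagnostics ---------------------------------------------
    # headline calibration for residuals/maps is the linear EDW-temperature fit
    linear = cal["poly_fits"].get(1) or fit_polynomial(
        df["edw_mean"].to_numpy(), df["temp_c"].to_numpy(), 1
    )
    first_meta = next(iter(study.values()))["meta"]
    scan_times = {i: float(t) for i, t in enumerate(first_meta["scan_times_s"])}
    heat_window = (0.0, float(first_meta.get("heat_duration_s", 300.0)))
    resid_df = raw_errors(linear, df, heating_window_s=heat_window,
                          scan_times_s=scan_times)
    bp = breusch_pagan(resid_df["raw_error_c"].to_numpy(),
                       resid_df["d_emit_mm"].to_numpy())
    err_corr = spearman(resid_df["raw_error_c"].to_numpy(),
                        resid_df["d_emit_mm"].to_numpy())
    report["diagnostics"] = {
        "mean_raw_error_c": float(resid_df["raw_error_c"].mean()),
        "breusch_pagan": {"lm": bp.lm, "lm_p": bp.lm_p_value, "f": bp.f,
                          "f_p": bp.f_p_value, "n": bp.n, "aux_slope": bp.aux_slope},
        "error_vs_distance": {"rho": err_corr.rho, "p": err_corr.p_value},
    }
    resid_df.to_csv(out / "residuals.csv", index=False)
    stage("diagnose")

    # --- thermometry maps + zone metrics ----------------------------------
    zones = {}
    if config.write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for sid, sub in study.items():
            times = [float(t) for t in sub["meta"]["scan_times_s"]]
            i_zone = int(np.argmin(np.abs(np.asarray(times) - config.map_scan_time_s)))
            zone_map = None
            for i_map, chans in enumerate(sub["scans"]):
                mask = validity_mask(chans[Channel.VMI70], config.mask)
                tmap = temperature_map(chans[Channel.EDW], linear, mask,
                                       smooth_sigma_mm=config.map_smooth_sigma_mm)
                if i_map == i_zone:
                    zone_map = tmap
                sio.write_volume(
                    # reuse the NIfTI writer through a SpectralVolume shell
                    SpectralVolume(channel=Channel.EDW,
                                   data=tmap.data.astype(np.float32),
                                   spacing=tmap.spacing, origin=tmap.origin,
                                   scan_index=i_map, scan_time_s=times[i_map]),
                    maps_dir / f"sub-{sid}_scan-{i_map:02d}_tempmap.nii.gz",
                )
            i_map, chans = i_zone, sub["scans"][i_zone]
            try:
                # seed just off the shaft: the emitting point itself sits in
                # the metal artifact and is therefore always mask-invalid
                u = sub["probe"].direction
                e1 = np.zeros(3)
                e1[int(np.argmin(np.abs(u)))] = 1.0
                e1 = e1 - (e1 @ u) * u
                e1 /= np.linalg.norm(e1)
                seed_pt = sub["probe"].emitting_point_mm + config.zone_seed_offset_mm * e1
                # segment on smoothed EDW at the level the calibration maps to
                # the treatment isotherm: the hottest voxels read below the
                # calibration span (the temperature map withholds them) but
                # low EDW = hot, so they certainly belong to the zone.
                # Artifact voxels take their mask-aware smoothed fill values.
                c0, c1 = linear.coefficients  # order-1: T = c0 + c1*EDW
                edw_thr = (config.zone_threshold_c - c0) / c1
                mask = validity_mask(chans[Channel.VMI70], config.mask)
                sigma_vox = config.map_smooth_sigma_mm / np.asarray(chans[Channel.EDW].spacing)
                sm = masked_smooth(np.asarray(chans[Channel.EDW].data, float),
                                   mask.data, sigma_vox)
                zone_vol = SpectralVolume(channel=Channel.EDW, data=sm,
                                          spacing=chans[Channel.EDW].spacing,
                                          origin=chans[Channel.EDW].origin)
                zone = segment_zone(zone_vol, edw_thr, seed_pt, above=False)
                zm = zone_metrics(zone, chans[Channel.CONVENTIONAL_HU], sub["probe"])
                zones[sid] = {
                    "volume_cm3": zm.volume_cm3, "long_axis_cm": zm.long_axis_cm,
                    "short_axis_cm": zm.short_axis_cm, "mean_hu": zm.mean_hu,
                    "n_voxels": zm.n_voxels, "scan_idx": i_map,
                }
            except ValueError as exc:
                zones[sid] = {"error": str(exc)}
        report["zones"] = zones
        stage("map")

    report["total_s"] = round(time.perf_counter() - t_start, 3)
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return report
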