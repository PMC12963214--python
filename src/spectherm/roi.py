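"""Spherical ROI extraction at thermocouple tips and temperature pairing.

For each (thermocouple, scan) a 3 mm-radius sphere of voxels is collected
around the sensor tip in world coordinates (anisotropic spacing respected; a
voxel belongs to the sphere when its centre lies within the radius), the
artifact mask is intersected, and per-channel summary statistics are paired
with the sensor's concurrent 1 Hz temperature reading. An ROI left empty by
the mask — a tip fully obscured by metal artifact — is flagged excluded
rather than dropped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Channel, SpectralVolume, VoxelMask, grid_bounding_box, voxel_centers

PAIRED_COLUMNS = [
    "subject", "sensor_id", "scan_idx", "temp_c", "edw_mean", "edw_sd",
    "zeff_mean", "hu_mean", "n_voxels", "vol_mm3",
    "d_shaft_mm", "d_emit_mm", "d_tip_mm", "excluded",
]


@dataclass
class RoiSample:
    """Per-(thermocouple, scan) spectral summary, later paired with temperature."""

    sensor_id: str
    scan_index: int
    scan_time_s: float
    n_voxels: int
    vol_mm3: float
    excluded: bool
    stats: dict = field(default_factory=dict)  # Channel -> (mean, sd)
    temp_c: float | None = None
    subject: str = ""
    d_shaft_mm: float = np.nan
    d_emit_mm: float = np.nan
    d_tip_mm: float = np.nan

    def mean(self, channel: Channel) -> float:
        return self.stats[Channel(channel)][0]

    def sd(self, channel: Channel) -> float:
        return self.stats[Channel(channel)][1]


def sphere_voxels(center_mm, radius_mm: float, shape, spacing, origin=(0.0, 0.0, 0.0)):
    """Indices of voxels whose centres lie within ``radius_mm`` of a point.

    Returns an (N, 3) int array. A centre outside the grid's physical
    bounding box yields an empty set with a warning (the caller decides
    whether that is an exclusion or an error).
    """
    if radius_mm <= 0:
        raise ValueError("sphere radius must be positive")
    center = np.asarray(center_mm, dtype=float).reshape(3)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    lo, hi = grid_bounding_box(shape, spacing, origin)
    if np.any(center < lo) or np.any(center > hi):
        warnings.warn(
            f"ROI centre {tuple(center)} lies outside the grid bounding box",
            stacklevel=2,
        )
        return np.empty((0, 3), dtype=int)
    # candidate index window, then exact distance test on voxel centres
    lo_idx = np.maximum(np.floor((center - radius_mm - origin) / spacing), 0).astype(int)
    hi_idx = np.minimum(
        np.ceil((center + radius_mm - origin) / spacing), np.asarray(shape) - 1
    ).astype(int)
    ranges = [np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)]
    gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
    d2 = (
        (origin[0] + gi * spacing[0] - center[0]) ** 2
        + (origin[1] + gj * spacing[1] - center[1]) ** 2
        + (origin[2] + gk * spacing[2] - center[2]) ** 2
    )
    keep = d2 <= radius_mm**2
    return np.stack([gi[keep], gj[keep], gk[keep]], axis=1)


def extract_roi_sample(channels: dict, mask: VoxelMask, center_mm, radius_mm: float,
                       sensor_id: str, scan_index: int) -> RoiSample:
    """ROI statistics over the sphere intersected with the validity mask.

    ``channels`` maps Channel -> SpectralVolume, all sharing the mask's
    geometry. When the mask wipes out the whole sphere the sample is flagged
    excluded and carries no statistics.
    """
    vols = {Channel(ch): v for ch, v in channels.items()}
    ref = next(iter(vols.values()))
    for v in vols.values():
        if v.data.shape != mask.data.shape or tuple(v.spacing) != tuple(mask.spacing):
            raise ValueError("channel geometry does not match the mask geometry")
    idx = sphere_voxels(center_mm, radius_mm, mask.shape, mask.spacing, mask.origin)
    if idx.shape[0]:
        keep = mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        idx = idx[keep]
    n = int(idx.shape[0])
    voxel_vol = float(np.prod(mask.spacing))
    if n == 0:
        return RoiSample(sensor_id=sensor_id, scan_index=scan_index,
                         scan_time_s=ref.scan_time_s, n_voxels=0, vol_mm3=0.0,
                         excluded=True)
    stats = {}
    for ch, v in vols.items():
        vals = v.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        stats[ch] = (float(vals.mean()), float(vals.std(ddof=0)))
    return RoiSample(sensor_id=sensor_id, scan_index=scan_index,
                     scan_time_s=ref.scan_time_s, n_voxels=n,
                     vol_mm3=n * voxel_vol, excluded=False, stats=stats)


def pair_samples(samples, tracks, drop_excluded: bool = True) -> pd.DataFrame:
    """Attach each sample's concurrent temperature reading; return a table.

    The reading nearest the scan's nominal time is used (logs are 1 Hz and
    the gantry rotation is sub-second, so averaging over the scan would
    change nothing material). A scan time outside a sensor's log raises,
    naming the sensor and scan. Excluded samples are dropped from the
    returned table by default.
    """
    by_id = {tr.sensor_id: tr for tr in tracks}
    rows = []
    for s in samples:
        if s.sensor_id not in by_id:
            raise KeyError(f"no thermocouple log for sensor {s.sensor_id!r}")
        try:
            temp = by_id[s.sensor_id].temperature_at(s.scan_time_s)
        except ValueError as exc:
            raise ValueError(
                f"sensor {s.sensor_id!r}, scan {s.scan_index}: {exc}"
            ) from exc
        s.temp_c = temp
        if s.excluded and drop_excluded:
            continue
        rows.append({
            "subject": s.subject,
            "sensor_id": s.sensor_id,
            "scan_idx": s.scan_index,
            "temp_c": temp,
            "edw_mean": s.mean(Channel.EDW) if not s.excluded else np.nan,
            "edw_sd": s.sd(Channel.EDW) if not s.excluded else np.nan,
            "zeff_mean": s.mean(Channel.ZEFF) if not s.excluded else np.nan,
            "hu_mean": s.mean(Channel.CONVENTIONAL_HU) if not s.excluded else np.nan,
            "n_voxels": s.n_voxels,
            "vol_mm3": s.vol_mm3,
            "d_shaft_mm": s.d_shaft_mm,
            "d_emit_mm": s.d_emit_mm,
            "d_tip_mm": s.d_tip_mm,
            "excluded": s.excluded,
        })
    return pd.DataFrame(rows, columns=PAIRED_COLUMNS)
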