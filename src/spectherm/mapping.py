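"""Voxelwise thermometry maps, isotherm segmentation and zone metrics.

A polynomial calibration maps EDW directly to temperature per voxel; the
thermal-expansion model predicts EDW from temperature, so mapping it the
other way goes through a bisection inversion (EDW is strictly decreasing in
T wherever alpha > 0, so the root is unique).

The treated zone is the 26-connected component at or beyond the treatment
threshold (>= 60 degC on a temperature map, or <= the matching EDW level,
~103 % of water, when thresholding EDW directly) that contains the probe's
emitting point. Zone axes follow standard ablation-zone reporting: the long
axis is the extent of the zone along the probe direction and the short axis
the maximal extent perpendicular to it in the plane through the emitting
point — not PCA axes, so the numbers line up with manufacturer charts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .calibration import CalibrationFit, ExpansionParams, edw_forward
from .core import ProbeGeometry, SpectralVolume, VoxelMask, voxel_centers, world_to_voxel

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TemperatureMap:
    """Voxelwise temperature (degC) with a validity mask."""

    data: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    scan_index: int = 0
    scan_time_s: float = 0.0

    @property
    def shape(self):
        return self.data.shape


@dataclass
class AblationZoneMetrics:
    volume_cm3: float
    long_axis_cm: float
    short_axis_cm: float
    mean_hu: float | None
    n_voxels: int


def invert_edw(params: ExpansionParams, edw, t_lo: float = 0.0, t_hi: float = 120.0):
    """Temperature at which the expansion model predicts the given EDW.

    Bisection (brentq) on the strictly monotone forward model; values outside
    the model's range over [t_lo, t_hi] are returned as NaN.
    """
    scalar = np.isscalar(edw) or np.ndim(edw) == 0
    edw_arr = np.atleast_1d(np.asarray(edw, dtype=float))
    hi_edw = edw_forward(params, t_lo)   # EDW decreasing: max at t_lo
    lo_edw = edw_forward(params, t_hi)
    out = np.full(edw_arr.shape, np.nan)
    ok = (edw_arr >= lo_edw) & (edw_arr <= hi_edw)
    for i in np.ndindex(edw_arr.shape):
        if ok[i]:
            out[i] = optimize.brentq(
                lambda t: edw_forward(params, t) - edw_arr[i], t_lo, t_hi, xtol=1e-10
            )
    return float(out[0]) if scalar else out


def masked_smooth(data: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian smoothing that ignores invalid voxels (normalised convolution).

    Artifact voxels carry corrupted values; plain smoothing would smear them
    into their neighbourhood, so the kernel is renormalised over the valid
    support instead. Voxels with no valid support in kernel reach return NaN.
    """
    m = mask.astype(float)
    num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma=sigma_vox)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-6, num / den, np.nan)
    return out


def temperature_map(edw: SpectralVolume, fit: CalibrationFit, mask: VoxelMask,
                    extrapolation_margin: float = 0.05,
                    smooth_sigma_mm: float = 0.0) -> TemperatureMap:
    """Apply a polynomial calibration voxelwise to an EDW volume.

    Voxels are invalid where the artifact mask excludes them or where EDW
    falls outside the calibration's training span padded by
    ``extrapolation_margin`` (fraction of the span) — thermometry outside
    the fitted range is untrustworthy and is withheld rather than
    extrapolated. ``smooth_sigma_mm > 0`` applies mask-aware Gaussian
    smoothing to EDW first; voxel-level EDW noise converts to tens of degC
    through the calibration slope, so isotherm segmentation needs it.
    """
    if fit.kind != "poly":
        raise ValueError(
            "temperature_map needs an invertible (polynomial) calibration; for an "
            "expansion-model fit use spectherm.mapping.invert_edw (bisection)"
        )
    if edw.data.shape != mask.data.shape:
        raise ValueError("EDW volume and mask shapes differ")
    data = np.asarray(edw.data, dtype=float)
    if smooth_sigma_mm > 0:
        sigma_vox = smooth_sigma_mm / np.asarray(edw.spacing, float)
        data = masked_smooth(data, mask.data, sigma_vox)
    lo, hi = fit.edw_range
    pad = extrapolation_margin * (hi - lo)
    with np.errstate(invalid="ignore"):
        in_range = (data >= lo - pad) & (data <= hi + pad)
    valid = mask.data & in_range & np.isfinite(data)
    temps = fit.predict(data)
    temps = np.where(valid, temps, np.nan)
    return TemperatureMap(data=temps, valid=valid, spacing=edw.spacing,
                          origin=edw.origin, scan_index=edw.scan_index,
                          scan_time_s=edw.scan_time_s)


def segment_zone(volume, threshold: float, seed_point_mm, above: bool = True) -> VoxelMask:
    """26-connected component beyond a threshold containing a seed point.

    ``volume`` is anything with ``data``/``spacing``/``origin`` (a
    TemperatureMap, SpectralVolume or VoxelMask). ``above=True`` keeps voxels
    >= threshold (temperature maps); ``above=False`` keeps <= threshold (EDW
    maps, where hot tissue reads low). A seed that is not itself beyond the
    threshold yields an empty mask with a warning.
    """
    data = np.asarray(volume.data, dtype=float)
    with np.errstate(invalid="ignore"):
        binary = data >= threshold if above else data <= threshold
    binary &= np.isfinite(data)
    seed_idx = np.rint(world_to_voxel(seed_point_mm, volume.spacing, volume.origin)).astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.asarray(data.shape)):
        raise ValueError(f"seed point {tuple(np.asarray(seed_point_mm))} outside the grid")
    if not binary[tuple(seed_idx)]:
        warnings.warn("seed point is not beyond the threshold; returning empty mask",
                      stacklevel=2)
        return VoxelMask(data=np.zeros(data.shape, bool),
                         spacing=volume.spacing, origin=volume.origin)
    labels, _ = ndimage.label(binary, structure=_STRUCT_26)
    zone = labels == labels[tuple(seed_idx)]
    return VoxelMask(data=zone, spacing=volume.spacing, origin=volume.origin)


def _planar_diameter(p2: np.ndarray) -> float:
    """Maximal pairwise distance among 2D points."""
    if p2.shape[0] < 2:
        return 0.0
    if p2.shape[0] > 16:
        try:
            from scipy.spatial import ConvexHull

            p2 = p2[ConvexHull(p2).vertices]
        except Exception:  # degenerate (collinear) clouds: fall through
            pass
    d2 = np.sum((p2[:, None, :] - p2[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def zone_metrics(mask: VoxelMask, hu: SpectralVolume | None,
                 probe: ProbeGeometry) -> AblationZoneMetrics:
    """Volume, probe-aligned axes and mean attenuation of a segmented zone."""
    idx = np.argwhere(mask.data)
    if idx.shape[0] == 0:
        raise ValueError("cannot compute metrics of an empty zone mask")
    spacing = np.asarray(mask.spacing, float)
    origin = np.asarray(mask.origin, float)
    pts = origin + idx * spacing  # voxel centres, world mm
    u = probe.direction
    rel = pts - probe.emitting_point_mm
    axial = rel @ u
    long_mm = float(axial.max() - axial.min())
    # short axis: maximal pairwise perpendicular extent within the slab of
    # voxels crossing the plane through the emitting point
    halfwidth = 0.5 * float(np.max(spacing))
    slab = np.abs(axial) <= halfwidth
    if not np.any(slab):
        short_mm = 0.0
    else:
        perp = rel[slab] - np.outer(axial[slab], u)
        # 2D coordinates in the plane, then diameter via the convex hull
        # (O(n log n) instead of an all-pairs scan)
        e1 = np.zeros(3)
        e1[np.argmin(np.abs(u))] = 1.0
        e1 = e1 - (e1 @ u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        p2 = np.stack([perp @ e1, perp @ e2], axis=1)
        short_mm = _planar_diameter(p2)
    vol_mm3 = idx.shape[0] * float(np.prod(spacing))
    mean_hu = None
    if hu is not None:
        if hu.data.shape != mask.data.shape:
            raise ValueError("HU volume shape does not match the zone mask")
        mean_hu = float(hu.data[mask.data].mean())
    long_cm, short_cm = sorted((long_mm / 10.0, short_mm / 10.0), reverse=True)
    return AblationZoneMetrics(
        volume_cm3=vol_mm3 / 1000.0,
        long_axis_cm=long_cm,
        short_axis_cm=short_cm,
        mean_hu=mean_hu,
        n_voxels=int(idx.shape[0]),
    )
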