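"""Core containers shared across the thermometry pipeline.

World coordinates are millimetres in a right-handed frame; voxel indices are
0-based and a voxel is located at its centre, so voxel (i, j, k) sits at
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Channel(str, Enum):
    """The four spectral results produced per scan."""

    VMI70 = "vmi70"  # 70 keV virtual monoenergetic image (HU), used for masking
    CONVENTIONAL_HU = "hu"  # polychromatic-equivalent attenuation (HU)
    ZEFF = "zeff"  # effective atomic number (atomic units)
    EDW = "edw"  # electron density, % of water


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    return a


@dataclass
class SpectralVolume:
    """One 3D scalar channel on a voxel grid.

    Parameters
    ----------
    channel : Channel
        Which spectral result this grid holds.
    data : ndarray, shape (nx, ny, nz)
        Scalar values; HU channels unbounded, EDW in % of water
        (soft tissue ~90-110).
    spacing : tuple of float
        Voxel edge lengths in mm, strictly positive, per axis.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    scan_index : int
        Position of this scan in the acquisition sequence.
    scan_time_s : float
        Acquisition time in seconds from ablation start.
    """

    channel: Channel
    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_index: int = 0
    scan_time_s: float = 0.0

    def __post_init__(self):
        self.channel = Channel(self.channel)
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"spectral volume must be 3D, got {self.data.ndim}D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal: axis-aligned grid)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VoxelMask:
    """Boolean validity grid sharing geometry with a reference volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim}D data")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ThermocoupleTrack:
    """A temperature sensor: tip position and its 1 Hz reading series.

    Times must be strictly increasing; temperatures are sanity-bounded to
    [0, 120] degC (the probes are calibrated to +/- 2 degC in an ice bath, so
    anything outside that window indicates a corrupt log).
    """

    sensor_id: str
    tip_mm: np.ndarray
    times_s: np.ndarray
    temps_c: np.ndarray

    def __post_init__(self):
        self.tip_mm = _as_point(self.tip_mm)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        if self.times_s.shape != self.temps_c.shape or self.times_s.ndim != 1:
            raise ValueError("times and temperatures must be 1D arrays of equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError(
                f"sensor {self.sensor_id!r}: times must be strictly increasing"
            )
        if self.temps_c.size and (
            self.temps_c.min() < 0.0 or self.temps_c.max() > 120.0
        ):
            raise ValueError(
                f"sensor {self.sensor_id!r}: temperatures outside [0, 120] degC"
            )

    def temperature_at(self, t: float) -> float:
        """Reading nearest to time ``t`` (logs are nominally 1 Hz).

        Raises ``ValueError`` if ``t`` falls outside the logged interval.
        """
        if self.times_s.size == 0:
            raise ValueError(f"sensor {self.sensor_id!r}: empty log")
        if t < self.times_s[0] or t > self.times_s[-1]:
            raise ValueError(
                f"sensor {self.sensor_id!r}: time {t} s outside logged range "
                f"[{self.times_s[0]}, {self.times_s[-1]}] s"
            )
        i = int(np.argmin(np.abs(self.times_s - t)))
        return float(self.temps_c[i])


@dataclass
class ProbeGeometry:
    """Ablation probe line: tip, unit shaft direction and emitting offset.

    ``direction`` points from the skin entry toward the tip; the microwave
    emitting point lies ``emitting_offset_mm`` proximal to the tip, i.e. at
    ``tip - offset * direction``.
    """

    tip_mm: np.ndarray
    direction: np.ndarray
    emitting_offset_mm: float = 15.0

    def __post_init__(self):
        self.tip_mm = _as_point(self.tip_mm)
        self.direction = _as_point(self.direction)
        n = float(np.linalg.norm(self.direction))
        if n == 0.0:
            raise ValueError("probe direction must be non-zero")
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"probe direction must be unit-norm (|v| = {n})")
        self.emitting_offset_mm = float(self.emitting_offset_mm)
        if self.emitting_offset_mm < 0:
            raise ValueError("emitting offset must be >= 0")

    @property
    def emitting_point_mm(self) -> np.ndarray:
        return self.tip_mm - self.emitting_offset_mm * self.direction


def voxel_centers(shape, spacing, origin) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates (mm) of voxel centres, one 1D array per axis."""
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    return tuple(
        origin[a] + spacing[a] * np.arange(shape[a], dtype=float) for a in range(3)
    )


def world_to_voxel(point_mm, spacing, origin) -> np.ndarray:
    """Continuous voxel coordinate of a world point (not rounded)."""
    return (_as_point(point_mm) - np.asarray(origin, float)) / np.asarray(spacing, float)


def grid_bounding_box(shape, spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    """Physical extent of the grid: voxel centres padded by half a voxel."""
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    lo = origin - spacing / 2.0
    hi = origin + (np.asarray(shape, float) - 0.5) * spacing
    return lo, hi
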