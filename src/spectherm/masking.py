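"""Voxel validity masks from the 70 keV VMI.

Metal artifact (probe, thermocouple wires) reads far above soft tissue and
gas bubbles / beam hardening far below, so a voxel is kept only when its
70 keV attenuation lies inside the closed interval
``[gas_threshold, metal_threshold]`` (defaults [0, 80] HU). The exclusion
rules are strict inequalities (> 80 HU metal, < 0 HU gas), hence validity is
boundary-inclusive — this changes counts on exact-boundary data, so it is
fixed here rather than left to float comparison accident.

Masks are computed per scan timepoint: gas forms and artifacts evolve as the
ablation proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Channel, SpectralVolume, VoxelMask


@dataclass
class MaskConfig:
    metal_threshold_hu: float = 80.0
    gas_threshold_hu: float = 0.0
    inclusive: bool = True  # validity boundaries are part of the valid set

    def __post_init__(self):
        if self.metal_threshold_hu <= self.gas_threshold_hu:
            raise ValueError("metal threshold must exceed gas threshold")


def validity_mask(vmi: SpectralVolume, config: MaskConfig | None = None) -> VoxelMask:
    """True where a voxel is artifact-free on the 70 keV VMI."""
    config = config or MaskConfig()
    if vmi.channel is not Channel.VMI70:
        raise ValueError(
            f"validity masks are defined on the 70 keV VMI, got channel {vmi.channel.value!r}"
        )
    d = vmi.data
    if config.inclusive:
        valid = (d >= config.gas_threshold_hu) & (d <= config.metal_threshold_hu)
    else:
        valid = (d > config.gas_threshold_hu) & (d < config.metal_threshold_hu)
    return VoxelMask(data=valid, spacing=vmi.spacing, origin=vmi.origin)


def apply_mask(volume: SpectralVolume, mask: VoxelMask):
    """Values at valid voxels with their indices.

    Returns ``(values, indices)`` where ``indices`` is an (N, 3) int array;
    an all-false mask yields empty arrays, not an error.
    """
    if volume.data.shape != mask.data.shape:
        raise ValueError(
            f"volume shape {volume.data.shape} does not match mask shape {mask.data.shape}"
        )
    idx = np.argwhere(mask.data)
    return volume.data[mask.data], idx
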