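"""Grayscale rendering of binary volumes for segmentation tests."""

from __future__ import annotations

import numpy as np

from ..core import BinaryVolume, VoxelVolume

__all__ = ["add_acquisition_noise"]


def add_acquisition_noise(
    volume: BinaryVolume,
    solid_level: float = 200.0,
    pore_level: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelVolume:
    """Render a two-phase volume as noisy grayscale.

    Each phase gets a constant level plus i.i.d. Gaussian noise, so the
    intensity histogram is a two-Gaussian mixture — the bimodal histogram a
    threshold-based segmentation expects. Pores default to the darker level
    (the "black voxel = void" convention of segmented tomograms).
    """
    if solid_level == pore_level:
        raise ValueError("solid_level and pore_level must differ")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    gray = np.where(volume.data, float(pore_level), float(solid_level))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    return VoxelVolume(gray, volume.grid, kind="grayscale")
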