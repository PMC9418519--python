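"""Shared synthetic fixtures (generated at test time, nothing on disk)."""

from __future__ import annotations

import numpy as np
import pytest

import frustule3d as f3
from frustule3d.synthetic import (
    FrustuleSpec,
    NanoporeFieldSpec,
    frustule_grid,
    generate_frustule,
    generate_nanopore_field,
    generate_primitive,
)


@pytest.fixture(scope="session")
def ball_r20():
    """Digitized ball R=20 vx on a 64^3 grid at 1 nm voxels, with truth."""
    grid = f3.GridSpec((64, 64, 64), 1.0)
    return generate_primitive("ball", grid, center=(32, 32, 32), radius=20)


@pytest.fixture(scope="session")
def nanopore_field():
    """Dilute oriented-ellipsoid field (~170 pores) with ground truth."""
    grid = f3.GridSpec((200, 256, 256), 1.0)
    return generate_nanopore_field(NanoporeFieldSpec(seed=2), grid)


@pytest.fixture(scope="session")
def frustule_fib():
    """Wide-chamber (FIB-SEM-like) 7-chamber valve patch at 25 nm voxels."""
    spec = FrustuleSpec.fib_like(seed=1)
    grid = frustule_grid(spec, voxel_size=25.0)
    volume, truth = generate_frustule(spec, grid)
    return spec, volume, truth


@pytest.fixture(scope="session")
def frustule_chambers(frustule_fib):
    """Watershed chamber labelling of the areola slab of the FIB-like patch."""
    _, volume, truth = frustule_fib
    b_f = truth.layer_boundaries["foramen_areola"]
    b_c = truth.layer_boundaries["areola_cribrum"]
    nz, ny, nx = volume.shape
    areola = volume.crop((b_f, 0, 0), (b_c - b_f, ny, nx))
    labels = f3.watershed_separate(areola, h_min_nm=100.0)
    return areola, labels, truth


@pytest.fixture(scope="session")
def ball_field():
    """Polydisperse smooth-ball field for Porod and (F,P) cloud tests."""
    rng = np.random.default_rng(0)
    shape = (128, 192, 192)
    m = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    for _ in range(30):
        r = rng.uniform(6, 13)
        c = rng.uniform([r + 2] * 3, [s - r - 2 for s in shape])
        m |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
    return f3.BinaryVolume(m, f3.GridSpec(shape, 1.0))
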