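"""Geometric primitives rasterized on a voxel grid.

Voxelization rule: a voxel belongs to the pore phase iff its *centre* lies
inside the continuous shape (centre sampling), which makes the voxel count
an unbiased estimator of the analytic volume and keeps every oracle simple.
All lengths are in voxels unless stated otherwise; physical units enter
only through ``grid.voxel_size``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import BinaryVolume, GridSpec
from .ground_truth import GroundTruth

__all__ = ["generate_primitive"]

_KINDS = ("ball", "ellipsoid", "cylinder", "slab", "hollow_shell", "torus")


def _coords(grid: GridSpec):
    z, y, x = np.ogrid[: grid.shape[0], : grid.shape[1], : grid.shape[2]]
    return z.astype(float), y.astype(float), x.astype(float)


def _check_margin(center, radius_zyx, grid: GridSpec, kind: str) -> None:
    for c, r, n in zip(center, radius_zyx, grid.shape):
        if c - r < 2 or c + r > n - 3:
            raise ValueError(
                f"{kind} with centre {center} and extent {radius_zyx} does not fit "
                f"inside grid {grid.shape} with a 2-voxel margin"
            )


def generate_primitive(kind: str, grid: GridSpec, **geometry):
    """Rasterize a single analytic shape.

    Parameters
    ----------
    kind
        One of ``ball, ellipsoid, cylinder, slab, hollow_shell, torus``.
    grid
        Target grid; the shape must fit with a >= 2-voxel margin
        (except for a slab, which spans the grid cross-section).
    geometry
        Shape parameters in voxel units:

        * ball: ``center=(z,y,x)``, ``radius``
        * ellipsoid: ``center``, ``semi_axes=(az,ay,ax)``
        * cylinder: ``center``, ``radius``, ``length``, ``axis`` (0|1|2)
        * slab: ``axis``, ``start``, ``thickness`` (spans the grid laterally)
        * hollow_shell: ``center``, ``outer_radius``, ``inner_radius``
        * torus: ``center``, ``ring_radius``, ``tube_radius`` (ring in the
          plane normal to ``axis``, default 0)

    Returns
    -------
    (BinaryVolume, GroundTruth)
        Pore phase ``True``; ground truth holds the analytic volume and the
        exact voxel count.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown primitive kind {kind!r}; expected one of {_KINDS}")
    z, y, x = _coords(grid)

    if kind == "ball":
        c, r = geometry["center"], float(geometry["radius"])
        _check_margin(c, (r, r, r), grid, kind)
        mask = (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= r**2
        analytic = 4.0 / 3.0 * np.pi * r**3
        params = {"radius": r}
    elif kind == "ellipsoid":
        c, (az, ay, ax_) = geometry["center"], geometry["semi_axes"]
        _check_margin(c, (az, ay, ax_), grid, kind)
        mask = (
            ((z - c[0]) / az) ** 2 + ((y - c[1]) / ay) ** 2 + ((x - c[2]) / ax_) ** 2
            <= 1.0
        )
        analytic = 4.0 / 3.0 * np.pi * az * ay * ax_
        params = {"semi_axes": (az, ay, ax_)}
    elif kind == "cylinder":
        c, r, length = geometry["center"], float(geometry["radius"]), float(geometry["length"])
        axis = int(geometry.get("axis", 0))
        ext = [r, r, r]
        ext[axis] = length / 2.0
        _check_margin(c, ext, grid, kind)
        coords = (z, y, x)
        lat = [coords[i] - c[i] for i in range(3) if i != axis]
        ax_rel = coords[axis] - c[axis]
        # half-open along the axis so the voxelized length equals `length`
        mask = (lat[0] ** 2 + lat[1] ** 2 <= r**2) & (
            (ax_rel >= -length / 2.0) & (ax_rel < length / 2.0)
        )
        analytic = np.pi * r**2 * length
        params = {"radius": r, "length": length, "axis": axis}
    elif kind == "slab":
        axis = int(geometry.get("axis", 0))
        start, thickness = int(geometry["start"]), int(geometry["thickness"])
        if start < 0 or start + thickness > grid.shape[axis]:
            raise ValueError(
                f"slab [{start}, {start + thickness}) exceeds grid extent "
                f"{grid.shape[axis]} along axis {axis}"
            )
        coords = (z, y, x)
        mask = (coords[axis] >= start) & (coords[axis] < start + thickness)
        mask = np.broadcast_to(mask, grid.shape).copy()
        cross = grid.n_voxels // grid.shape[axis]
        analytic = float(thickness * cross)
        params = {"start": start, "thickness": thickness, "axis": axis}
        c = tuple(s / 2 for s in grid.shape)
    elif kind == "hollow_shell":
        c = geometry["center"]
        ro, ri = float(geometry["outer_radius"]), float(geometry["inner_radius"])
        if not 0 < ri < ro:
            raise ValueError("hollow_shell needs 0 < inner_radius < outer_radius")
        _check_margin(c, (ro, ro, ro), grid, kind)
        d2 = (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2
        mask = (d2 <= ro**2) & (d2 > ri**2)
        analytic = 4.0 / 3.0 * np.pi * (ro**3 - ri**3)
        params = {"outer_radius": ro, "inner_radius": ri}
    else:  # torus
        c = geometry["center"]
        R, r = float(geometry["ring_radius"]), float(geometry["tube_radius"])
        axis = int(geometry.get("axis", 0))
        if not 0 < r < R:
            raise ValueError("torus needs 0 < tube_radius < ring_radius")
        ext = [R + r] * 3
        ext[axis] = r
        _check_margin(c, ext, grid, kind)
        coords = (z, y, x)
        lat = [coords[i] - c[i] for i in range(3) if i != axis]
        rho = np.sqrt(lat[0] ** 2 + lat[1] ** 2)
        mask = (rho - R) ** 2 + (coords[axis] - c[axis]) ** 2 <= r**2
        analytic = 2.0 * np.pi**2 * R * r**2
        params = {"ring_radius": R, "tube_radius": r, "axis": axis}

    mask = np.ascontiguousarray(np.broadcast_to(mask, grid.shape))
    volume = BinaryVolume(mask.copy(), grid)
    objects = pd.DataFrame(
        [
            {
                "object_id": 1,
                "kind": kind,
                "center_z": c[0],
                "center_y": c[1],
                "center_x": c[2],
                "voxel_count": int(mask.sum()),
                "analytic_volume_vx": analytic,
                **{f"param_{k}": str(v) for k, v in params.items()},
            }
        ]
    )
    truth = GroundTruth(objects=objects, meta={"kind": kind, **{k: str(v) for k, v in geometry.items()}})
    return volume, truth
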