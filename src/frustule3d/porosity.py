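"""Scalar and distributional porosity metrics.

Covers the whole metrology chain of a layered porous valve: global and
masked porosity fractions, per-pore volume distributions Prob(v) with
equivalent sizes v^(1/3), layer-boundary detection from solid-fraction
profiles (inflection points), per-layer thicknesses and porosities,
chamber metrology (mid-plane equivalent diameter, height, volume) and the
chamber connectivity graph with throat equivalent diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryVolume, LabeledVolume

__all__ = [
    "porosity_fraction",
    "pore_volume_distribution",
    "PoreVolumeDistribution",
    "equivalent_size",
    "solid_fraction_profile",
    "detect_layer_boundaries",
    "LayerModel",
    "combine_total_porosity",
    "chamber_metrics",
    "connectivity_graph",
    "ConnectivityGraph",
]


def porosity_fraction(binary: BinaryVolume, mask: np.ndarray | None = None) -> float:
    """Pore voxels / total voxels, optionally restricted to a mask."""
    if mask is None:
        return float(binary.data.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != binary.data.shape:
        raise ValueError("mask shape does not match volume shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: porosity undefined")
    return float(binary.data[mask].sum() / n)


@dataclass
class PoreVolumeDistribution:
    """Per-pore volumes and their probability density over log-spaced bins."""

    volumes_nm3: np.ndarray
    bin_edges_nm3: np.ndarray
    density: np.ndarray  # integrates to 1 over the support

    @property
    def count(self) -> int:
        return int(len(self.volumes_nm3))

    @property
    def equivalent_sizes_nm(self) -> np.ndarray:
        return np.cbrt(self.volumes_nm3)


def pore_volume_distribution(
    labels: LabeledVolume, bins_per_decade: int = 10
) -> PoreVolumeDistribution:
    """Prob(v) of individual pore volumes, no shape assumption.

    v = voxel count x voxel_size^3 per label; density over logarithmic
    bins (``bins_per_decade`` per decade) normalized so that the integral
    over v is one.
    """
    if labels.n_labels < 1:
        raise ValueError("no labels: empty pore-volume distribution")
    counts = np.bincount(labels.data.ravel(), minlength=labels.n_labels + 1)[1:]
    counts = counts[counts > 0]
    volumes = counts.astype(float) * labels.grid.voxel_volume
    lo = np.floor(np.log10(volumes.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(volumes.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    edges = 10 ** np.arange(lo, hi + 0.5 / bins_per_decade, 1.0 / bins_per_decade)
    hist, edges = np.histogram(volumes, bins=edges)
    widths = np.diff(edges)
    density = hist / (len(volumes) * widths)
    return PoreVolumeDistribution(volumes, edges, density)


def equivalent_size(v_nm3) -> float | np.ndarray:
    """Characteristic pore size v^(1/3) in nm."""
    v = np.asarray(v_nm3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("pore volume must be > 0")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


def solid_fraction_profile(binary: BinaryVolume, axis: int = 0) -> np.ndarray:
    """Solid fraction per slice along ``axis`` (one value in [0,1] each)."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    other = tuple(a for a in range(3) if a != axis)
    return 1.0 - binary.data.mean(axis=other)


@dataclass
class LayerModel:
    """Layer boundaries and per-layer metrology along one axis."""

    axis: int
    boundaries: list[int]  # slice indices, strictly increasing
    names: list[str]       # one per layer (len(boundaries) + 1)
    thicknesses_nm: list[float]
    porosities: list[float]
    voxel_size: float

    def layer_slices(self, n_slices: int) -> list[tuple[int, int]]:
        cuts = [0, *self.boundaries, n_slices]
        return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]

    def layer_index(self, name: str) -> int:
        return self.names.index(name)


def detect_layer_boundaries(
    binary: BinaryVolume,
    axis: int = 0,
    smoothing_nm: float = 50.0,
    min_jump: float = 0.015,
    names: list[str] | None = None,
) -> LayerModel:
    """Locate layer interfaces at inflection points of the solid profile.

    The per-slice solid fraction is smoothed with a moving average of
    physical width ``smoothing_nm``; boundaries are the sharp extrema of
    its derivative — the zero crossings of the second derivative between
    plateaus. A transition counts as a boundary when a solid-fraction jump
    of at least ``min_jump`` is concentrated within about one smoothing
    window (so abrupt interfaces register while gentle ramps, e.g. a
    tapering chamber wall, do not). Raises ``ValueError`` when no layering
    is detected. With exactly three layers the default names are
    ``foramen, areola, cribrum`` in increasing-z order (internal layer
    first); otherwise layers are numbered.
    """
    from scipy.signal import find_peaks

    profile = solid_fraction_profile(binary, axis)
    n = len(profile)
    if n < 5:
        raise ValueError("profile too short for boundary detection (need >= 5 slices)")
    vs = binary.voxel_size
    win = max(1, int(round(smoothing_nm / vs)))
    kernel = np.ones(win) / win
    padded = np.pad(profile, win, mode="edge")  # no edge dip from zero padding
    smooth = np.convolve(padded, kernel, mode="same")[win:-win]
    d1 = np.gradient(smooth)

    # a step of height J smeared over the window has peak slope ~ J / win
    # (J / 2 for an unsmoothed central difference); demanding that much
    # *prominence* keeps abrupt interfaces and rejects staircase wiggles
    # riding on a gentle ramp
    height = min_jump / max(2, win)
    peaks, _ = find_peaks(
        np.abs(d1), height=height, prominence=height, distance=max(2, win)
    )
    boundaries = [int(p) for p in peaks if 0 < p < n - 1]
    if not boundaries:
        raise ValueError("no layering detected: solid-fraction profile has no inflection")

    cuts = [0, *boundaries, n]
    n_layers = len(cuts) - 1
    if names is None:
        if n_layers == 3:
            names = ["foramen", "areola", "cribrum"]
        else:
            names = [f"layer_{k}" for k in range(n_layers)]
    elif len(names) != n_layers:
        raise ValueError(f"expected {n_layers} names, got {len(names)}")

    thicknesses, porosities = [], []
    sl_all = [slice(None)] * 3
    for a, b in zip(cuts[:-1], cuts[1:]):
        sl_all[axis] = slice(a, b)
        sub = binary.data[tuple(sl_all)]
        thicknesses.append((b - a) * vs)
        porosities.append(float(sub.mean()))
    return LayerModel(axis, boundaries, names, thicknesses, porosities, vs)


def combine_total_porosity(layers: LayerModel) -> float:
    """Thickness-weighted mean of the layer porosities.

    With layers tiling the axis this equals the whole-volume porosity
    exactly (conservation of voxel counts).
    """
    t = np.asarray(layers.thicknesses_nm, dtype=float)
    p = np.asarray(layers.porosities, dtype=float)
    if len(t) < 1:
        raise ValueError("need at least one layer")
    if t.sum() <= 0:
        raise ValueError("zero total thickness")
    return float((t * p).sum() / t.sum())


def chamber_metrics(
    chambers: LabeledVolume,
    layers: LayerModel | None = None,
    mid_slice: int | None = None,
) -> pd.DataFrame:
    """Per-chamber mid-plane equivalent diameter, height and volume.

    The mid-plane is the middle slice of the areola layer (or an explicit
    ``mid_slice``); the equivalent diameter is that of the circle with the
    chamber's mid-plane cross-section area (robust to hexagonal sections).
    Chambers not intersecting the mid-plane are flagged
    (``at_mid_plane=False``) and should be excluded from diameter
    statistics.
    """
    if layers is None and mid_slice is None:
        raise ValueError("need a LayerModel or an explicit mid_slice")
    axis = layers.axis if layers is not None else 0
    nz = chambers.data.shape[axis]
    if mid_slice is None:
        try:
            k = layers.layer_index("areola")
        except ValueError:
            k = int(np.argmax(layers.thicknesses_nm))
        a, b = layers.layer_slices(nz)[k]
        mid_slice = (a + b) // 2
    vs = chambers.voxel_size
    sl = [slice(None)] * 3
    sl[axis] = mid_slice
    mid_plane = chambers.data[tuple(sl)]
    mid_areas = np.bincount(mid_plane.ravel(), minlength=chambers.n_labels + 1)
    counts = np.bincount(chambers.data.ravel(), minlength=chambers.n_labels + 1)

    slices = ndimage.find_objects(chambers.data)
    rows = []
    for lab in range(1, chambers.n_labels + 1):
        slc = slices[lab - 1]
        if slc is None:
            continue
        extent = slc[axis].stop - slc[axis].start
        area = int(mid_areas[lab])
        rows.append(
            {
                "label": lab,
                "mid_diameter_nm": 2.0 * np.sqrt(area / np.pi) * vs if area else np.nan,
                "height_nm": extent * vs,
                "volume_nm3": counts[lab] * vs**3,
                "at_mid_plane": area > 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConnectivityGraph:
    """Chamber adjacency with throat metrology.

    Edges exist between labels whose pore voxels are face-adjacent across
    the watershed boundary; the throat equivalent diameter is that of the
    disc with the contact area.
    """

    nodes: list[int]
    edges: pd.DataFrame  # label_i, label_j, contact_area_nm2, throat_diameter_nm, throat_z_nm

    @property
    def n_edges(self) -> int:
        return int(len(self.edges))


def connectivity_graph(chambers: LabeledVolume, binary: BinaryVolume | None = None) -> ConnectivityGraph:
    """Build the chamber connectivity graph from a watershed labelling."""
    lab = chambers.data
    contacts: dict[tuple[int, int], list] = {}
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        a = lab[tuple(sl_a)]
        b = lab[tuple(sl_b)]
        touch = (a > 0) & (b > 0) & (a != b)
        if not touch.any():
            continue
        ii = np.minimum(a[touch], b[touch])
        jj = np.maximum(a[touch], b[touch])
        idx = np.nonzero(touch)
        z_of_pair = idx[0] + (0.5 if axis == 0 else 0.0)
        for i, j, z in zip(ii, jj, z_of_pair):
            contacts.setdefault((int(i), int(j)), []).append(float(z))
    vs = chambers.voxel_size
    rows = []
    for (i, j), zs in sorted(contacts.items()):
        area = len(zs) * vs**2
        rows.append(
            {
                "label_i": i,
                "label_j": j,
                "contact_area_nm2": area,
                "throat_diameter_nm": 2.0 * np.sqrt(area / np.pi),
                "throat_z_nm": float(np.mean(zs)) * vs,
            }
        )
    edges = pd.DataFrame(
        rows,
        columns=["label_i", "label_j", "contact_area_nm2", "throat_diameter_nm", "throat_z_nm"],
    )
    nodes = list(range(1, chambers.n_labels + 1))
    return ConnectivityGraph(nodes=nodes, edges=edges)
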