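"""Reading and writing voxel volumes.

Supported formats:

* multi-page TIFF stacks (via :mod:`tifffile`), 8-bit for binary volumes
  and 16-bit for grayscale, with the grid metadata in a JSON sidecar
  (``<stem>.json``) written alongside;
* MRC2014 single-volume files (modes 0, 1, 2, 6) with the voxel size taken
  from / written to the cell dimensions of the 1024-byte header;
* raw binary dumps with a mandatory JSON sidecar giving shape, dtype and
  voxel size.

Round trips are bit-identical for integer data. TIFF stacks without a
sidecar or resolution information require an explicit ``voxel_size`` —
there is deliberately no silent default.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import tifffile

from .core import BinaryVolume, GridSpec, LabeledVolume, VoxelVolume

__all__ = ["read_volume", "write_volume", "crop_subvolume"]

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _wrap(data: np.ndarray, grid: GridSpec, kind: str) -> VoxelVolume:
    if kind == "binary":
        return BinaryVolume(data.astype(bool), grid)
    if kind == "labels":
        n = int(data.max()) if data.size else 0
        return LabeledVolume(data.astype(np.int32), grid, n_labels=n)
    return VoxelVolume(data, grid, kind="grayscale")


# ---------------------------------------------------------------------------
# TIFF

def _write_tiff(path: Path, volume: VoxelVolume) -> None:
    data = volume.data
    if volume.kind == "binary":
        data = data.astype(np.uint8) * 255
    elif volume.kind == "labels":
        data = data.astype(np.int32 if volume.data.max() > 65535 else np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "shape": list(volume.grid.shape),
        "voxel_size_nm": volume.grid.voxel_size,
        "origin": list(volume.grid.origin),
        "kind": volume.kind,
        "dtype": str(data.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_tiff(path: Path, voxel_size: float | None) -> VoxelVolume:
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 2:
        data = data[None]
    kind = "grayscale"
    origin = (0, 0, 0)
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if tuple(meta["shape"]) != data.shape:
            raise ValueError(
                f"sidecar shape {meta['shape']} does not match TIFF data shape {list(data.shape)}"
            )
        voxel_size = voxel_size or meta["voxel_size_nm"]
        kind = meta.get("kind", "grayscale")
        origin = tuple(meta.get("origin", (0, 0, 0)))
    if voxel_size is None:
        raise ValueError(
            f"no voxel size: {path} has no JSON sidecar; pass voxel_size explicitly"
        )
    if kind == "binary":
        data = data > 0
    return _wrap(data, GridSpec(data.shape, voxel_size, origin), kind)


# ---------------------------------------------------------------------------
# MRC2014 (minimal: single 3D volume, little-endian, modes 0/1/2/6)

def _write_mrc(path: Path, volume: VoxelVolume) -> None:
    data = volume.data
    if volume.kind == "binary":
        data = data.astype(np.int8)
    elif volume.kind == "labels":
        data = data.astype(np.uint16 if volume.data.max() <= 65535 else np.float32)
    dtype = np.dtype(data.dtype).newbyteorder("<")
    if np.dtype(data.dtype).newbyteorder("=") not in _MRC_MODE_OF:
        data = data.astype(np.float32)
        dtype = np.dtype(np.float32)
    mode = _MRC_MODE_OF[np.dtype(data.dtype).newbyteorder("=")]
    nz, ny, nx = data.shape
    a = volume.grid.voxel_size / 10.0  # MRC cell is conventionally in Å
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)        # NX NY NZ
    struct.pack_into("<i", header, 12, mode)              # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)       # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * a, ny * a, nz * a)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)        # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)          # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])     # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data, dtype=dtype).tobytes())


def _read_mrc(path: Path, voxel_size: float | None) -> VoxelVolume:
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode not in _MRC_MODES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    cella = struct.unpack_from("<3f", raw, 40)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    n = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=n, offset=1024 + nsymbt)
    data = data.reshape(nz, ny, nx).astype(_MRC_MODES[mode])
    if voxel_size is None:
        if cella[0] > 0 and nx > 0:
            voxel_size = cella[0] / nx * 10.0  # Å -> nm
        else:
            raise ValueError(f"{path}: MRC header carries no cell size; pass voxel_size")
    return _wrap(data, GridSpec(data.shape, voxel_size), "grayscale")


# ---------------------------------------------------------------------------
# raw + sidecar

def _write_raw(path: Path, volume: VoxelVolume) -> None:
    data = volume.data
    if volume.kind == "binary":
        data = data.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(np.ascontiguousarray(data).tobytes())
    sidecar = {
        "shape": list(volume.grid.shape),
        "dtype": str(np.asarray(data).dtype),
        "voxel_size_nm": volume.grid.voxel_size,
        "origin": list(volume.grid.origin),
        "kind": volume.kind,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_raw(path: Path, voxel_size: float | None) -> VoxelVolume:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise ValueError(f"raw volume {path} requires a JSON sidecar at {sc}")
    meta = json.loads(sc.read_text())
    for key in ("shape", "dtype"):
        if key not in meta:
            raise ValueError(f"sidecar {sc} missing required field '{key}'")
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta["dtype"])
    expected = int(np.prod(shape)) * dtype.itemsize
    raw = Path(path).read_bytes()
    if len(raw) != expected:
        raise ValueError(
            f"sidecar field 'shape': {shape} with dtype {dtype} implies "
            f"{expected} bytes but file holds {len(raw)}"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(shape).copy()
    vs = voxel_size or meta.get("voxel_size_nm")
    if vs is None:
        raise ValueError(f"sidecar {sc} missing required field 'voxel_size_nm'")
    kind = meta.get("kind", "grayscale")
    if kind == "binary":
        data = data > 0
    return _wrap(data, GridSpec(shape, vs, tuple(meta.get("origin", (0, 0, 0)))), kind)


# ---------------------------------------------------------------------------

def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".mrc", ".map"):
        return "mrc"
    return "raw"


def read_volume(path, format: str | None = None, voxel_size: float | None = None) -> VoxelVolume:
    """Read a volume; format inferred from the extension unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _format_of(path, format)
    if fmt == "tiff":
        return _read_tiff(path, voxel_size)
    if fmt == "mrc":
        return _read_mrc(path, voxel_size)
    if fmt == "raw":
        return _read_raw(path, voxel_size)
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(path, volume: VoxelVolume, format: str | None = None) -> Path:
    """Write a volume; format inferred from the extension unless given."""
    path = Path(path)
    fmt = _format_of(path, format)
    if fmt == "tiff":
        _write_tiff(path, volume)
    elif fmt == "mrc":
        _write_mrc(path, volume)
    elif fmt == "raw":
        _write_raw(path, volume)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def crop_subvolume(volume: VoxelVolume, lower, extents) -> VoxelVolume:
    """Half-open crop ``[lower, lower+extents)`` with provenance in the grid origin."""
    return volume.crop(tuple(lower), tuple(extents))
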