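"""Projection-based 2D spectral density and Porod analysis.

Projecting the pore phase along one axis and Fourier-transforming the
projection gives the 2D small-angle scattering pattern I(qx, qy) of the
structure along that direction (projection-slice theorem); it doubles as a
2D spectral density sensitive to structural anisotropy. Azimuthal sector
averages (default ±15°) along qx and qy give 1D curves I(q); smooth pore
surfaces produce a Porod q^-4 regime at high q whose low-q end q_c maps to
a characteristic real-space distance r = π/q_c (half a spatial period,
with the convention q = 2π × spatial frequency used throughout).

The projection mean is subtracted before the transform (removes the q=0
spike, keeps Parseval exact); an optional Hann window is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryVolume

__all__ = [
    "Projection",
    "SpectralDensity2D",
    "AzimuthalProfile",
    "project_volume",
    "power_spectrum_2d",
    "azimuthal_average",
    "porod_fit",
    "porod_cutoff",
    "characteristic_distance",
]


@dataclass
class Projection:
    """Pore-voxel counts along one axis: P(row, col)."""

    data: np.ndarray
    pixel_size: float  # nm
    axis: int
    depth: int  # voxels integrated over

    @property
    def total_pore_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class SpectralDensity2D:
    """I(q_row, q_col) on centred q grids (nm^-1), q = 2π × frequency."""

    intensity: np.ndarray
    q_row: np.ndarray
    q_col: np.ndarray
    pixel_size: float


@dataclass
class AzimuthalProfile:
    """Sector-averaged 1D spectrum along qx or qy."""

    direction: str  # "qx" (columns) | "qy" (rows)
    half_angle_deg: float
    q: np.ndarray          # bin centres, nm^-1, strictly increasing
    intensity: np.ndarray  # mean I per bin; NaN where the sector bin is empty
    n_pixels: np.ndarray


def project_volume(binary: BinaryVolume, axis: int = 0) -> Projection:
    """Sum the pore phase along ``axis``; pixel value = pore count per ray."""
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    data = binary.data.sum(axis=axis).astype(float)
    return Projection(
        data=data,
        pixel_size=binary.voxel_size,
        axis=axis,
        depth=binary.data.shape[axis],
    )


def power_spectrum_2d(p: Projection, window: str | None = None) -> SpectralDensity2D:
    """Squared-modulus 2D FFT of the mean-subtracted projection.

    ``window='hann'`` applies a separable Hann window first (default none,
    which keeps Parseval's identity Σ I / N = Σ (P - mean)^2 exact).
    """
    data = np.asarray(p.data, dtype=float)
    if data.shape[0] < 4 or data.shape[1] < 4:
        raise ValueError("projection must be at least 4x4 pixels")
    data = data - data.mean()
    if window == "hann":
        wr = np.hanning(data.shape[0])[:, None]
        wc = np.hanning(data.shape[1])[None, :]
        data = data * wr * wc
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    f = np.fft.fftshift(np.fft.fft2(data))
    intensity = np.abs(f) ** 2
    q_row = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(data.shape[0], d=p.pixel_size))
    q_col = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(data.shape[1], d=p.pixel_size))
    return SpectralDensity2D(intensity, q_row, q_col, p.pixel_size)


def azimuthal_average(
    spec: SpectralDensity2D, direction: str = "qx", half_angle_deg: float = 15.0
) -> AzimuthalProfile:
    """Mean intensity in a ±half-angle sector about one q axis, binned in |q|.

    ``direction='qx'`` selects the sector around the column axis,
    ``'qy'`` around the row axis; opposite half-axes are pooled. Radial bin
    width is the q-grid step of the shorter grid axis. Bins with no pixels
    are reported as NaN, not zero.
    """
    if direction not in ("qx", "qy"):
        raise ValueError("direction must be 'qx' or 'qy'")
    if not 0.0 < half_angle_deg < 90.0:
        raise ValueError("half_angle_deg must lie in (0, 90)")
    qr, qc = np.meshgrid(spec.q_row, spec.q_col, indexing="ij")
    qmag = np.hypot(qr, qc)
    along = np.abs(qc) if direction == "qx" else np.abs(qr)
    with np.errstate(invalid="ignore", divide="ignore"):
        in_sector = along >= qmag * np.cos(np.radians(half_angle_deg))
    in_sector &= qmag > 0
    dq = max(
        np.diff(spec.q_row).mean() if len(spec.q_row) > 1 else np.inf,
        np.diff(spec.q_col).mean() if len(spec.q_col) > 1 else np.inf,
    )
    qmax = qmag[in_sector].max()
    n_bins = max(1, int(np.ceil(qmax / dq)))
    edges = np.arange(n_bins + 1) * dq
    which = np.clip(np.digitize(qmag[in_sector], edges) - 1, 0, n_bins - 1)
    inten = spec.intensity[in_sector]
    sums = np.bincount(which, weights=inten, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return AzimuthalProfile(direction, half_angle_deg, centres, mean, counts)


def porod_fit(profile: AzimuthalProfile, q_range: tuple[float, float]):
    """Least-squares slope of log10 I vs log10 q over ``q_range``.

    Returns ``(slope, intercept)``; a smooth-interface Porod regime gives a
    slope of -4.
    """
    lo, hi = q_range
    sel = (
        (profile.q >= lo)
        & (profile.q <= hi)
        & np.isfinite(profile.intensity)
        & (profile.intensity > 0)
    )
    if sel.sum() < 5:
        raise ValueError(
            f"need >= 5 usable bins in q_range {q_range}, found {int(sel.sum())}"
        )
    lq = np.log10(profile.q[sel])
    li = np.log10(profile.intensity[sel])
    slope, intercept = np.polyfit(lq, li, 1)
    return float(slope), float(intercept)


def porod_cutoff(
    profile: AzimuthalProfile,
    fit_band: tuple[float, float],
    tolerance: float = 0.15,
):
    """Low-q end of the Porod regime.

    Fits the q^-4 band first, then scans downward from the bottom of the
    fit band and returns the largest q at which log10 I departs from the
    fitted line by more than ``tolerance`` (log10 units). Returns ``None``
    when the profile never departs (pure power law).
    """
    slope, intercept = porod_fit(profile, fit_band)
    lo = fit_band[0]
    below = np.nonzero(
        (profile.q < lo) & np.isfinite(profile.intensity) & (profile.intensity > 0)
    )[0]
    for idx in below[::-1]:  # scan downward in q
        predicted = intercept + slope * np.log10(profile.q[idx])
        if abs(np.log10(profile.intensity[idx]) - predicted) > tolerance:
            return float(profile.q[idx])
    return None


def characteristic_distance(q_cutoff: float) -> float:
    """r = π / q_cutoff (nm): half the spatial period at the cutoff."""
    if not q_cutoff > 0:
        raise ValueError(f"q_cutoff must be > 0, got {q_cutoff}")
    return float(np.pi / q_cutoff)
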