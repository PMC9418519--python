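"""End-to-end orchestration: segment → label → metrics → shape → chords → spectra.

A single :class:`RunConfig` drives the full chain and every stage
parameter — including defaults the user never touched — is echoed into the
run record, so a run is reproducible from its ``run_record.json`` alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .chords import chord_lengths, first_moment, specific_surface_from_chords
from .core import BinaryVolume, VoxelVolume
from .io import read_volume, write_volume
from .minkowski import fp_diagram
from .porosity import (
    combine_total_porosity,
    detect_layer_boundaries,
    pore_volume_distribution,
    porosity_fraction,
)
from .scattering import (
    azimuthal_average,
    porod_cutoff,
    porod_fit,
    power_spectrum_2d,
    project_volume,
    characteristic_distance,
)
from .segmentation import (
    bimodal_threshold,
    label_components,
    morphological_cleanup,
    watershed_separate,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]


@dataclass
class RunConfig:
    """All stage parameters of a full analysis run."""

    input_path: str | None = None
    voxel_size_nm: float | None = None  # required for raw/TIFF without sidecar
    output_dir: str = "frustule3d_out"
    threshold: str | float = "auto"     # "auto" (Otsu) or a manual value
    dark_is_void: bool = True
    open_pairs: int = 1
    separate: str = "components"        # "components" | "watershed"
    connectivity: int = 26
    h_min_nm: float | None = None
    detect_layers: bool = False
    layer_axis: int = 0
    layer_smoothing_nm: float = 50.0
    chord_directions: str = "axes"
    chord_boundary_policy: str = "discard"
    projection_axes: tuple[int, ...] = (0, 1)
    sector_half_angle_deg: float = 15.0
    porod_band: tuple[float, float] | None = None  # nm^-1; None = upper half-decade
    porod_tolerance: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.input_path is None:
            raise ValueError("config field 'input_path' is required")
        if self.separate not in ("components", "watershed"):
            raise ValueError("separate must be 'components' or 'watershed'")


def _stage(name):
    """Decorator-free stage guard: re-raise with the stage name attached."""
    class _Ctx:
        def __init__(self, n):
            self.n = n

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{self.n}' failed: {exc}") from exc
    return _Ctx(name)


def run_pipeline(config: RunConfig, volume: VoxelVolume | None = None) -> dict:
    """Run the full analysis; returns the machine-readable summary.

    ``volume`` may be passed directly (bypassing I/O); otherwise
    ``config.input_path`` is read. Artifacts (labels, tables, summary JSON,
    run record) are written under ``config.output_dir``.
    """
    if volume is None:
        config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        if volume is None:
            volume = read_volume(config.input_path, voxel_size=config.voxel_size_nm)
        if volume.voxel_size is None or not volume.voxel_size > 0:
            raise ValueError("voxel size missing or invalid")

    summary: dict = {
        "schema_version": 1,
        "frustule3d_version": __version__,
        "voxel_size_nm": volume.voxel_size,
        "volume_shape": list(volume.shape),
        "seed": config.seed,
    }

    with _stage("segment"):
        if isinstance(volume, BinaryVolume) or volume.kind == "binary":
            binary = BinaryVolume(volume.data.astype(bool), volume.grid)
            summary["threshold"] = None
        else:
            manual = None if config.threshold == "auto" else float(config.threshold)
            thr, binary = bimodal_threshold(
                volume, manual=manual, dark_is_void=config.dark_is_void
            )
            summary["threshold"] = thr
        binary = morphological_cleanup(binary, config.open_pairs)

    with _stage("porosity"):
        summary["porosity_fraction"] = porosity_fraction(binary)
        if config.detect_layers:
            layers = detect_layer_boundaries(
                binary, axis=config.layer_axis, smoothing_nm=config.layer_smoothing_nm
            )
            summary["layers"] = {
                "boundaries": layers.boundaries,
                "names": layers.names,
                "thicknesses_nm": layers.thicknesses_nm,
                "porosities": layers.porosities,
                "total_porosity_thickness_weighted": combine_total_porosity(layers),
            }

    with _stage("label"):
        if config.separate == "watershed":
            labels = watershed_separate(binary, h_min_nm=config.h_min_nm)
        else:
            labels = label_components(binary, connectivity=config.connectivity)
        summary["n_pores"] = labels.n_labels

    with _stage("pore_volumes"):
        if labels.n_labels:
            dist = pore_volume_distribution(labels)
            summary["pore_volume_nm3"] = {
                "min": float(dist.volumes_nm3.min()),
                "max": float(dist.volumes_nm3.max()),
                "mean": float(dist.volumes_nm3.mean()),
            }
            np.savetxt(
                out / "prob_v.csv",
                np.column_stack(
                    [dist.bin_edges_nm3[:-1], dist.bin_edges_nm3[1:], dist.density]
                ),
                delimiter=",",
                header="v_lo_nm3,v_hi_nm3,density",
                comments="",
            )

    with _stage("shape"):
        if labels.n_labels:
            table, shape_summary = fp_diagram(labels)
            table.to_csv(out / "shapes.csv", index=False)
            summary["shape_finder"] = shape_summary

    with _stage("chords"):
        dist_p = chord_lengths(
            binary,
            phase="pore",
            directions=config.chord_directions,
            boundary_policy=config.chord_boundary_policy,
            seed=config.seed,
        )
        if not dist_p.is_empty:
            lp = first_moment(dist_p)
            ss = specific_surface_from_chords(lp)
            summary["mean_pore_chord_nm"] = lp
            summary["specific_surface_per_nm"] = ss.per_nm
            summary["specific_surface_m2_cm3"] = ss.m2_per_cm3

    with _stage("scattering"):
        spectra = {}
        for axis in config.projection_axes:
            proj = project_volume(binary, axis=axis)
            spec = power_spectrum_2d(proj)
            entry = {}
            for direction in ("qx", "qy"):
                prof = azimuthal_average(
                    spec, direction, half_angle_deg=config.sector_half_angle_deg
                )
                band = config.porod_band
                if band is None:
                    q_nyq = float(np.nanmax(prof.q))
                    band = (q_nyq / 3.0, q_nyq)
                d = {"porod_band_nm^-1": list(band)}
                try:
                    slope, intercept = porod_fit(prof, band)
                    d["porod_slope"] = slope
                    qc = porod_cutoff(prof, band, tolerance=config.porod_tolerance)
                    d["porod_cutoff_nm^-1"] = qc
                    d["characteristic_distance_nm"] = (
                        characteristic_distance(qc) if qc else None
                    )
                except ValueError as err:
                    d["porod_slope"] = None
                    d["error"] = str(err)
                entry[direction] = d
            spectra[f"axis_{axis}"] = entry
        summary["spectra"] = spectra

    with _stage("write"):
        write_volume(out / "labels.tif", labels)
        record = {"config": asdict(config), "summary": summary}
        (out / "run_record.json").write_text(json.dumps(record, indent=1, default=float))
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def make_fixtures(suite: str, seed: int, directory) -> Path:
    """Write the synthetic volumes + ground truth used by the test suites.

    ``suite`` ∈ {"primitives", "nanopores", "frustule"}.
    """
    from .core import GridSpec
    from .synthetic import (
        FrustuleSpec,
        NanoporeFieldSpec,
        frustule_grid,
        generate_frustule,
        generate_nanopore_field,
        generate_primitive,
    )

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if suite == "primitives":
        g = GridSpec((64, 64, 64), 1.0)
        specs = {
            "ball": dict(center=(32, 32, 32), radius=20),
            "hollow_shell": dict(center=(32, 32, 32), outer_radius=20, inner_radius=12),
            "torus": dict(center=(32, 32, 32), ring_radius=18, tube_radius=7),
            "slab": dict(axis=0, start=27, thickness=10),
        }
        for kind, geom in specs.items():
            vol, truth = generate_primitive(kind, g, **geom)
            write_volume(directory / f"{kind}.tif", vol)
            truth.save(directory, stem=f"{kind}_truth")
    elif suite == "nanopores":
        g = GridSpec((128, 128, 128), 1.0)
        vol, truth = generate_nanopore_field(NanoporeFieldSpec(seed=seed), g)
        write_volume(directory / "nanopores.tif", vol)
        truth.save(directory, stem="nanopores_truth")
    elif suite == "frustule":
        spec = FrustuleSpec(seed=seed)
        g = frustule_grid(spec, voxel_size=20.0)
        vol, truth = generate_frustule(spec, g)
        write_volume(directory / "frustule.tif", vol)
        truth.save(directory, stem="frustule_truth")
    else:
        raise ValueError(f"unknown fixture suite {suite!r}")
    return directory
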