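"""Ground-truth bookkeeping for synthetic volumes."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class GroundTruth:
    """Exact per-object and per-layer truth emitted by a generator.

    Attributes
    ----------
    objects
        One row per generated object (pore, chamber, ...) with its centre,
        size parameters, orientation and the exact voxel count painted.
    layer_boundaries
        Slice indices of the layer interfaces along z, where applicable.
    layer_porosity
        Exact pore fraction of each named layer, computed on the emitted
        voxel grid (not the continuous model), where applicable.
    adjacency
        Chamber connectivity edge list with throat diameters, where
        applicable.
    meta
        Generator spec echo (parameters, seed) for provenance.
    """

    objects: pd.DataFrame
    layer_boundaries: dict[str, int] | None = None
    layer_porosity: dict[str, float] | None = None
    adjacency: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_pore_voxels(self) -> int:
        if "voxel_count" in self.objects.columns:
            return int(self.objects["voxel_count"].sum())
        return 0

    def save(self, directory, stem: str = "ground_truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.objects.to_csv(directory / f"{stem}_objects.csv", index=False)
        if self.adjacency is not None:
            self.adjacency.to_csv(directory / f"{stem}_adjacency.csv", index=False)
        extras = {
            "layer_boundaries": self.layer_boundaries,
            "layer_porosity": self.layer_porosity,
            "meta": self.meta,
        }
        (directory / f"{stem}.json").write_text(json.dumps(extras, indent=1, default=str))
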