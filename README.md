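# frustule3d

Multiscale 3D porosity quantification for tomographic volumes of diatom
frustules (*Coscinodiscus*-type valves), and for hierarchical porous
silica more generally.

Diatom valves are built from three nested silica layers — an internal
**foramen** plate with one large (~1.2 µm) pore per hexagonal unit, a
honeycomb of **areola** chambers (~2.5 µm high) between thin walls, and an
external **cribrum** plate perforated by ~300 nm macropores — with 140 nm
connecting pores linking neighbouring chambers and, at the nanometre
scale, a dilute population (volume fraction ~2×10⁻³) of elongated
ellipsoidal nanopores inside the solid walls. Quantifying that hierarchy
from FIB-SEM, array-tomography or electron-tomography voxel volumes takes
a chain of standard but fiddly steps; this package implements the chain as
a tested, reusable library.

## What it computes

Given a grayscale or binary voxel volume with a physical voxel size:

- **Segmentation** — bimodal-histogram thresholding (Otsu with an
  imbalance-robust intermeans fallback), erosion/dilation cleanup,
  connected-component labelling (6/26-connectivity) and distance-transform
  watershed separation of chambers joined through narrow throats.
- **Porosity metrics** — porosity fractions φ (global, masked, per layer),
  layer boundaries from inflections of the solid-fraction profile, the
  pore-volume distribution Prob(v) with equivalent size v^(1/3), chamber
  mid-plane equivalent diameters/heights/volumes, and the chamber
  connectivity graph with throat equivalent diameters.
- **Shape classification** — the four 3D Minkowski functionals per pore,
  V₀ = V, V₁ = S/6, V₂ = H/(3π), V₃ = χ, and the shape-finder
  x = πV₀V₂/(4V₁²), y = 8V₁V₃/(3πV₂²),
  P = (1−x)/(1+x), F = (1−y)/(1+y)
  (planarity/filamentarity; both zero for a ball), as an (F, P) diagram.
- **Specific surface from chords** — pore/solid chord-length
  distributions f_p(r), f_s(r) and S_part/V_part = 4/⟨l_p⟩.
- **Spectral anisotropy** — 2D projections P(x, y), their power spectrum
  I(qx, qy) (q = 2π × spatial frequency), ±15° azimuthal sector averages,
  the Porod q⁻⁴ slope and its low-q cutoff, and characteristic distances
  r = π/q.
- **Synthetic volumes** — analytic primitives, oriented nanopore fields
  and full three-layer valve units, each with exact ground truth, so every
  estimator has a parameter-recovery test.

## Worked example

```python
import frustule3d as f3
from frustule3d.synthetic import FrustuleSpec, frustule_grid, generate_frustule

spec = FrustuleSpec.fib_like(seed=1)          # 7-chamber valve patch
grid = frustule_grid(spec, voxel_size=25.0)   # nm
volume, truth = generate_frustule(spec, grid)

layers = f3.detect_layer_boundaries(volume, axis=0)
b_f, b_c = truth.layer_boundaries.values()
areola = volume.crop((b_f, 0, 0), (b_c - b_f, *volume.shape[1:]))
chambers = f3.watershed_separate(areola, h_min_nm=100.0)
graph = f3.connectivity_graph(chambers)
```

Running `python examples/02_frustule_metrology.py` (which does exactly
this) prints:

```
detected boundaries (slices): [7, 107]  truth: [7, 107]
  foramen : thickness    175 nm  porosity  19.2 %
  areola  : thickness   2500 nm  porosity  43.3 %
  cribrum : thickness    200 nm  porosity  15.6 %
total porosity (thickness-weighted): 39.9 %
chambers found: 7 (generated: 7)
chamber-chamber throats: 12, mean equivalent diameter 149 nm (generated at 140 nm)
```

Both plate interfaces are found on the exact ground-truth slices, the
watershed recovers all seven chambers, and the 140 nm connecting throats
are measured to within a few percent from the watershed contact areas.
The other scripts in `examples/` walk through the nanopore field
(`01`), the (F, P) shape finder (`03`), chord-based specific surface
(`04`) and spectral anisotropy (`05`) the same way.

A thin CLI mirrors the library:
`frustule3d generate|convert|segment|porosity|shape|chords|scatter|run`.

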