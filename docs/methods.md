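# Methods

This note records the models, discrete estimators, parameter choices and
known limitations behind `frustule3d`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Conventions

Volumes are numpy arrays in `(z, y, x)` order with cubic voxels of edge
`voxel_size` (nm); `z` is the slicing/projection axis of a serial-section
acquisition. Index windows are 0-based and half-open. In binary volumes
`True` is pore/void (the "black voxel = void" convention of segmented
tomograms); labels use `0 = solid`, `k ≥ 1 = pore k`. The pore phase is
26-connected and the solid phase 6-connected — a complementary pair, so
Euler characteristics of pore and solid are topologically consistent.

## Segmentation

`bimodal_threshold` formalizes "choose a threshold between the two modes
of the histogram" as Otsu's between-class-variance maximum, then checks
that the induced split is genuinely bimodal: the class means must be
separated by more than 1.8× the sum of the class standard deviations (a
single Gaussian split at its middle gives ≈1.6σ vs 1.8 × 1.2σ, and is
rejected). Otsu is known to misplace the threshold under extreme class
imbalance — a nanopore volume is ~99.8% solid — so when its split fails
the check, the Ridler–Calvard intermeans threshold (iterating
t ← (μ₀ + μ₁)/2), which is insensitive to class weights, is tried before
giving up. A manual threshold always overrides. The criterion and both
estimators are affine-equivariant in intensity.

Cleanup applies `n_pairs` erosion/dilation pairs (openings) of the pore
phase with the 6-connected structuring element; the number of pairs in
published pipelines is typically unstated ("several"), so the default is
1 and the parameter is exposed everywhere. Opening removes sub-element
speckle but also destroys pores thinner than ~3 voxels; dilute nanopore
analyses should run with `n_pairs = 0` (as the examples do).

`watershed_separate` floods the negated Euclidean distance transform from
markers obtained by h-maxima suppression at depth `h_min_nm` (physical
units, default two voxel lengths, so the splitting scale does not change
with resampling). Chambers joined through throats narrower than their
bodies by more than `h_min` in inscribed-sphere radius are split; merging
all labels reproduces the input binary exactly (tested as an invariant).

## Minkowski functionals and the shape finder

For each labelled object (cropped to its bounding box with a one-voxel
background margin):

- **V₀** is the voxel count × voxel volume — exact.
- **χ (V₃)** is the Euler characteristic of the polyhedral union of the
  closed voxel cubes, computed as vertices − edges + faces − cubes with
  the "count an element if any incident voxel is foreground" rule. This
  realises 26-connectivity of the foreground exactly (two voxels sharing
  only a corner are one body), and is cross-checked in the tests against
  an independent library implementation on random volumes and on
  hand-built topologies (ball χ=1, shell χ=2, torus χ=0, all exact).
- **S (6V₁)** uses Crofton intercept counting over the 13 lattice
  directions of the 2×2×2 neighbourhood:
  S = 2a² Σ_k w_k T_k / |d_k|, where T_k counts phase changes between
  lattice neighbours along direction d_k and w_k is the solid angle of the
  spherical Voronoi cell of ±d_k on the unit sphere (computed at import
  time with `scipy.spatial.SphericalVoronoi` — no hard-coded weight
  table). A digitized ball of R = 20 voxels comes out within 0.4% of
  4πR²; the acceptance tolerance is 3% for R ≥ 15.
- **H (3πV₂)**, the integral of mean curvature ∮(κ₁+κ₂)/2 dA, uses the
  Crofton section formula H = 2π ⟨Σ_sections χ₂⟩ averaged over section
  orientations, estimated from the three axis-normal slice stacks with 2D
  Euler characteristics (8-connected in-plane, closed-square complex). A
  ball gives 4πR within 2.5% at R = 20. Only three plane orientations are
  sampled, so H carries an orientation bias for strongly anisotropic
  bodies — the prolate-spheroid oracle test budgets 15% for a 1:6 aspect
  ratio. This bias shifts individual (F, P) values slightly but not the
  qualitative reading of the diagram (F vs P ordering), which is what the
  cloud centroid summarizes.

The shape finder follows the planarity/filamentarity construction:
x = πV₀V₂/(4V₁²), y = 8V₁V₃/(3πV₂²), P = (1−x)/(1+x), F = (1−y)/(1+y).
For isolated pores V₃ is forced to 1 in the shape finder (the convention
when only flattening and elongation are of interest); the measured χ is
always reported alongside. Objects with non-positive V₁ or V₂ (possible
for voxel-scale rough objects, where the curvature estimator can go
negative) get an undefined shape entry — reported, never dropped. Objects
touching the volume boundary are flagged and excluded from the (F, P)
cloud summary by default, since truncated functionals are biased.

## Chord lengths and specific surface

A chord is a maximal same-phase run along a ray with both ends on the
interface. The default ray set is the three lattice axes pooled: runs are
exact (no interpolation) and the engine is verified against a brute-force
run-length oracle voxel for voxel. Chords touching the volume boundary
are discarded by default (truncation biases ⟨l⟩ downward); the
`truncate` policy keeps them, reproducing finite-size-affected estimates,
and per-ray length conservation (pore + solid + discarded = ray length)
is a tested invariant. For anisotropic media an isotropic direction
sample is available: seeded random orientations traced at half-voxel
steps with trilinear phase interpolation thresholded at 0.5 — the
interpolation prevents oblique rays from fragmenting one chord into
several at a jagged digital surface (nearest-voxel lookup biases the
ball mean chord ~20% low; trilinear brings it within 5%).

The specific surface of a (possibly disconnected) pore phase is
S_part/V_part = 4/⟨l_p⟩, reported in nm⁻¹ and m² cm⁻³ (×1000). The
digitized-ball closed forms (⟨l⟩ = 2D/3, S/V = 6/D) anchor the tests; a
4.41 nm mean chord maps to 907 m² cm⁻³.

Histogram densities use 1-voxel bins normalized to unit integral; the
first moment is always the mean of the raw chord lengths, not of bin
centres.

## Projections, spectra and the Porod regime

`project_volume` counts pore voxels along one axis; by the
projection-slice theorem the squared-modulus 2D FFT of that projection is
the small-angle scattering pattern I(qx, qy) of the structure in the
plane qz = 0, with q = 2π × spatial frequency. The projection mean is
subtracted before the transform (removes the q = 0 spike and keeps
Parseval's identity exact, which the tests assert bit-tight); a Hann
window is available but off by default. With r = π/q, a cutoff q maps to
half a spatial period — the convention that makes r a pore-size estimate.

Azimuthal profiles average I over ±15° (configurable) sectors about the
qx or qy axis, pooling both half-axes, in radial bins one q-step wide;
empty bins are NaN, never zero. The Porod slope is the least-squares
slope of log₁₀I vs log₁₀q over a stated band (a smooth-interface field
gives −4; the polydisperse-ball fixture lands at −3.9). The Porod cutoff
scans downward from the fit band and returns the largest q whose
intensity departs from the fitted line by more than 0.15 log₁₀ units
(default; the cutoff was historically located by eye, and a fixed
documented tolerance makes it reproducible). On voxel-scale pores the
spectra carry discretization wiggles, so the oriented-nanopore analyses
use a 0.3 tolerance; the robust anisotropy readout is the
intensity-weighted q centroid of each sector, whose qx/qy ratio is ≈1
for isotropic fields and ≈4–5 for the oriented default field.

## Synthetic volumes

All generators are pure functions of (spec, grid, seed) and voxelize by
centre sampling (a voxel is pore iff its centre is inside the continuous
shape), which makes the voxel count an unbiased volume estimator.

**Nanopore fields** pack non-overlapping ellipsoids by bounded rejection
sampling until the target volume fraction (default 1.9×10⁻³) is reached;
failure reports the achieved fraction. Semi-axes are drawn log-uniformly
from (2.4–28.4, 1.0–2.9, 1.0–2.9) nm, which spans pore volumes of
10–1000 nm³ with 2.4–10× elongation; at the reconstruction scale used in
the acceptance run (330×770×804 voxels at 1 nm) this yields ~2700 pores.
Long-axis orientations follow an axial Dimroth–Watson-style density
∝ exp(κ cos²θ) about the preferred axis (κ = 0 is isotropic, verified by
a χ² octant test; default κ = 10). A minimum separation (default 2 nm)
is enforced by an inflated-ellipsoid occupancy check, and candidates
whose sub-voxel-thin rasterization would split into several connected
components are rejected, so labelled-component count equals ground-truth
pore count exactly.

**Frustule units** place hexagonal-prism chambers on a hexagonal lattice
(flats facing neighbours) between a foramen plate (180 nm, one 1.2 µm
circular pore per unit) and a cribrum plate (200 nm, a 13-pore rosette of
300 nm pores per chamber). The chamber width tapers linearly
(trapezoidal vertical section, ±15% from mid-plane by default, walls
thickening towards the foramen); dividing walls are 230 nm-high
pyramidal-section ridges on the foramen pore rim; 140 nm connecting
pores are horizontal cylinders scattered through the bottom third of the
chamber height between adjacent chambers. The lattice parameter is not
a published measurement; the default is 1.8 µm (chosen so the largest
chambers plus walls fit) and is user-overridable. Two stock parameter
sets mirror the two acquisition modalities the geometry comes from:
the default draws chamber mid-plane equivalent diameters from
{1.2, 1.5} µm (the bimodal chamber-size statistics an array-tomography
series shows), while `FrustuleSpec.fib_like()` uses wide uniform chambers
on a 2 µm lattice, giving the strong foramen/areola/cribrum porosity
contrast a FIB-SEM fragment exhibits — the natural fixture for
layer-boundary metrology. Ground truth records exact per-layer porosities
of the emitted grid, boundary slices, per-chamber voxel counts and the
throat list.

**Acquisition noise** renders a binary volume as a two-Gaussian mixture
(defaults: solid 200, pore 50, the pore phase dark).

What the generators deliberately do not model: image-formation physics
(beam damage, curtaining, missing wedge), section misalignment, the
cribellum layer, and curved (circle-arc) valve geometry. Passing the
recovery suites therefore shows the estimators are correct on clean
geometry at realistic sizes and fractions — not that segmentation of a
noisy, artefact-laden experimental tomogram is solved.

## Layer-boundary detection

The per-slice solid fraction is smoothed with a moving average of
physical width 50 nm (default), and boundaries are the sharp extrema of
its derivative — the zero crossings of the second derivative between
plateaus. A transition registers only if a solid-fraction jump of at
least `min_jump` (default 0.015) is concentrated within about one
smoothing window; the peak must also be prominent by the same amount, so
staircase wiggles riding on the gentle ramp of a tapering chamber wall
do not register. With three layers the names foramen/areola/cribrum are
assigned in increasing z. On the `fib_like` fixture at 20–25 nm voxels
the two interfaces are recovered on the exact ground-truth slices across
seeds, and layer porosities agree with ground truth to well under one
percentage point.

## Combining layer porosities

The total porosity of a layered stack is the thickness-weighted mean of
the layer porosities — the only combination that conserves voxel counts
when the layers tile the axis (tested as an exact invariant). For the
reference triple (180 nm at 33%, 200 nm at 27%, 2500 nm at 78%) this
gives 71.6%. Combinations of the same triple quoted elsewhere as "about
64%" are not reproducible by thickness weighting (nor by unweighted
averaging, which gives 46%); the discrepancy is surfaced rather than
hidden, and the operation implemented is the physically conservative one.

## Problem sizes and determinism

The acceptance run uses a 330×770×804-voxel nanopore field at 1 nm
(~2700 pores), a 7-chamber `fib_like` valve at 25 nm voxels for layer and
throat metrology, a 5-diameter valve at 30 nm voxels for the
volume–diameter power law (exponent 2.0 for constant-height chambers),
64³ primitives for the Minkowski oracles and a 128×256² ball field for
the Porod slope; it completes in about a minute on one CPU. Every source
of randomness is a `numpy.random.default_rng` seeded from the single
`--seed` argument (per-stage seeds derived by fixed affine maps, kept
below 2³¹). Watershed flooding, labelling and FFTs are deterministic, so
repeated runs with one seed are bit-identical.

## Known limitations

- H (and thus V₂, P, F) uses three section orientations; needle- or
  plate-like objects carry a ~10–15% H bias. Adding oblique section
  planes would reduce it at the cost of resampling.
- The Porod cutoff is a thresholded departure from a fitted line; on
  profiles with strong form-factor oscillations (few large monodisperse
  pores) it can latch onto an oscillation. Polydispersity or wider
  tolerance smooths this.
- Chord statistics along the three axes are exact but directionally
  coarse; for strongly anisotropic media use the random-direction mode
  and expect the ~1-voxel interface softening of trilinear lookup.
- The frustule generator is an idealization: perfectly periodic lattice,
  flat plates, no wall curvature or surface roughness. It is built for
  estimator validation, not for morphological realism beyond the printed
  dimensions.
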