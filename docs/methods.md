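# Methods

This note documents the models, the synthetic-data design, and the
numerical choices behind `rudimorph`, in the spirit of a model-description
chapter: what is computed, under which assumptions, and what the tests do
and do not demonstrate.

## 1. Biphasic tissue model

Cartilaginous rudiment tissue is modelled as a saturated porous medium
(biphasic theory): an elastic solid skeleton representing ECM and cells,
and an interstitial fluid occupying an initial volume fraction
`porosity` (default 0.8, the typical water content of cartilage). Both
constituents are intrinsically incompressible, so volume change requires
fluid exchange. The unknowns are the skeleton displacement **u** and the
pore pressure *p*, taken positive in compression so that "compressive
pore pressure" is the positive part of *p*.

* Momentum balance of the mixture: `div(sigma' - p I) = 0` with a linear
  isotropic effective stress `sigma' = 2 mu eps + lambda tr(eps) I`.
* Fluid mass balance: `d/dt tr(eps) + div w = 0` with Darcy seepage
  velocity `w = -k grad p`.

The solid skeleton is **linear small-strain elastic**. This is a
deliberate simplification of finite-strain poro-viscoelastic
formulations: the default loads (peak contact traction 1 kPa against an
aggregate modulus of 17.5 kPa) keep strains in the ~5–10% range, and all
of the behaviours this package is built to exhibit — pressure generation
under fast loading, dissipation under sustained load, localization of
compressive pressure beneath a moving contact, the consolidation
benchmark — are small-strain phenomena. Growth kinematics (below) use
updated coordinates, so cumulative growth can be large even though each
elastic solve is linear.

Default parameters (configurable, `PoroMaterial`):

| parameter | default | unit | rationale |
|---|---|---|---|
| shear modulus mu | 5 | kPa | soft embryonic/regenerating cartilage |
| Poisson ratio nu | 0.3 | – | drained skeleton, standard for cartilage models |
| porosity n0 | 0.8 | – | cartilage water content (metadata in the linear theory) |
| hydraulic conductivity k | 10 | um^2 kPa^-1 s^-1 | = 1e-14 m^4 N^-1 s^-1, soft-tissue order of magnitude |

With these values the consolidation coefficient is
`c_v = k (lambda + 2 mu) = 175 um^2/s` and the radial consolidation time
of a 150 um shaft is ~130 s, so a 1 s load cycle is deeply in the
undrained regime — pressure builds under the moving contact and cannot
drain within a cycle, while a sustained load drains essentially
completely within tens of consolidation times. This separation of time
scales is what makes cyclic loading an effective growth stimulus in the
model and static loading an ineffective one.

### Discretization

Trilinear (Q1) displacements and pressures on 8-node hexahedra with
2x2x2 Gauss quadrature. Equal-order u-p pairs violate the inf-sup
condition; the polynomial-pressure-projection stabilization (element-mean
projection, coefficient `1/(2 mu)`) is assembled into the pressure block,
which suppresses checkerboard modes at negligible cost and keeps the
matrix symmetric. Time integration is backward Euler (unconditionally
stable at the 0.01 s load steps). The monolithic system is linear; it is
factorized once per distinct time-step size (sparse LU) and re-solved per
step, with an explicit residual check (tolerance 1e-8 relative) in place
of a nonlinear loop.

Boundary conditions for the rudiment follow the anatomy of the problem:
free fluid flow (p = 0) across all external surfaces except the proximal
base; the base is fixed in all displacement components, which prevents
rigid motions while letting the shaft grow outward.

The solver is validated against the closed-form Terzaghi consolidation
series on a 20-element column (relative L2 error a fraction of a percent,
see `tests/test_poro.py` and the acceptance benchmarks) and carries
objectivity (rotated problem, rotated solution), conservation
(discrete divergence theorem) and time-step self-convergence checks.

### Seepage-velocity divergence

The alternative growth stimulus, the positive divergence of the seepage
velocity, measures the local rate of solid compaction. Because trilinear
pressure gives an (almost) element-wise constant gradient, an in-element
divergence is identically ~0; div(w) is therefore reconstructed per
element from an affine least-squares fit of w over the centers of
node-connected neighbour elements. The reconstruction is exact for
seepage fields linear in position (verified by a manufactured quadratic
pressure) and satisfies the discrete divergence theorem to well under 1%
on refined meshes.

## 2. The load program

A 1 s flexion–extension cycle, in 0.01 s increments. The contact of the
neighbouring skeletal elements is represented by an inward pressure patch
on the distal articular cap; the patch center sweeps along a parametric
path at fixed polar angle while a sine amplitude profile rises from zero
(extension) to the peak traction at mid-cycle (peak flexion) and back.
Defaults (`LoadProgram`): patch radius 100 um, peak traction 1 kPa,
sweep over the azimuthal sector of the ventral condyle (the anatomical
contact area of the articulating elements), ending at the ventral
condyle azimuth at peak flexion, at polar angle 1.2 rad (the articular
margin). The sweep path and traction magnitude are free configuration;
the defaults were chosen once as an anatomically motivated ventral-sector
contact.

## 3. Growth model

Per-element volumetric growth per cycle:
`theta_e = 1 + k_bio + k_mech S_e`, with
`S_e = int max(p_e, 0) dt` over one cycle (trapezoidal). `k_bio`
(default 0.002/cycle) is spatially and temporally constant — chondrocyte
density is approximately uniform in the rudiment at this stage, and the
biological contribution is assumed proportional to it. `k_mech` (default
0.02 per kPa s) scales the mechanical contribution; `k_mech = 0` is the
mechanosensitively impaired case. Defaults keep single-cycle growth below
~1%, within the validity of extrapolating a single solved cycle.

The single-cycle field is extrapolated over `n_cycles` (default 100)
compound-wise, `theta_total = theta_cycle^n`; linear extrapolation
(`1 + n g`) is available and agrees within 1% while `n g < 0.02`. The
mechanics are **not** re-solved between extrapolated cycles: one cycle is
solved, growth is extrapolated, and the grown configuration is computed
once. Re-solving per increment would couple growth and load history at
substantially higher cost; with per-cycle growth « 1 the first-order
behaviour is identical.

Growth is applied as an isotropic growth tensor `Fg = theta^(1/3) I`
(no directional information is assumed): the growth stretch enters a
drained elastic equilibrium solve as a stress-free eigenstrain under the
original displacement constraints, and the mesh nodes move to the
equilibrium configuration. For a spatially uniform field on an
unconstrained body this reproduces exact uniform scaling (rigid modes are
removed by zero-mean/zero-moment Lagrange constraints). Element inversion
is checked and is a hard error — the remedy is smaller per-cycle growth
or fewer extrapolated cycles.

### Surface-growth maps

The healthy (`k_mech > 0`) and impaired (`k_mech = 0`) grown shapes are
compared through per-node displacement magnitudes between the original
and grown surfaces (node correspondence is exact). Both cases are
normalized by their shared maximum, then flattened with the same
reference-surface machinery as the experimental-style morphometry. Note
that a displacement-magnitude map conflates outward growth with
growth-induced bending of the whole rudiment; `point_surface_distance`
provides a perpendicular (sliding-blind) alternative for diagnostics.
Under the default ventral-sector sweep the healthy map's ventral sector
exceeds its dorsal sector, while the impaired map is azimuthally uniform
to a fraction of a percent with only a proximo-distal gradient — the
contrast the model exists to demonstrate.

## 4. Synthetic data

The generator provides every input with exact ground truth; all outputs
are pure functions of (spec, seed).

**Limb surfaces.** A capped cylinder (shaft radius 150 um, length
600 um — a plausible scale for a regenerating humerus in a 3–5 cm
animal; the true dimensions are configuration, not constants) carrying
C1 cosine-taper radial features: two condyles (defaults: dorsal height
0.25 and ventral 0.30 of the shaft diameter, angular width 0.9 rad,
on the upper shaft/articular margin at azimuths 2pi/3 and 4pi/3) and two
shallower concavities between them. The cosine taper gives closed-form
apex heights and super-threshold contour radii, hence analytic condyle
areas/volumes for end-to-end recovery tests. Right-handed limbs are exact
mirror images of their left twins by construction, so mirror-consistency
can be asserted to machine precision. Widths were chosen once as broad,
anatomically plausible features that a 512-element mesh can represent.

**Voxelization.** Watertight surfaces are rasterized slice-by-slice
(plane section + even-odd polygon fill) into binary stacks with
anisotropic spacing, axis order (z, y, x), z proximo-distal before
alignment. Marching cubes reconstructs surfaces from stacks.

**Nuclei stacks.** Gaussian-profile blobs (radius 4–6 um, sigma = r/2)
at non-overlapping uniform positions, with Poisson shot noise on a
constant background plus additive Gaussian read noise; SNR is blob peak
over background noise sd (default 5). Volume outliers are planted at
>= 3x the upper radius bound. What the generator does *not* emulate:
optical PSF anisotropy and depth attenuation, intensity inhomogeneity,
clustered or touching nuclei beyond the overlap limit, autofluorescent
background structure. Detection results on this data are therefore an
upper bound on real-stack performance; the downstream logic (volumes,
outlier fences, cut-off, counts, statistics) is exercised realistically.

**Meshes.** Structured boxes for benchmarks, and a ~512-hexahedron
humerus built by a butterfly (O-grid) cross-section extruded along the
axis with the top layers morphed into the hemispherical dome. The outer
cell layers are radially aligned, so azimuth-dependent radial scaling
cannot invert them. The feature field is low-passed to the mesh's angular
resolution (a 3-point Gauss box average over each cell's angular
footprint) and applied to the boundary nodes; interior nodes follow by
harmonic (graph-Laplacian) extension — coarse meshing deliberately loses
a little surface detail, as any 512-element mesh must. Corner Jacobians
are checked positive.

## 5. Morphometry pipeline

1. **Mirroring.** Right limbs are reflected through the plane containing
   the long axis and the azimuth-0 direction (y = 0).
2. **Alignment.** The minimum principal axis of the volume inertia tensor
   maps to +z (sign conventions are fixed deterministically). The distal
   end is identified geometrically: the end whose vertices protrude
   radially beyond the median shaft radius (condyles live there), with a
   tie-break for featureless limbs — the tapering (rounded) end is distal,
   the flat amputation face proximal. Near-isotropic solids (principal
   moments within 1%) are rejected as degenerate.
3. **Cylinder fit.** Least-squares cylinder (axis point, small tilts,
   radius) over the proximal 50% of the axial extent, excluding the
   bottom 5% (amputation face). The fitted diameter d normalizes all
   metrics, cancelling animal size.
4. **Reference surface.** A hemispherical cap of radius r on the fitted
   cylinder, raised along the axis until tangent to the distal end: the
   cap center height is the maximum over surface points inside the cap
   footprint of `z - sqrt(r^2 - rho^2)`, so the minimum gap is exactly
   zero and never negative.
5. **Flattening.** Each surface point has a unique (azimuth, meridian)
   coordinate: meridian = axial distance on the shaft, continuing as polar
   arc length on the cap. Its signed normalized distance is
   (radial distance - r)/d, measured from the axis on the shaft and from
   the cap center on the cap (the reference normal directions). The map
   is a 256 x 128 (azimuth x meridian) grid of bin means over dense
   deterministic barycentric samples of the surface triangles; empty
   cells are masked, and the lowest two rows (the amputation face, which
   has no meaningful radial distance) are always masked. Cell areas in
   d^2 units are tracked per row (cap rows shrink with the cosine of the
   polar angle). This point-projection flattening replaces per-cell ray
   casting; for the star-shaped geometries of rudiments the two are
   equivalent, and projection is orders of magnitude faster in pure
   numpy.
6. **Condyles.** Connected map regions >= 0.2 (azimuthally periodic);
   the two largest are dorsal/ventral, identified by their cyclic
   arrangement (the companion region lies counter-clockwise of the dorsal
   one within half a turn — consistent after mirroring). Normalized area
   = sum of cell areas (d^2), normalized volume = sum of value x cell
   area (the 2D map integral, not a 3D protrusion volume — the map-based
   definition is the one implemented and reported). Concavities use the
   analogous <= -0.2 rule.
7. **Mean maps.** Maps are rolled periodically in azimuth to align dorsal
   centroids, then averaged cell-wise over valid cells.

## 6. Nuclei counting

Matched-filter detection: the stack is normalized by a robust MAD noise
estimate, smoothed at the blob scale (sigma = half the mid-radius), and
local maxima above `noise_sd * (sqrt(2 ln N) + 2)` (N voxels; an
extreme-value threshold with margin for the Poisson tail) are nucleus
centers, deduplicated within one minimum radius. Watershed on the
smoothed foreground with the maxima as markers splits merged blobs and
yields volumes (which are systematically inflated by the smoothing — all
downstream use is relative, so only ordering matters). Volume outliers
are flagged by Tukey fences (1.5 IQR) on the volume distribution — the
fence rule is this package's choice. A fixed-length axial cut-off from the
distal tip keeps the counted volume comparable across limbs; the cut-off
length is required configuration (default 140 um in the synthetic study).

This classical pipeline deliberately replaces a trained segmentation
network; it preserves the bespoke downstream logic while remaining fully
deterministic and dependency-light.

## 7. Statistics and the synthetic study

Per metric (condyle normalized areas and volumes, shaft diameter, kept
count): Shapiro–Wilk per group at alpha 0.05; one-way ANOVA if no group
rejects normality, else Kruskal–Wallis. Constant samples fall back to
Kruskal–Wallis with p = 1. No multiple-testing correction is applied
across metrics (each metric is reported on its own; the report carries
the rule text).

The default study design: 10 control and 11 treated limbs (the treated
group has a 0.7x ventral and 0.9x dorsal condyle height and a fourfold
lower planted nuclei count), 8% lognormal limb-to-limb height jitter,
10% lognormal animal-size jitter (which the d-normalization cancels),
random handedness, 1.5 um surface vertex noise. Nuclei stacks are
80^3 voxels at 2 um; planted counts are Poisson around the group means
(400 vs 100).

## 8. Problem sizes and runtime

The test and benchmark studies use: 20-element columns (80 for the
refinement arm of the conservation check) for consolidation oracles; the
512-hexahedron humerus with 100 steps/cycle (1–3 cycles) for the
simulation studies; surface resolution 96–128 with 256x128 maps for
single-limb morphometry and 72 with 128x64 maps inside the multi-limb
studies; voxelization at (3, 2, 2) um spacing; and 20 repetitions of the
null study for the type-I measurement. These sizes were chosen to keep
the full validation suite in the minutes range on one CPU while leaving
every oracle comfortably inside its tolerance.

## 9. Known limitations

* Small-strain elasticity: very large tractions (strains beyond ~15%)
  leave the regime the solver is intended for; growth handles large
  cumulative volume change but each increment must stay moderate.
* Constant permeability (no strain dependence) and no solid-phase
  viscoelasticity; the only tissue time scale is consolidation.
* The displacement-magnitude growth map conflates bending with growth
  (see section 3); the healthy/impaired sector contrast is accordingly
  conservative.
* One mechanics solve per study: no growth–load feedback.
* The synthetic nuclei and limb generators are idealized (section 4);
  passing tests demonstrate pipeline correctness on known ground truth,
  not segmentation performance on real light-sheet data.
* Condyle metrics are map-based (2D); they are internally consistent and
  scale-invariant but not literal 3D protrusion volumes.
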