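# Methods

## Physical model and assumptions

`olftes` treats the head as a passive volume conductor.  For stimulation
pulses of duration *T* = 0.5 ms the Fourier magnitude spectrum |A·T·sinc(fT)|
concentrates power below the first zero crossing 1/*T* = 2 kHz; at the
representative analysis frequency of 1 kHz (half the first zero) the
reactive ratio ωε/σ of head tissues is of order 10⁻² or less (e.g. gray
matter with ε ≈ 10⁵·ε₀ gives ωε/σ ≈ 0.02; `reactive_ratio` computes this
for any σ, ε pair).  The displacement term of
∇·((σ + jωε)∇V) = 0 is therefore dropped and the purely conductive
equation ∇·(σ∇V) = 0 is solved with DC conductivities.  Consequences of
this quasi-static assumption: the solution at any instant scales linearly
with the injected current (doubling the current doubles every field value),
waveform shape only scales the answer, and no tissue dispersion is modeled.

Conductivities (S/m, isotropic): scalp 0.465, muscle 0.35, skull 0.01,
CSF 1.65, gray 0.276, white 0.126, fat 0.04, blood 0.7, eye 1.65,
air 10⁻⁷, conductive gel 0.3, electrode metal 5.8 × 10⁷, cartilage 1.01,
intestines 0.164, mucosa 4 × 10⁻⁴, olfactory bulb 0.126, olfactory
epithelium/olfactory mucosa 4 × 10⁻⁴.  The table is immutable by default
and serializes losslessly to YAML.

Boundary conditions follow the stimulation setup: one uniform inward normal
current density J_n over the union of all anterior (source) electrode
exposed faces, sized so J_n × total source area = I_total (this implies an
area-proportional split among multiple source electrodes); Dirichlet V = 0
on posterior (ground) electrode exposed faces; zero normal current
elsewhere.  Exterior air is excluded from the computational domain (an
insulated boundary is equivalent to meshing σ = 10⁻⁷ exterior air to
numerical precision); internal cavities keep the air conductivity and stay
inside the domain.

## Discretization and solver

The grid is isotropic voxels (spacing in mm; all unit conversions live in
`olftes.units`).  A 7-point finite-volume stencil conserves current between
voxel centers; the face conductance between voxels a and b is the harmonic
mean 2σaσb/(σa+σb) times face area over center distance, the standard
choice for flux continuity across conductivity jumps (scalp/skull alone span
a factor 46; gel/epithelium nearly 10³).  Source faces contribute fixed-flux
right-hand-side terms; ground-face owners are eliminated as V = 0
(Dirichlet); conductive components with no path to ground are excluded from
the solve (a source on such a component is an error).  The matrix is
symmetric positive definite.

For geometries with an analytic description, `assemble_system` optionally
computes sub-voxel homogenized face conductances: each face is subdivided
4 × 4, each sub-segment between voxel centers is sampled at 8 points and
composed harmonically (series, normal to the face), and sub-segments are
combined arithmetically (parallel, across the face).  This removes the
shell-thickness quantization error when representing thin curved layers and
is used by the layered-sphere validation; label volumes without an analytic
description use the plain harmonic-mean faces.

The solve is preconditioned conjugate gradients.  Because conductivities
span twelve orders of magnitude (electrode metal to internal air), the
unscaled residual recomputed in float64 has a cancellation floor near 10⁻⁶
relative; the solver therefore iterates on the symmetrically Jacobi-scaled
system (unit diagonal), where the relative residual is the natural
row-balanced convergence measure, and reports the recursive PCG residual —
the standard measure iterative field solvers report.  Default tolerance
10⁻⁸, iteration cap 50·N^(1/3).  The preconditioner is a
smoothed-aggregation multigrid V-cycle: geometric 2×2×2 voxel aggregates,
prolongation smoothed by one damped-Jacobi step (weight 1.0), Galerkin
coarse operators, two damped-Jacobi sweeps (weight 0.7) per level, direct
factorization below 2000 unknowns.  On the 1 mm olfactory head
(~2.2 million unknowns) a montage solves in roughly 200–250 iterations.

The electric field is −∇V by central differences in the interior and
one-sided differences at the domain boundary, converted to V/m.
Per-electrode currents are recovered from the solved field as discrete flux
integrals over each electrode's conductor/domain interface, so source and
ground totals (±I_total within the solver tolerance) are genuine outputs of
the solve, not echoes of the imposed flux.

## Synthetic phantoms

The licensed, cluster-scale anatomical model that motivated this pipeline
is replaced by two parameterized phantoms (`olftes.phantom`).

**Layered sphere** — concentric shells (default scalp/skull/CSF/gray at
radii 80/75/71/69 mm) used solely for solver validation against the
analytic series solution.

**Olfactory head** — a stylized adult head: nested scalp/skull/CSF/gray/
white ellipsoids (outer semi-axes 70 × 85 × 78 mm; layer thicknesses
6/7/4/8 mm), a skin-covered muscle neck, eye spheres, deep ellipsoidal ROI
masks standing in for hippocampus and basal ganglia (tissue labels remain
gray/white; the ROIs are masks, matching how segmentations merge
compartments of equal conductivity), and the nasal complex:

- a mucosa-filled nasal block (turbinate stand-in, 27 × 38.5 × 33 mm)
  whose front face sits ~6 mm behind the anterior scalp surface, so only
  skin and a thin bone sliver separate it from nose-bridge electrodes —
  mirroring the short skin/nasal-bone path of the real nose;
- a narrow internal air channel through the block (the cavity lumen);
- the OE: a 2 mm sheet at the channel roof, wider than the channel, so it
  touches air centrally and rests on mucosa laterally.  The sheet thickness
  is exaggerated relative to real epithelium (tens of µm–mm) so it stays
  resolvable at 1–2 mm grids; its anterior–posterior extent is a free
  parameter, as the anatomical boundary of the olfactory region is not
  sharply defined;
- a 2 mm bone plate (cribriform stand-in) directly above the OE, with the
  two OB ellipsoids resting on it.

This arrangement preserves the conduction pathway that makes anterior
montages effective: current entering beside the nose crosses skin and thin
bone into the resistive mucosa block, and the series voltage drop
concentrates across the low-conductivity epithelium, producing OE fields an
order of magnitude above brain-tissue fields.  An earlier design with a
hollow air cavity and thin lining insulated the OE entirely (the drop moved
into the air gap), which is why the block is tissue-filled — a reminder that
for this target the cavity *walls*, not the lumen, carry the current.

What the phantom does not emulate: real cranial anatomy (gyri, skull
thickness variation, foramina), the perforations of the cribriform plate
(the plate here is solid thin bone; conduction to the OB passes around and
through it only diffusely), anisotropic white matter, and inter-subject
variability.  Passing tests on the phantom therefore demonstrate the
*pipeline and the montage-ranking mechanism*, not subject-level field
magnitudes; absolute OE/OB values on the phantom should not be read as
clinical predictions.

The OE mask partitions into anterior/middle/posterior thirds along +y
(the anterior axis): the anterior and middle sub-sections take ⌊L/3⌋
bounding layers each, measured from the anterior end, and the posterior
absorbs the remainder — a deterministic rule, documented here because any
L not divisible by 3 needs one.

## Electrode montages

Electrodes are 6 mm circular or 25 × 20 mm oval conductor disks (1 mm
thick) over 1 mm of conductive gel, anchored to named landmarks: the
cranial fiducials plus 10-10 positions computed as fractional arc lengths
along surface arcs (midline labels on the nasion→vertex→inion arc — Fpz
10%, POz 80%, Iz 100%; P9/P10 at 75% of the lateral nasion→preauricular→
inion arcs, behind the ears).  Tangential offsets are walked along the
surface as arc lengths (lateral, then vertical) with re-snapping to the
voxel surface at each step; normals come from local tissue centroids with
exact summation, and snapping uses a mirror-commuting tie-break, so
left/right-symmetric montages stamp exactly x-mirrored footprints on
symmetric phantoms.  Gel conforms to the stair-stepped voxel surface by
morphological dilation (guaranteeing electrical contact); the conductor is
the next dilation band.  Oval long axes are horizontal.

Choices where the montage descriptions leave freedom, all configurable:
nose-bridge electrodes sit ±0.8 cm lateral of the nasion; montage 1's
posterior ovals keep 1 cm between their inner edge and the midline (centers
±2.25 cm — ovals centered ±1 cm would physically overlap); montages 4/6 use
a 4 cm-spaced posterior oval pair, matching montage 3's spacing.

## Metrics and screening

Focality curves use strict inequality (|E| > t) at 101 evenly spaced
thresholds on [0, 1] V/m; montages are ranked by the OE volume fraction
above the 1 V/m reference threshold.  The two-stage screen
(`run_screening`) solves all configured montages, ranks them, and reruns the
top-k (default 3) with OE-third summaries, deep-ROI summaries, coronal
cross-sections (display clipping at 0.4 V/m affects rendering only, never
stored values) and axonal driving profiles; outputs carry the config digest,
package version and per-stage solver residuals, and identical configs
produce byte-identical tables.

Axonal drivers: paths are piecewise-linear polygons resampled at uniform
arc length (default ds = 0.1 mm, sub-voxel so second differences stay
smooth); Ve and E are sampled by trilinear interpolation (exterior voxels
nearest-filled to keep interpolation clean at the domain boundary);
Et = E·t̂ is signed, positive along increasing arc length; the activating
function is the central second difference of Ve over ds² (V/m²) with
endpoint values copied from their nearest interior neighbor.  The default
exemplary axons run anterior–posterior along the OE sheet, one per third,
the posterior one shortest.  Cross-montage normalization divides each
quantity by its global maximum absolute value over the profile set and
records which profile supplied the reference.

## Validation against the analytic sphere

`olftes.sphere` implements the Legendre-series potential of a point current
source and sink on an L-layer concentric sphere (per-degree 2L−1 linear
systems from interface continuity of V and σ∂V/∂r, regularity at the
center, and the surface flux condition; default truncation N = 200 with a
tail-magnitude warning flag).  The series reproduces the textbook
homogeneous-sphere solution to 10⁻¹⁸ and satisfies interface continuity to
10⁻¹⁵.

`oracle_error` voxelizes the same geometry, stamps two 6 mm disk electrodes
at the source/sink directions, solves, and compares mean-removed potentials
on the mid-shell sampling sphere (radius halfway between the outer surface
and the innermost interface, r = 74.5 mm for the default model), excluding
samples within 3 voxel-widths of the stamped electrode assemblies.  With
sub-voxel homogenized faces the relative L2 error decreases monotonically
under refinement — about 15% at 4 mm, 7% at 2 mm and 4% at 1 mm.  The
residual error at coarse spacing is the staircase representation of the
thin CSF and skull shells (tangential partial-volume effects that two-point
flux schemes on a Cartesian grid cannot remove); reaching a few percent at
2 mm would require a conforming-mesh or multi-point-flux discretization,
which is outside this package's scope.  Deep-brain potentials are more
sensitive (roughly 2–3× larger relative error at each spacing), which is
the expected behavior of voxel solvers under a resistive shell and worth
keeping in mind when reading absolute deep-ROI values at coarse grids.

## Numerical conventions and degenerate inputs

- Thresholds must be strictly ascending; ties at a threshold are excluded
  (strict >).
- Empty ROIs, unknown tissues/landmarks/montages, non-positive spacings and
  durations, coincident axon control points, paths leaving the solved
  domain, all-zero normalization sets, and assembling with non-positive
  conductivities raise specific exceptions (`olftes.errors`).
- OE sheets that would voxelize to zero layers raise a resolution error
  rather than silently vanishing (spacing ≤ 1 mm recommended; 2 mm is the
  coarsest that resolves the default 2 mm sheet).
- Pointwise field comparisons (e.g. the dose-linearity check) are made over
  voxels with |E| above 10⁻⁸ of the peak: the field has isolated stagnation
  points and near-zero values inside conductors where a relative ratio is
  ill-conditioned at any solver tolerance.
- Problem sizes used by the shipped end-to-end checks: 2 mm grids
  (~0.3 M unknowns) for conservation, linearity and the acceptance script;
  a 4/2/1 mm ladder for the oracle convergence study; one full six-montage
  screen at 1 mm (~2.2 M unknowns per solve) for the ordering check.
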