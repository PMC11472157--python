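# Methods

This note documents the models, conventions and numerical choices behind
`vtcorridor`, in the order the pipeline runs.

## Coordinates and units

One right-handed world frame in millimetres is shared by the SI volume
(through its NIfTI affine) and all meshes. Areas are cm², times ms,
signal intensity is normalized to percent of a reference.

## Phantom model

The LV is a truncated ellipsoidal shell. The endocardium is an ellipsoid
with semi-axes (22, 22, 40) mm cut by a basal plane at half the long
semi-axis (a stand-in for the mitral annulus, capped and flagged
`valve`); the epicardium is the outward offset of that surface by the
wall thickness (10 mm default) along the endocardial normal. Offsetting a
convex surface preserves normal distance, so the transmural fraction of
any wall point is exactly (distance to the endocardial ellipsoid) /
(wall thickness) — this is what makes every downstream stage testable
against closed forms. The foot point on the ellipsoid is found by
vectorized bisection on the standard closest-point root equation.

Scar anatomy is parameterized on the shell: a dense-core patch is an
angular window (longitude × polar angle × transmural depth); a channel is
a meridian strip with metric width, an SI level, and a transmural depth
span, carved through the core. Decoy channels are identical strips that
no reentrant circuit uses. SI levels are generated directly as the values
the classifier will see after normalization (dense core = maximum). The
voxel grid is isotropic at 1.5 mm, matching typical high-resolution 3D
acquisitions; optional white Gaussian noise is added with a seeded
generator, so a fixed spec is bit-reproducible.

Two deliberate departures from naive rendering:

- Cavity/background voxels take the remote-myocardium level rather than
  0. Blood pool in late-enhancement images is not dark, and a zero
  background would manufacture a dark rim under trilinear sampling at
  the 10% layer.
- The ground-truth channel vertex sets are the *voxel-resolution
  interior* of the nominal strip (eroded by one voxel laterally and an
  equivalent polar margin). Boundary voxels are genuinely ambiguous
  partial-volume tissue at 1.5 mm; defining truth at the resolution the
  data actually has keeps recovery metrics meaningful.

The simulated VT map assigns activation times arc-length-proportionally
around a reentrant loop (channel exit → outer limb around the scar →
entrance → back through the channel), spanning 85% of the cycle length —
activation maps in practice cover ~80–90% of the CL. Only the time
geometry matters to ROI construction, so no electrophysiological model is
simulated. Off-circuit points are area-weighted samples of the shell with
wavefront-like times spreading from the exit. The EP-space geometry is
the CMR geometry moved by a known rigid transform (8–20°, ±25 mm) with
0.5 mm point and landmark noise.

What the phantom does *not* emulate: papillary muscles, RV geometry,
trabeculation, MR physics (inversion-time/PSIR effects, surface-coil
shading), wall-thickness variation, multi-channel interdigitated scar,
or far-field EGM annotation error. Passing tests therefore demonstrate
correctness of the processing chain under the stated geometry and noise
model, not clinical performance.

## Layering

Correspondence is cast from each endocardial vertex along its outward
normal onto the epicardial mesh (vectorized Möller–Trumbore over
KD-tree-gathered candidate triangles); vertices whose ray misses fall
back to the nearest epicardial point (warned above 5%, error if nothing
lies within 25 mm). The normal-ray definition matches wall-thickness
semantics and is exact on the phantom.

SI is sampled trilinearly at endo + f·(epi−endo) for f = 0.1..0.9 and
normalized to percent of the myocardial maximum (default; a percentile
reference, default 99.5, is available for noisy data — percentile(100)
is identical to max). All nine layers live on the endocardial base mesh:
projection to a surface is an index operation with zero resampling error.
Samples outside the volume are flagged invalid and excluded downstream.

## Corridor extraction

The published description of the corridor computation names the sweep
(15 sequential ranges starting at 33%/53% of maximum SI) but not the
component rule, so the rule here is this package's explicit formalization:

- classification is lower-inclusive: healthy < bz ≤ border < core ≤ core-label;
- a corridor on one layer is a connected component of border-zone
  vertices that (a) is adjacent to at least one dense-core vertex and
  (b) whose boundary-ring healthy vertices split into ≥ 2 connected
  pieces (a BZ path joining two healthy regions through core);
- components entirely enclosed by core qualify only with
  `include_enclosed` (default off);
- vertices flagged `valve` are neutral: they neither join healthy pieces
  nor count as core;
- components below `min_vertices` (default 5, ≈ 0.1 cm² at the default
  mesh resolution) are partial-volume specks, not corridors.

The default sweep advances both thresholds by +1% at constant 20% width,
(33,53) … (47,67). The published method states the first pair and the
sequential ordering; step and width are a documented convention here and
fully overridable (`SweepPlan` from YAML).

## Footprints

Endocardial footprint = union of corridors from layers 10–50%; epicardial
= layers 60–90% (index-transferred). The split mirrors the method
definition and is exposed in configuration but not meant to be tuned.
Per-vertex provenance records every contributing (range, layer), which is
what restriction and ranking consume. The total-scar footprint uses the
first range's BZ threshold across the same layer split.

## EP ROI and registration

The activation window keeps EGMs within 0.35·CL of the latest activation
point or 0.10·CL after the earliest (times on the linear ms axis relative
to QRS onset; no modular wrapping — its measure over a uniform cycle is
0.45·CL). Mapping points carry no lateral extent, so point sets become
areas via geodesic discs of configurable radius; 5 mm reflects typical
ablation-relevant localization accuracy and is reported in every output.
Junctions (earliest↔latest, pace-map entrance↔exit, entrainment chains)
are shortest edge paths on the mesh, also grown by the disc radius.

Registration is a least-squares landmark fit (Umeyama, via scikit-image)
on the four landmarks; rigid by default — four landmarks barely constrain
an isotropic scale, so similarity mode is opt-in. Collinear landmarks are
rejected; residual RMS is always reported. EGMs transfer to their nearest
base-mesh vertex; points further than 10 mm from the surface are flagged
unmapped and excluded with a warning.

## Confusion counting

An isthmus EGM on the corridor footprint is TP; off the footprint it is
excluded (counted 0) when another EGM of the *same characterized isthmus*
is detected, else FN — "interdependent" is operationalized per isthmus
grouping key. Non-isthmus EGMs are FP on / TN off the footprint.
Curvature EGMs default to the non-isthmus side; the convention is
selectable (`isthmus`, `non_isthmus`, `exclude`) because published
tallies are ambiguous on this point. Zero-denominator rates are reported
as undefined, never 0. Ablation lesions (6 mm diameter default) count as
inside a corridor by their centre vertex; the ablated-area fraction uses
the union of geodesic discs.

## Range optimization

Per case and range r: contribution(r) = area(ROI ∩ vertices whose
provenance includes r) / area(ROI); cohort aggregate = median; ties break
by range id. Both the denominator (`roi` | `overlap`) and aggregator
(`median` | `mean`) are options since the precise normalization admits
variants. Ranking is in-sample, matching threshold-optimization practice;
an honest out-of-sample estimate would need leave-one-case-out, which the
API supports by re-ranking on case subsets. Top-k evaluation restricts
footprints by provenance and recomputes all metrics; overlap retained and
corridor area are non-increasing as k decreases by construction.

The bundled optimization cohort uses a functional channel at SI 39.5%
and a decoy at 59.5%: with the default sweep's threshold algebra these
are the values that make the functional channel border-zone in exactly
ranges 1–7 and the decoy in exactly ranges 8–15, giving the cohort a
known top-7 answer against which the optimizer is validated.

## Problem sizes and numerical choices

Default phantom: ~2 mm mesh edge (≈ 2 400 vertices/surface), ≈ 110 k
voxels, 300 EGMs/map, 5-case cohorts. These sizes keep every oracle
comparison exact while a full case runs in ~1.5 s. Geodesics are graph
shortest paths (Dijkstra on edge lengths) — an overestimate of true
surface geodesics by at most the lattice stretch, consistently on both
sides of every comparison. Areas are barycentric (one third of incident
triangle area per vertex). Ellipsoid foot points use 100 bisection
iterations (double-precision limit). JSON output is key-sorted and floats
round-trip exactly, which is what makes `demo` byte-reproducible.

## Known limitations

- The corridor rule is a formalization of an unpublished proprietary
  algorithm; agreement with it can only be directional.
- Graph geodesics and vertex-set areas discretize at the mesh scale;
  sub-millimetre claims need finer meshes.
- The epicardial footprint reuses endocardial indexing; true epicardial
  geometry (fat, vessels) is out of scope, as is RV mesh generation —
  septal reporting is flag-based.
- Cohort-level published medians arise from animal/patient data that are
  not redistributable; the package validates directional and structural
  properties on phantoms instead.
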