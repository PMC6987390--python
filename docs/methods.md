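# Methods

This note documents the models, estimators and numerical choices behind
`stereoglia`, in the order data flows through the package: synthetic
tissue → sectioning and imaging → probes → end-to-end workflow.  It
states what the simulator does and does not emulate, so it is clear what
a passing validation suite shows about real tissue — and what it cannot.

## Coordinate and unit conventions

All geometry is in micrometres, coordinates (x, y, z) with y the
"vertical" axis of the vertical designs (stack rotations are about y)
and z the optical/sectioning axis.  Boxes used for counting are
half-open ([lo, hi)); boxes used for clipping are closed, which differs
only on a null set.  Densities are handled internally in µm-based units
(µm⁻² for L_V, µm⁻³ for N_V) and converted to the conventional mm/mm³
and cells/mm³ only in reports (`stereoglia.units`).

## Synthetic tissue model

**Placement.** Soma centroids follow a homogeneous Poisson process at
the regime intensity.  With `halo_um > 0` (the pipeline uses 70 µm)
cells are also generated in a margin around the reference block so that
process density inside it is free of edge depletion; 70 µm covers ~95%
of the length-weighted arbor reach of the control regime.  Densities and
counts always refer to centroids inside the reference space.

**Somata** are ellipsoids with lognormal volumes (control 149 ± 74 µm³,
reactive 249 ± 118 µm³ — the published pooled means), mild lognormal
aspect spread (σ = 0.2) and uniform random orientation.

**Arbors** are recursive binary trees.  Primary counts are rounded Gamma
(mean 4.1 vs 9.0); primaries start on the soma surface along
near-uniform directions (an optional anisotropy parameter flattens them
away from vertical, off by default, for tangentially oriented
superficial-lamina cells).  Segment lengths are exponential (capped at
4× the mean); each segment either terminates or branches into two
children tilted ~40° ± 15° off the parent direction, to a regime maximum
depth (4 vs 3); segments carry a Brownian-bridge tortuosity orthogonal
to their chord, amplitude proportional to segment length.  Nothing in
the emulated study constrains arbor topology beyond summary statistics,
so these rules are the package's own; the constrained quantities are the
targets below.

**Length calibration.** The mean total process length per cell is a
regime target (800 µm control, 400 µm reactive).  The segment-length
scale is fitted once per parameter set on a fixed internal sample (seed
12345, 800 arbors) and cached; one fixed-point step is exact because
realized length is homogeneous of degree one in the scale.  Block
realizations then vary naturally around the target (SD of the per-cell
length is ~60% of its mean).

**Radii.** Radius tapers geometrically across branch orders from a
regime root radius (0.6 vs 0.9 µm) to a tip radius (0.04 vs 0.02 µm),
with vertex radii interpolated within segments and a per-cell lognormal
caliber factor (σ = 0.15) that makes the population radius distribution
continuous.  The tip radii were set once so that the length fraction
below the chromogenic detection threshold (next section) is comparable
across regimes, as the emulated study observed (~30% control, ~26%
reactive).

**Regime targets.** Control: N_V = 10⁴ cells/mm³ and 800 µm/cell, i.e.
L_V = 8,000 mm/mm³; reactive: 5 × 10⁴ cells/mm³ and 400 µm/cell, i.e.
L_V = 20,000 mm/mm³.  These sit inside the published per-side ranges and
give exactly the reported effect sizes (×5 cells, ×2.5 length, 50%
length-per-cell drop), so end-to-end recovery is checked against clean
targets.

**What is not emulated:** laminar density gradients (blocks are
homogeneous), microglial motility and contact dynamics, realistic
confocal optics (Airy PSF, depth attenuation, photobleaching),
soma-shape irregularity beyond ellipsoids, and the pseudopodic
expansions of reactive cells.  Passing recovery tests therefore show
that the estimators are unbiased for tissue-like curve and point
geometry at realistic densities; they do not certify segmentation or
staining artefacts beyond the thin-process loss model.

## Sectioning and shrinkage

`cut_sections` cuts serial coronal slabs of nominal thickness (40 µm),
keeps every k-th with a random start, clips all geometry exactly
(Liang–Barsky, runs merged so re-entries stay distinct polylines) and
rescales z by a collapse factor (pipeline default 0.75).  The nominal
cut thickness is kept as metadata.  Thickness is "measured" at every
third sampling spot (with 0.2 µm measurement noise) and the
count-weighted mean t̄_Q = Σqᵢtᵢ/Σqᵢ corrects sampled volumes by
t_cut/t̄_Q, exactly as in the emulated workflow.  This correction
restores densities referred to the cut-section volume; it cannot restore
the z-component of curve *length* lost to compression (≈ 7.9% at
k = 0.75 for isotropic curves, E[√(1−(1−k²)cos²θ)]).  That shortfall is
shared by the bench workflow, affects both staining routes equally and
cancels in every ratio the pipeline reports; absolute L_V report values
are accordingly ~8% below the generator target.

## Imaging model

Process centerlines are splatted into isotropic voxel grids (0.5 µm)
with radius-dependent intensity, optional Gaussian PSF and additive
noise; somata are stamped as solid ellipsoids (z-compressed).  The
chromogenic ("dab") modality drops contiguous sub-threshold-radius
stretches before rasterization; the threshold is not a free dial but the
length-weighted quantile of radii on a calibration sample
(`calibrate_detection_threshold`, tie-aware so the dropped fraction is
exact).  The pipeline calibrates once per experiment on sectioned
control material (~150 cells, quantile stable to ~1 pp).  Stack rotation
about the vertical axis uses trilinear interpolation with zero padding
(scipy.ndimage); binarization is Otsu by default and skeletons are
1-pixel (scikit-image).  Image-mode cycloid counting is deliberately
conservative: hits are connected runs along the sampled cycloid path
(runs closer than ~1.5 px merged), so pixel-level grazing can only lose
events relative to geometric counting, matching the known direction of
projection-masking bias.

## Probes

**Isotropic virtual planes.** Orientations are area-uniform on the
hemisphere (cos θ uniform — mean |z| exactly ½); the family phase is
uniform in [0, d).  Plane areas inside the box are exact clipped-polygon
areas; ΣQ uses the half-open signed-distance rule (a crossing exactly on
a plane belongs to the segment on its negative side), making tie-breaks
deterministic.  Plane–curve crossings are counted after clipping curves
to the box, so edge correction reduces to guard zones around the box —
full frame-edge rules are not reproduced; unbiasedness is enforced by
the property suite instead, including the all-parallel-segments stress
case.  `probe_lv` pools ΣQ and Σa over placements before forming the
ratio, and by default probes each drawn orientation together with its
two cyclic axis permutations (each still isotropic) — a
systematic-orientation design that cuts orientation variance roughly
five-fold on anisotropic scenes without affecting the expectation.  The
sampling-box dimensions are a configurable assumption (60 × 60 × 12 µm
default in the probe config; 60 × 60 × 20 µm mid-depth in the pipeline)
— the emulated protocol does not publish them.

**Cycloids on vertical projections.** The grid tiles columns of cycloid
arcs running along the vertical axis (minor axis perpendicular to it,
the orientation required for length estimation from vertical
projections; the 90°-rotated system is kept only as an orientation-guard
stress case and fails horizontal scenes by >30%).  Successive periods
mirror their bulge; with rolling radius r = spacing/4 the mirrored
tiling covers the plane so densely that vertical structures are counted
with zero variance.  a/l = π·spacing/4 independent of r.  Arcs are
subdivided into ≤0.25 µm chords (crossing counts verified against an
orientation-test oracle); crossings are counted per polyline, so
processes overlapping in projection still contribute separate hits in
geometric mode.  With the five fixed angles (0–144°), projected-length
weights deviate from 2/π by at most ±3.3% depending on azimuth (+1.7%
for x-parallel, −3.3% for z-parallel structures); this protocol ripple
is inside every stated tolerance and vanishes for isotropic scenes.
Reference volumes come from a square point grid with random offset ×
slab depth.  The grid constant (a/l = 25 µm) and point spacing (20 µm)
are config parameters — the emulated protocol does not publish its
values; all angles are counted with equal weight and per-angle counts
are kept for diagnostics.

**Optical disector.** Systematic grids of half-open boxes with uniform
random start; only fully interior boxes are kept, so the realized area
fraction matches the target up to the edge rows (exact for fraction 1,
which tiles the region).  The density estimator pools counts and volumes
(unbiased for any placement since boxes are independent of the point
process).  The soma reference point is the centroid.

**Vertical rotator.** Measurement lines with spacing h (default 1 µm)
and random phase; each boundary chord contributes its exact
solid-of-revolution shell integral, so off-axis and indented profiles
are handled without the l⁺/l⁻ approximation (which it reduces to for
axis-containing convex profiles).  Profiles of model somata are computed
analytically: central quadric sections ("section" mode, unbiased over
rotation — used in closed-form validation) or projection silhouettes via
the Schur complement of the rotated quadric ("silhouette" mode — what
rotated maximum projections actually show; it overestimates volume by
~5% on the soma population, reported as a diagnostic, and the
three-angle protocol mean stays within 10% of the regime targets).

**CE.** For per-section values f with covariogram terms A, B, C:
Var_SRS = [3(A − noise) − 4B + C]/240 (m = 1; divisor 12 for m = 0),
CE² = (noise + Var_SRS)/(Σf)², noise defaulting to Σf for count data;
Var_SRS is floored at 0 and fewer than three sections fall back to the
noise-only CE with a warning.  m = 1 is the default, the standard choice
for count data in this methodology; whether the emulated study used
m = 0 or m = 1 is not stated, and its printed mean CEs (8.6%/13.3%) are
not recomputable from published data — the pipeline's own mean CEs land
in the same range (~8%/~11%).

## End-to-end workflow and problem sizes

`run_experiment` simulates n_sides = 3 sides per regime: 300 × 300 ×
120 µm reference blocks (70 µm halo), three 40-µm sections each,
z-collapse 0.75.  Per side it estimates L_V twice — virtual planes on
thin-depleted ("DAB") curves pooled over systematically sampled boxes,
and cycloid counts on 4-µm vertical-projection substacks at several
systematically placed spots per section ("IF") — plus N_V by disector
and L_N = L_V/N_V (exact by construction on every computed row).
Sampling fractions are doubled relative to the bench protocol (planes
20%, disector 80%, preserving its 4× ratio) because the desk-scale
region is orders of magnitude smaller than a real nucleus outline; this
restores the bench counting effort (~100–300 intersections and ~50–200
cells per side) and with it comparable CEs.  One master seed fans out to
per-stage child seeds; identical (config, seed) give identical reports.

Two between-stain comparisons are reported.  The *paired* deficit counts
the same plane probes in the same boxes on full vs thin-depleted curves;
it isolates the detection loss from tissue fluctuations and is stable at
≈30 ± 3 pp across seeds.  The *report-level* deficit compares the two
L_V routes as estimated, which sample different subvolumes; clustered
arbors make local length density fluctuate 10–20% at probe scale
(30–50 µm), so this deficit scatters more widely (±8 pp) around the same
value — a realistic property of the workflow, not an artefact.  The same
heterogeneity is why end-to-end ratio recoveries are tested against each
run's realized ground truth with tolerances of max(2 × pooled CE, 15–20%)
rather than against the nominal ×5/×2.5 alone.

## Worked-example arithmetic

The bundled reference table stores the published per-side means.  The
derived percentages fix one pooling convention per statistic — the
arithmetic that reproduces each printed integer: deafferentation ratios
compare the deafferented side to the contralateral side of the same
animals (the length-density increase averages the two per-stain ratios);
between-stain differences pool the two control sides per stain and are
expressed relative to the larger mean; the single-cell-reconstruction
comparison pools both control fluorescence sides against both
reconstruction sides; the soma excess compares pooled regime means.
Rounding is half-away-from-zero to integer percent.  The
deafferented-side between-stain differences (reported as 4% and 26%)
come from per-animal paired computations whose per-animal values were
never published; no pooling of the per-side means reproduces them, so
`ref-check` flags them as not derivable instead of computing something
else.  The published L_N column is itself a per-animal mean of ratios,
so no L_N = L_V/N_V consistency is asserted on the stored table (the
pipeline enforces it on computed rows).

## Known limitations

* Projection masking in image-mode cycloid counting is quantified, not
  corrected; the geometric mode is the unbiased reference.
* The z-length-compression shortfall under shrinkage is uncorrectable by
  thickness rescaling (see above) and cancels only in ratios.
* Five fixed projection angles carry the ±3.3% orientation ripple noted
  above; scenes dominated by a single orientation inherit it.
* The simulator's homogeneous blocks cannot probe estimator behaviour
  under laminar gradients; within-animal heterogeneity of microgliosis
  is an open modelling question.
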