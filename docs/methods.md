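# Methods

## Coordinate conventions

Volumes are 3-D arrays indexed (i, j, k) in file-axis order, 0-based, with
world coordinates `origin + direction @ (spacing * ijk)` in millimetres.
NIfTI is the primary on-disk format, NRRD the alternate; both carry spacing
and orientation and are handled by SimpleITK. Integer HU is stored as
16-bit signed, real HU as 32-bit float. DICOM series reading is out of
scope.

The stem coordinate system is built from three landmarks (stem center, stem
tip, head/neck point): ŷ = unit(center − tip), x̂ = the component of
(neck − center) orthogonal to ŷ, ẑ = x̂ × ŷ. Landmarks within 1° of
collinearity are rejected. The frame is invariant to uniform scaling of the
landmark distances.

**Left hips.** Results are reported "as if all hips were right-sided":
positive x = medial, y = superior, z = anterior. To keep every frame
right-handed (det +1), the left-hip frame negates x̂; the migration engine
and the measurement correspondingly mirror the x component when mapping
between the reported convention and the stem grid. The net effect is that a
medially shifted left stem is both *recorded* and *measured* as positive x,
and mirrored left/right phantoms give identical reported values. The
mirrored-x bookkeeping lives in exactly two places (`_grid_shift` in the
engine, `_to_stem_frame` in the measurement) so it cannot half-apply.

## Resampling ("rotation") model

The simulator's "3-D rotation of the CT" is implemented as resampling onto a
grid whose axes are parallel to the stem frame; the "inverse rotation"
resamples back onto the original grid. Both are grid changes in a fixed
world space, so the forward and inverse rigid transforms compose to the
identity exactly, independent of interpolation error. The stem-grid spacing
defaults to the CT spacing permuted to the closest-aligned axes, so a
one-voxel protocol step stays comparable to the baseline spacing (for a
stem along the scanner axis, the stem y step inherits the axial spacing).
The output grid covers the voxel-centre bounding box of the input and is
sized so that an axis-aligned frame reproduces the input grid exactly —
this makes the zero-shift follow-up bit-identical to the baseline in the
axis-aligned case, a useful end-to-end null test.

Interpolation is linear for HU and always nearest-neighbour for labels
(preserving label identity); out-of-volume padding is −1024 HU (air).
Neither choice is claimed to match any particular clinical tool; they are
the conservative defaults.

## Migration engine

Inside the stem grid the implant voxels (stem + head labels) are moved by a
pure integer array translation — no interpolation — so the applied
displacement is exact by construction and the ground truth is exactly
`shift × stem-grid spacing`. Shifts that would push any implant voxel out
of the grid raise, naming the offending axis. Destination voxels previously
holding other tissue are overwritten (physical implants displace tissue);
the overwritten fraction is returned for monitoring. Voxels in neither the
source nor the destination of the implant mask are bit-identical to the
input.

Vacated voxels (source ∖ destination) are relabelled soft tissue and filled
in two steps: (1) each receives the HU of its nearest donor voxel
(Euclidean distance scaled by the physical spacing, via a distance
transform) where donors are soft-tissue-labelled voxels outside the vacated
and implant sets — bone is deliberately never a donor; if no donor exists
anywhere, the nearest non-implant voxel is used; (2) a mean filter of
radius 1 voxel (configurable, 0 disables) is applied to the vacated voxels
only, averaging the filled and surrounding non-implant values. Filling
happens in frame space, before the inverse resampling.

## Shift protocol

Per baseline: one-voxel steps −4…+4 along x and z, −5…+5 along y (the axial
spacing is finer, so more steps span a similar physical range), zeros
included per family — 29 one-axis shifts; for each axis pair (a, b), all
a ∈ ±1…±4 with b = ±a (16 per pair) plus one dedicated zero — 49 two-axis
shifts; 78 in total, 780 over a ten-baseline cohort (90/110/90 one-axis and
490 two-axis follow-ups). The zero shift is emitted once per one-axis
family plus once in the two-axis family because the per-family counts and
the precision pools require it; the manifest records them as distinct rows
even though the images are identical.

Precision pooling: for axis q, every follow-up generated along the *other*
two one-axis families has zero true migration on q, giving pools of
20 (x), 18 (y), 20 (z) per baseline — 200/180/200 over ten baselines, drawn
from 290 distinct follow-ups.

## Phantom generator

The phantom emulates what the simulator needs from a post-operative hip CT,
not anatomy: a tapered-cylinder stem (tip radius 0.45× the top radius)
along a centerline tilted 10° from the scanner axis by default, a neck
cylinder at 45° ending in a spherical head, all at 3000 HU; a cortical bone
cylinder (1200 HU) coaxial with the stem, separated from it by a 2 mm
soft-tissue canal so fill donors exist where vacated voxels appear; a
soft-tissue ellipsoid (40 HU) in air (−1000 HU). HU levels follow typical
clinical ranges; the spec of the emulated cohort gives none. Defaults:
96×96×128 voxels at (0.7812, 0.7812, 0.45) mm — the modal spacing of the
ten-scan cohort the simulator is designed around; the ten cohort spacings
(in-plane 0.72–0.86 mm, axial 0.45–0.6 mm) are available as presets.
Geometry (26 mm stem, 5 mm radius, 4.5 mm head) is desk-scale: real stems
are ~150 mm, but the method only needs a well-defined centerline, neckline
and fill neighbourhood, and small volumes keep the test suite fast; the
cohort runs use a further-scaled 64×64×96 phantom. The implant must clear
every volume face by ≥ 6 voxels so the whole shift protocol stays in
bounds; violations raise at generation time.

Optional additive Gaussian noise (image only, never labels) and cosmetic
radial streak "artifacts" (implant voxels untouched) are seeded and fully
deterministic. Left-sided phantoms are exact sagittal mirrors of the
right-sided construction.

What the phantom does *not* emulate: beam hardening, photon starvation,
scanner-dependent noise texture, anatomical bone morphology, the pelvis and
cup. Tests passing on phantoms therefore demonstrate the *simulation and
evaluation machinery*, not clinical measurement performance.

## Measurement stand-in

The bundled measurement is intentionally simple and fully transparent;
it replaces nothing clinical and claims no clinical accuracy. Metal is
segmented by HU threshold (default 2500, between bone and implant levels)
keeping the largest 26-connected component. Translation is either the
difference of HU-weighted centroids of the metal masks, or the integer-voxel
normalised cross-correlation peak of the metal neighbourhood with optional
parabolic sub-voxel refinement, expressed in the stem frame. Femur-to-femur
registration is omitted because the simulator never moves the femur.
Rotation is not measured (a threshold/centroid method cannot credibly
estimate rotation of a near-symmetric solid); the evaluation layer accepts
externally computed rotation differences so zero-rotation precision tables
remain available for any tool's output.

On a noise-free axis-aligned phantom the whole loop is exact: integer shifts
commute with the permutation grid, fill never crosses the metal threshold,
and centroid recovery errors are at machine precision. With a tilted stem
frame, linear resampling smears the metal boundary and the thresholded
centroid acquires a bias up to ~0.15 mm along the stem axis; this is a
property of the deliberately naive stand-in, not of the simulation, whose
ground truth remains exact.

## Evaluation statistics

Differences are truth − measured throughout. SD uses the sample (n−1)
denominator. Precision under zero migration is 1.96 × SD of the pooled
differences. Bland–Altman limits of agreement are mean ± 1.96 × SD with
the *true* migration on the abscissa (any directional bias is then directly
visible); the 95% CI of the mean uses SD/√n and of each limit the standard
Bland–Altman standard error SD·√(3/n). Q-Q data use probability points
(i − 0.5)/n against a normal with the sample mean and SD. Single-record
summaries report SD = 0 with an explicit flag. Tables display three
decimals; internal computation is never rounded.

## Numerical and design notes

- Orthonormality of frames is enforced to 1e-9 after an SVD
  re-orthonormalisation; grid congruence tolerance is 1e-6 mm.
- The manifest CSV round-trips floats exactly (repr on write,
  round-trip parsing on read) and validates truth = shift × spacing
  bitwise on load.
- Nearest-donor fill ties (equidistant donors) are resolved by the distance
  transform's internal order; the brute-force oracle in the tests agrees
  exactly off ties and bounds the filled values by the donor HU range.
- The two-axis protocol enumerates {a ∈ ±1…±max, b ∈ ±a} literally,
  giving 4·max shifts per pair (16 at the default max of 4).
- Whether vacated voxels are filled before or after the inverse rotation is
  an open choice; filling precedes it here so donors are looked up on the
  undistorted stem grid.

## Problem sizes

Unit tests run on 64×64×96 phantoms; the end-to-end recovery check uses one
noise-free 96×96×128 phantom through all 78 shifts, and the cohort check
ten 64×64×96 phantoms (780 follow-ups, 15 HU noise, alternating sides,
cohort spacings). These sizes were chosen so the whole validation runs on a
laptop-class single CPU in a few minutes while still exercising every code
path at clinically representative voxel spacings.
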