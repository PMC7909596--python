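# Methods

## The measurement problem

Three-dimensional optical scanners deliver a body surface as a triangular
mesh — a list of 3D vertices and a list of vertex-index triples — but every
manufacturer locates its own, undocumented measurement sites.  `anthroscan`
implements a device-independent pipeline that turns any such mesh into
eleven standard circumferences (chest, waist, hip, and left/right upper
arm, thigh, calf, ankle), plus the statistics used to compare those digital
values against flexible-tape reference measurements.

The pipeline is: canonical alignment → face repair → hole filling →
landmark detection → body segmentation → site location → circumference.

## Canonical frame

All processing happens in a body-centred frame: +z up with z = 0 at the
lowest vertex, the subject's left at +x, anterior toward −y, units cm.
(The frame is right-handed; with "+z up" and "+x subject-left" fixed, the
anterior direction necessarily falls on −y.)  Alignment uses the principal
axes of the *surface-area-weighted* face-centroid distribution — vertex
clouds are useless for this because scanners (and our phantom generator)
sample body parts at wildly different densities.  Two sign ambiguities are
resolved anatomically:

* **up/down** — the body end that splits into more connected surface
  patches (two legs/feet vs. one head) is down; tie-break by the sign of
  the third moment along the axis;
* **front/back** — the feet protrude anteriorly, so the area-weighted
  skewness of the anterior–posterior coordinate is negative toward −y.

Alignment is idempotent and scale-preserving.  Note that the principal
axis of an asymmetric body is not exactly the vertical: re-canonicalizing
an already well-posed scan can tilt it by up to ~1°, which perturbs
transverse circumferences by well under 0.1%.

## Repair and hole filling

`repair` drops faces with repeated vertex indices, faces below the
1e-6 cm² area threshold, and duplicate faces (same unordered index
triple); vertices are never moved, so repair is idempotent.  `fill_holes`
walks the directed boundary edges into loops (deterministic start at the
lexicographically smallest vertex; non-manifold tangles are reported, not
fatal) and patches each loop with a fan around one inserted centre vertex.
The centre sits at the umbrella-smoothing fixed point (the boundary-ring
mean) and is lifted along the boundary-ring vertex normals — a
first-order continuation of the surrounding curvature, so patches on a
curved limb bulge with the limb instead of capping it flat.

## Landmarks

Seven surface landmarks anchor everything: crotch, left/right armpit,
shoulder and foot.  Only superficial geometry exists in a scan, so the
detectors operate on transverse cross-sections:

* **crotch** — the lowest height whose transverse section contains a
  single central contour (one whose convex hull covers the point
  (0, y̅) on the body column) while the section just below shows two
  separate leg contours.  Coarse scan at 5 mm over 25–60% of body height,
  bisection refinement to 1 mm.  Legs whose contours come within 0.2 cm
  of each other are declared non-separable — the known failure mode for
  subjects with adjacent inner thighs.
* **armpits** — per side, the highest section in the 55–90% band showing
  an arm contour strictly disjoint from the torso contour and lateral of
  it (centroid beyond the torso's extreme |x| minus 1 cm); bisection to
  1 mm; the landmark is the medial-most contour point just below the
  merge.  Contours under 10 cm² are never treated as limb sections: a
  plane grazing a noisy, near-horizontal surface patch emits small
  spurious loops that would otherwise masquerade as arms.
* **shoulders** — highest vertex within a 3 cm search cylinder above each
  armpit (widened once to 6 cm before failing).
* **feet** — lowest vertex on each side of the sagittal plane; ties break
  by smallest |x|, then lexicographically, making detection bit-stable.

## Segmentation

Legs are the connected face patches below the horizontal crotch plane,
grouped left/right by patch-centroid sign; patches straddling the sagittal
plane (e.g. trunk geometry caught just below the cut) stay with the trunk.
Each arm is cut by the plane spanned by its shoulder→armpit segment and
the anterior–posterior axis; arm faces lie lateral to the plane and must
be connected to the face farthest from the armpit (the hand).  Faces are
assigned whole, by centroid — the partition is an exact disjoint cover,
at the cost of one-face-width jitter along the cuts.  The head and neck
remain in "center"; no measurement uses them.

## Circumferences

The tape analog is the perimeter of the *planar convex hull* of a
cross-section contour — a flexible tape bridges concavities.  The raw
contour perimeter is available as an option (`hull ≤ raw` always).  Trunk
sites are transverse sections of the full mesh, selecting the contour that
contains the trunk's footprint centroid; limb sites section perpendicular
to the limb axis — the dominant principal direction of the segment's
vertex cloud, pointed distally — selecting the contour around the local
segment centroid.  In an A-pose scan the arm axis sits at roughly 45° to
the vertical, so arm sections are markedly non-horizontal.

Site rules (all bands configurable; defaults are this package's geometric
conventions for palpation-defined sites that are unobservable on a
surface):

| site | rule | band (normalized) |
|---|---|---|
| chest | max hull perimeter | 0.70–1.00 of crotch→armpit |
| waist | min hull perimeter | 0.35–0.70 of crotch→armpit |
| hip | max hull perimeter | 0.00–0.35 of crotch→armpit |
| upper arm | fixed fraction | 0.25 of shoulder→hand extent |
| thigh | fixed fraction | 0.25 of crotch→foot extent |
| calf | max hull perimeter | 0.55–0.80 of crotch→foot |
| ankle | min hull perimeter | 0.85–0.95 of crotch→foot |

Extremum sweeps use 2 mm plane spacing; ties break toward the lower plane
offset.  All eleven measurements are scale-equivariant, invariant to
rotation about the vertical, and swap exactly under mirror reflection.

## Comparison statistics

For paired digital (DA) and conventional tape (CA) readings the package
reports, per site and device: Δ = mean(DA) − mean(CA); a paired two-sided
t test (t = d̄/(s_d/√n), df = n − 1; identical pairs give t = 0, p = 1; a
constant nonzero offset is degenerate certainty, p = 0); OLS of DA on CA
with R² and the regression standard error RMSE = √(SSE/(n−2)) — a paired
RMSD √(mean d²) is reported separately to avoid ambiguity; and a
Bland–Altman analysis (bias, bias ± 1.96 SD limits, and the slope of
d on the pair means for proportional bias).  Significance tiers are
p < 0.05, < 0.01, < 0.0001, with no multiple-testing correction — each
site/device comparison is reported at its per-test level, matching how
such validation tables are conventionally presented.

## The synthetic phantom

Real scans cannot ship with the package, so tests and the acceptance
script run on a parametric A-pose phantom: stacked polygonal rings form a
trunk (elliptical sections, 1.25:1 width:depth so the thighs fit under the
hips), two legs, two arms tilted 45° from vertical and clipped flat at
shoulder height, a head, and two box feet protruding anteriorly (which
also pins the front/back sign during alignment).  Radius profiles are
piecewise linear with *plateaus at the eleven sites*, so ground truth is
closed form: a circular ring of radius r at resolution n has perimeter
2·n·r·sin(π/n); trunk truth is the exact perimeter of the generated
elliptical ring polygon.  The arm is placed so its surface is exactly
tangent to the trunk at the armpit height — the armpit detector's target —
and overlaps the trunk above it, as merged geometry does in real scans.

Defaults model a 175 cm adult: crotch 80, armpit 140, shoulder 150 cm,
leg gap 4 cm, ring resolution 96 (~1 cm lateral resolution, typical of
consumer depth scanners; recovery experiments use 360).  `degrade_mesh`
injects the classic artifacts: holes carved at the crotch and below the
armpits (the self-occluded regions), and isotropic Gaussian vertex noise.
`leg_gap = 0` produces touching thighs and `arm_gap = 0` arms subsumed
into the trunk silhouette — both exercise the documented failure paths,
not measurements.

What the phantom does *not* emulate: realistic body-shape variation
(it is a union of generalized cylinders, not a statistical shape model),
pose variation, motion artifacts, clothing, or scanner-specific
distortion fields.  Passing the recovery tests therefore demonstrates
that the geometry engine is exact on known ground truth and robust to
holes and noise — not that site conventions match any particular
scanner's output on real bodies.

## Numerical choices and limitations

* Section planes are offset by a fixed sub-resolution epsilon (≈1.2e-4 cm)
  so sweeps never slice exactly through a vertex ring or a flat cap.
* Unit auto-inference maps the bounding-box height into the plausible
  adult stature band 120–220 cm by a factor of 0.1, 1 or 100; anything
  else demands explicit units.
* The convex hull of a noisy contour rides the outward noise excursions:
  at vertex noise σ = 0.2 cm the hull perimeter carries a systematic
  +1–2 cm bias depending on site radius and vertex density.  This is a
  property of the tape-analog convention itself, of the same order as the
  ~2 cm systematic differences reported between digital and tape
  anthropometry; the degradation tests budget 2 cm per site for it.
* Landmark detection assumes separable legs and arms; subjects whose
  thighs touch or whose arms press against the trunk raise typed errors
  rather than returning wrong measurements.
* Hole patches are single-vertex fans: adequate for the ≤3 cm holes
  scanners produce at occluded regions, not for reconstructing large
  missing areas.
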