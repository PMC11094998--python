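# Methods

## The measurement

On one axial CT slice per vertebral level — the slice closest to the
vertical centre of the vertebra — three markers define the transverse
morphometry of that vertebra:

- **m1**: the centre of the vertebral body;
- **m2**: the end tip of the spinous process, or its in-plane projection
  (absent when no clear tip is identifiable);
- **m3**: the point where the straight line through m1 and m2 crosses the
  nearest outer body contour beyond m2 (computed, never user-set).

The Euclidean distances `L12 = |m1 − m2|` and `L13 = |m1 − m3|` are
computed from pixel positions and per-axis pixel spacings. Both are
transverse-plane distances; in a deformed spine the m1→m2 axis generally
leaves the sagittal plane, and L12 deliberately does **not** equal the
anatomical spinous-process length because vertebral rotation out of the
axial plane is ignored.

Coordinate convention, repo-wide: slice arrays are `(row, col)` 0-based;
`+col` is patient-left, `+row` posterior (supine LPS); mm coordinates are
index × spacing, so pixel centres sit at integer indices. In mm space we
write `(x, y) = (col·col_spacing, row·row_spacing)`.

## Body contour and quadrant areas

The outer body contour is extracted by marching squares at a fixed
iso-level (default **−300 HU**, configurable), keeping the closed contour
that encloses the **largest area** — internal bone or air contours are
smaller by construction. Saddle-cell ambiguity is resolved by the
implementation's standard higher-value-connected rule. No smoothing is
applied. If the above-threshold region touches the image border, the body
is cut by the field of view and extraction fails rather than returning an
open outline.

Two axis-parallel lines through m1 divide the contour-enclosed area into
four quadrants `a1` (anterior-right), `a2` (anterior-left), `a3`
(posterior-left), `a4` (posterior-right). All areas come from the
Surveyor's (shoelace) formula; the clipping itself is done with shapely
box intersections. Clip slivers below 1e−9 mm² are treated as zero. The
two **area aspects** are

    f_back = (a3 + a4) / total        (posterior-half fraction)
    f_left = (a2 + a3) / total        (left-half fraction)

These are the binding outputs; the numbering of the four quadrants is a
bookkeeping convention (fixed as above), chosen so that the two aspects
have unambiguous anatomical meaning.

## Equal-area ellipse mapping

To compare vertebral-body positions across patients with different body
shapes, the aspects are mapped into a fixed generalized ellipse. The area
fraction of an ellipse beyond a chord at normalized offset `t` is

    F(t) = 1/2 − (t·√(1−t²) + arcsin t)/π ,

independent of both semi-axes (area fractions are affine-invariant), so no
ellipse is ever fitted to a contour. The normalized position is
`u = F⁻¹(f_left)`, `v = F⁻¹(f_back)` (+u patient-left, +v posterior),
each chord computed independently — for extreme aspect pairs `(u, v)` may
fall outside the inscribed ellipse, which is accepted as a property of the
construction. Inversion uses Brent's bracketed root finder on `[−1, 1]`
(`xtol` default 1e−10); F is strictly decreasing so the bracket is
guaranteed. The sign convention is pinned by the round-trip property: for
an exact ellipse contour, quadrants → aspects → mapping recovers the
point's normalized coordinates (a posterior vertebra maps to a posterior
position). The 1.5 : 1 display aspect ratio of the plotted ellipse is
cosmetic only.

## Cohort classification and aggregation

- **Severity** from the largest Cobb angle: mild `< 20°`, strong `> 40°`,
  medium for all in between — the boundary values 20° and 40° are medium.
- **Region** from the apex of the main curve (largest angle; ties break
  toward the more cranial apex): thoracic T2–T11, thoraco-lumbar T12/L1,
  lumbar L2–L5. *Combined* requires at least one thoracic-range **and**
  one lumbar-range apex; thoraco-lumbar apexes alone never trigger it. A
  main apex outside T2–L5 (e.g. C7) is unclassifiable and raises an error.
- **Aggregation**: per group and level, arithmetic mean and *sample* SD
  (n−1; the estimator is our choice) of L12 and L13. Missing L12 (no
  identifiable spinous tip) is excluded from mean and count. Regional rows
  ("T2...T11", "T12/L1", "L2...L5", "all") pool all (patient, level)
  values in the region rather than per-level means, so their SDs mix
  between-patient and between-level spread; "all" includes every measured
  level (C7 and T1 when present). Both conventions are interpretations
  fixed here and kept consistent everywhere, including the brute-force
  oracle.
- The findings report is descriptive (no inference): per group it
  evaluates SD(L13) > SD(L12), the mild < medium < strong ordering of
  SD(L13), upper-thoracic level ratios, and whether the regional row with
  maximal SD(L13) coincides with the group's curve region.

## The phantom and what it does (not) emulate

The synthetic slice is an analytic closed contour
`r(θ) = r_ellipse(θ; a_lr, a_ap) + A·exp(−Δθ²/2w²)` — an ellipse plus a
Gaussian posterior bulge emulating a rib hump on the convex side — filled
with soft tissue (+40 HU) over air (−1000 HU), containing a bony
(+1000 HU) vertebral disk and a ~2.5 px-wide spinous bar. Rendering uses
4×4 sub-pixel coverage averaging (a partial-volume edge, as in real CT);
Gaussian noise (default sd 20 HU, a typical soft-tissue CT noise level) is
truncated at ±4 sd so a −300 HU threshold can never misclassify air.
Defaults: semi-axes 150 × 100 mm and 0.7 mm in-plane spacing (an adult
torso at common CT resolution), 5 mm slice step, vertebral body 25 mm
posterior of the contour centre with a 55 mm process — placing L12/L13 in
the 50–80 mm range typical of thoracic levels. Specs whose bone would
leave the contour are rejected.

Ground truth is analytic: m2 from the process geometry, m3 by bracketed
root finding on the ray–contour equation, and quadrant fractions by
clipping a 50 000-vertex sampling of the analytic contour (inscribed-
polygon area error ∼n⁻² ≈ 5e−9, comfortably below the 1e−6 agreement we
require against the closed-form ellipse-segment formula). A deliberately
independent occupancy-counting oracle on a 0.1 mm grid cross-checks the
quadrant areas to 0.5%.

The phantom has no lungs, ribs, organs, bone texture, beam hardening or
partial overlap of structures; multi-slice volumes are stacks of
independent per-slice specs without longitudinal curvature continuity.
Passing tests therefore demonstrate the correctness of the *geometry and
measurement machinery* under controlled conditions, not robustness to
anatomical segmentation pitfalls in clinical scans.

## Numerical notes

- **Threshold sensitivity.** The marching-squares iso-line sits where the
  interpolated intensity equals the level; with an air→tissue contrast of
  1040 HU the line shifts ≈ Δlevel/1040 px per Δlevel. Over a ±100 HU
  window around −300 HU the enclosed area of the default phantom varies by
  ≈0.3% (measured 0.31%, matching the perimeter × shift estimate) — the
  property test asserts < 0.4%. The extracted area also sits ≈0.17 px
  inside the true edge because −300 HU is not the 50% coverage level; this
  bias stays well inside the 1% symmetric-difference budget.
- **Marker rounding.** Annotators produce integer pixel positions; with
  m1 and m2 each rounded, L12/L13 recover truth within
  max(1 px-diagonal, 1 mm) — the tolerance used throughout.
- **Skin crossing.** The ray m1→m2 is intersected with every polygon
  edge; the crossing with the smallest parameter t > 1 (strictly beyond
  m2) is taken, which automates the "nearest outer contour" choice
  deterministically. Half-open edge intervals avoid double-counting
  vertices.
- **Determinism.** Phantoms are seeded (`numpy` Generator, bit-identical
  per seed); pipeline CSVs use fixed 6-significant-digit formatting and
  carry version/config/input hashes, so re-runs are byte-identical.
- **Degenerate inputs** rejected with specific errors: m1 = m2, centre on
  or outside the contour, fractions outside (0, 1), polygons with < 3
  vertices, non-positive spacings, apexes outside C7–L5.

## Problem sizes used in the verification suite

Regular 360-gon for the shoelace closed form; 1000 random star/convex
polygons for quadrant conservation (1e−9 relative); 20 phantom contours
(half with rib hump) against the 0.1 mm occupancy oracle (0.5%);
201-point grid and 99-fraction round trip for the ellipse closed form
(1e−8 / 1e−9); 50 random interior points for the ellipse round trip (1% of
the semi-axes); 20 seeded phantoms for L12/L13 recovery
(max(1 px-diag, 1 mm)) and contour symmetric difference (1%); 100 random
cohorts against brute-force aggregation; one phantom pipeline run twice
for byte-identical outputs. `scripts/acceptance.py` re-runs the same
checks at slightly reduced counts and reports the measured values.

## Known limitations

- Marker placement is manual by design; no vertebra detection is
  attempted.
- Cobb angles are inputs (from coronal radiographs); nothing here measures
  them.
- Vertebral axial rotation is not analysed.
- The severity/region SD orderings are descriptive diagnostics on whatever
  cohort is supplied; the package makes no claims about their clinical
  generality.
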