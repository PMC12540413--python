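# Methods

`rowturn` implements a three-stage vision pipeline for visualizing a
headland turn in ridge-planted row crops, plus a synthetic-scene generator
that provides exact ground truth for every stage.  This note records the
models, the parameters that matter, the numerical choices, and the known
limitations.

## Coordinate frames and camera model

Three frames are used throughout:

- **World** `(X_W, Y_W, Z_W)`: ground-anchored; `Z_W` is the vehicle's
  forward direction, `Y_W` height above the ground plane (`Y_W = 0`), and
  `X_W` lateral — negative to the right of the `Z_W` axis, positive to the
  left.
- **Camera** `(X_C, Y_C, Z_C)`: obtained by rotating the world frame about
  `X_W` by the pitch `γ` and translating the origin to `T` (default
  `T = (0, 2, 0)` m, camera 2 m above ground).  The transforms are

      P_W = R_X(γ)⁻¹ · P_C + T,      P_C = R_X(γ) · (P_W − T),

  with `R_X(γ)` the elementary rotation about X.
- **Image** `(u, v)`: top-left origin, `u` rightward, `v` downward,
  continuous sub-pixel coordinates; rounding happens only at draw time.
  Projection is the pinhole model `u = f_x·X_C/Z_C + c_x`,
  `v = f_y·Y_C/Z_C + c_y`, optionally preceded by a 5-coefficient
  radial–tangential distortion `(k1, k2, p1, p2, k3)` applied to the
  normalized coordinates.  The all-zero model is the identity.

**Pitch sign.**  The component-form expansions of the world↔camera
transforms are stated (and unit-tested) at `γ = +30°`.  With that sign the
optical axis points 30° *above* the world horizontal, so a camera 2 m over
a ground plane cannot image the field at working distances.  A camera
mounted "60° to the ground" physically pitches the axis *below* the
horizontal; the synthetic scenes and the default pipeline configuration
therefore use `γ = −30°` — the same rotation machinery with the
field-facing sign.  Rendering, localization and path projection all share
one `CameraPose`, so the system is self-consistent under either sign.
A side effect of combining a Y-up camera frame with v-down pixel
coordinates is a vertical flip: near ground appears toward the top of the
synthetic image and far ground toward the bottom.  Every stage (ROI
strips, termination-band heuristic, projection) uses the same convention,
so no stage depends on the "photographic" orientation.

## Stereo localization

Depth follows triangulation, `Z_C = f·B/d`, with focal length `f` in
pixels, baseline `B` in meters, and disparity `d` in pixels
(`d ≤ 0` is invalid).  Defaults `f = 400` px, `B = 0.075` m match a small
machine-vision stereo head.  A pixel at known depth lifts to
`X_C = (u−c_x)·Z_C/f_x`, `Y_C = (v−c_y)·Z_C/f_y`.

A detection's bounding box is reduced to one 3D point by taking the box
center as `(u, v)` and the **median of the valid disparities in the
central 50% × 50% sub-box** as `d`.  The median resists box edges that
straddle background; the sub-box is built with odd extents symmetric about
the integer center pixel, so for a disparity field that varies only with
`v` (any ground plane under a pitch-only pose) the median reduces exactly
to the center pixel's value and exact-disparity localization is recovered
to machine precision.

Error metrics are per-axis absolute differences, their Euclidean norm, and
the relative error (Euclidean error over the norm of the true coordinates,
in percent).  Everything is computed at full precision; rounding to the
3-decimal reporting convention happens only in tables.

## Row segmentation

Vegetation is separated in HSV space: a pixel is crop if
`H ∈ [70°, 170°]`, `S ∈ [0.25, 1]`, `V ∈ [0.20, 1]` (all configurable).
The band is deliberately generous: soil (`H ≈ 20–35°`), straw
(`H ≈ 40–60°`) and multiplicative shadow (which scales V but leaves H and
S unchanged) all stay outside it.

The mask is cleaned by a staged opening schedule: pass `i` erodes with a
`(6−i, 6−i)` rectangle then dilates with `(i, i)`, for `i ∈ {1, 3, 5}` —
three passes, every kernel positive.  Early passes erode hard (speckle
removal), later passes dilate hard (edge smoothing).  Structuring elements
are filled rectangles and pixels outside the image are background.  Note
that each pass erodes at least as hard as it dilates, so the schedule is
anti-extensive: the output is contained in the opening of the input by a
5×5 rectangle, and disjoint components are never merged.

External contours of the surviving 8-connected components are filled
(holes included) and kept when their area reaches `min_area`
(default 500 px² at 640×480, scaled by image area).

## Feature points and centerline fit

Full-width horizontal ROI strips (height 40 px, laid out every 60 px from
`y = 0`; strips that would overrun the bottom edge are dropped) are
intersected with each filled contour by a bitwise AND.  Each connected
piece of the intersection with area ≥ 50 px² contributes its center of
mass `(ΣxC/ΣC, ΣyC/ΣC)` as a sub-pixel feature point, grouped by contour.

Each contour's centroid set is fit by **orthogonal (total) least squares**:
the line passes through the centroid mean with direction equal to the
principal axis of the scatter, minimizing the perpendicular sum of squared
distances.  (A printed form of this objective that repeats `v_y` in both
residual terms is degenerate; the perpendicular-distance form is the
meaningful one and is what the principal-axis solution minimizes.)  The
direction is canonicalized to `v_y ≥ 0` (ties toward `v_x > 0`); the
orientation `β = atan2(v_y, v_x)` is reported in degrees in `(−90°, 90°]`
relative to the horizontal image axis.  Endpoints at `x = 0` and `x = W`
are attached when `|v_x| ≥ 10⁻⁶`; near-vertical lines fall back to
top/bottom-edge intersections.

Accuracy against a ground-truth *standard line* is the signed deviation
`θ` = fitted orientation − standard orientation, wrapped to `(−90°, 90°]`.
In image coordinates this makes `θ` negative when the fitted line's upper
end sits at smaller `u` than the standard line's (deviation to the left).
The magnitude agrees with the slope formula
`arctan |(m₂−m₁)/(1+m₁m₂)|` wherever that is defined, and the
orientation-difference form stays finite for perpendicular pairs.
Summaries report the signed mean, the mean absolute error and the maximum
absolute error.

## Arc turn planning

Given the headland's world position `(X_W, Z_W)` on the ground plane and
the row azimuth `β_deg`:

- radius `R = min(|X_W|, |Z_W|)`, required to exceed the vehicle's minimum
  turning radius (`R_min`, default 1.5 m — a typical small-tractor value);
- center `O = (sign(X_W)·R, 0, Z_W − R)` when the turn is laterally
  limited (`R = |X_W| < |Z_W|`), else `O = (sign(X_W)·R, 0, 0)`;
- swept angle `α = β_deg` for `β_deg > 0`, else `180° + β_deg`
  (`β_deg = 0` is an error, not a guess).

The arc is anchored so its start lies on the vehicle's forward axis
(`X = 0`), which the center rules make geometrically consistent, and
traversed as `P(t) = O + R·(−sign(X_W)·cos t, 0, sin t)`, `t ∈ [0, α]`
(default 100 samples).  A straight lead-in connects the origin to the arc
start at the same spacing when they differ.  The waypoint chain is
interpolated by a **natural cubic spline** in X and Z parameterized by
cumulative chord length — natural boundary conditions and chord-length
parameterization are conventional choices where none is prescribed — giving
C² continuity at every interior knot.

Because `α` depends only on `β_deg`, the arc terminal coincides with the
target exactly only in the laterally-limited case with `α = 90°`; in
general there is a residual offset, which the planner reports as a
`terminal_offset` diagnostic rather than silently clipping the arc.

Projection of the planned path into the image drops points with
`Z_C ≤ 0` (counted), projects the rest with distortion applied analytically
inside the forward model, clamps out-of-frame pixels to the border
(counted), and draws filled discs (radius 3 px, green by default).

## Synthetic scenes

The generator emulates the planting and camera geometry of a ridged
soybean field: three rows per ridge on the platform centerline and at
±0.225 m, ridge base 1.100 m, platform 0.700 m, ridge height 0.250 m, and
a camera 2 m above ground pitched 30° toward it, 640×480 with
`f_x = f_y = 400` px.  Rows run along a configurable world azimuth
(90° = straight ahead) from 1.2 m to 5.0 m along-row; the unplanted band
past the termination is the headland.

Every pixel's depth is the exact ray/ground-plane intersection under the
package's own transforms; disparity is `f·B/depth`.  Plants are filled
discs of jittered green hue (`H ∈ [95°, 140°]`) with radius 0.07 m every
0.08 m along the row — within-row soybean seed spacing is typically
3–8 cm, and this spacing keeps the canopy band nearly closed, so the
opening schedule removes clutter without eating genuine row area.  Plants
drop out independently with a missing-plant probability (fractured rows).
Clutter presets (low/medium/high) control beige straw streaks drawn on the
soil, a smooth multiplicative shadow field, and the dropout probability.

Recorded truth per scene: the per-row *standard line* (joining the
midpoints of the row band's top and bottom edges — midpoints are taken
over a thin end slice rather than the single extreme pixel row, whose
midpoint is the tilted band's corner tip and would bias the reference
orientation), the per-row true orientation, the crop mask and row-id map,
the headland bounding box (integer center enforced), the headland world
position (the ground point under the box center), and the dense depth map.
Identical (config, seed) pairs produce bit-identical outputs.

**What the generator does not emulate:** plant height (depth is
ground-plane depth — adequate at 2 m camera height for V3–V8 canopies),
photorealistic texture, stereo-matcher failure modes (disparity is exact
or absent), weeds with crop-like color, and inter-ridge adhesion beyond
what blob overlap and dropout produce.  Passing the synthetic benchmarks
therefore demonstrates the geometric and algorithmic consistency of the
pipeline, not field-robustness of the color segmentation.

## Benchmark problem sizes

The bundled evaluation (`scripts/acceptance.py`, mirrored by the test
suite) uses 20 scenes at 640×480 spanning azimuths 60–120° with clutter
cycling low/medium/high, a size at which the statistics are stable across
seeds while the whole evaluation stays interactive (~10 s).  Orientation
recovery is scored as the mean absolute deviation between matched fitted
and standard lines (greedy one-to-one matching by horizontal distance at
the standard line's mid-height); headland localization is scored from the
exact disparity map against the recorded world position.

## Known limitations

- The heuristic headland stub (termination band below the last crop
  pixels) is a placeholder for a real detector; its box differs from the
  truth box, so stub-based localization inherits that offset.
- Rows nearly dead ahead give `|X_W| < R_min` and the planner correctly
  refuses the turn; the CLI surfaces the error and keeps earlier artifacts.
- All angle statistics assume undirected lines; behavior at exactly ±90°
  relies on the `(−90°, 90°]` wrap and is covered by tests.
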