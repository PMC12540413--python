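# rowturn

Headland-turn steering-path visualization for ridge-planted row crops.

When a wheeled agricultural machine reaches the **headland** — the
unplanted strip at the end of the crop rows — it must turn into the next
pass.  `rowturn` implements the vision pipeline that makes that turn
visible in the camera image:

1. **Row segmentation** — HSV green thresholding of the RGB field image,
   a staged morphological opening (pass *i* erodes with a (6−*i*, 6−*i*)
   rectangle and dilates with (*i*, *i*), for *i* ∈ {1, 3, 5}), and
   area-filtered contour extraction.
2. **Centerline orientation** — full-width ROI strips (40 px tall, every
   60 px) are intersected with each row contour; the centers of mass of
   the screened intersections are fit by orthogonal least squares, giving
   each row's centerline and its orientation β ∈ (−90°, 90°] to the
   horizontal image axis.
3. **Stereo localization** — a detected headland box is lifted to 3D via
   `Z_C = f·B/d` (median disparity of the box core) and
   `X_C = (u−c_x)·Z_C/f_x`, `Y_C = (v−c_y)·Z_C/f_y`, then into the world
   frame by the rigid camera pose.
4. **Arc planning** — turn radius `R = min(|X_W|, |Z_W|)` (> R_min),
   center per the lateral/forward case rules, swept angle α = β (β > 0)
   or 180° + β (β < 0); a straight lead-in plus the sampled arc is
   smoothed by a natural cubic spline on chord length.
5. **Projection** — the world-frame path is projected back through the
   pinhole model with radial–tangential distortion, clamped to the image
   boundary, and drawn as an overlay.

A seeded synthetic-scene generator reproduces the target planting
geometry (three soybean rows per ridge at centerline ±0.225 m, ridge base
1.100 m, platform 0.700 m, camera 2 m above ground pitched 30°) with
straw/shadow/missing-plant clutter and *exact* ground truth — per-row
standard lines, crop masks, headland box and world position, dense depth —
so every stage is testable without any dataset.  See
[`docs/methods.md`](docs/methods.md) for the models and design choices.

## Worked example

Generate a scene with rows angled 62° in the world frame and run the full
pipeline on it:

```sh
python -c "
from rowturn.synthetic_scenes import SceneConfig, render_scene
render_scene(SceneConfig(seed=5, row_azimuth_deg=62.0, straw_streaks=6,
                         shadow_strength=0.1,
                         missing_plant_prob=0.02)).write('demo/scene')"
rowturn run demo/scene/image.png demo/scene/disparity.tif --out demo/out
```

which logs

```
INFO rowturn: segmentation: 3 contours, 15 feature points, 3 lines
INFO rowturn: headland at world (2.379, -0.000, 5.159)
INFO rowturn: path: 189 waypoints, 0 dropped, 36 clamped
artifacts written to demo/out
```

`demo/out/orientations.json` holds the three fitted row orientations,
`{"0": 75.14, "1": 81.20, "2": 69.60}` degrees — the scene's recorded
truth is `[81.18, 75.17, 70.17]`, i.e. each row is recovered to well
under a degree (contour ids and row ids are ordered differently).
`demo/out/arc_spec.json` holds the planned turn

```json
{"R": 2.379, "O": [2.379, 0.0, 2.781], "alpha_deg": 75.31,
 "direction": "left", "terminal_offset_m": 0.608}
```

a left turn of radius 2.38 m centered at (2.38, 0, 2.78); the terminal
offset is the planner's diagnostic for how far the arc end misses the
target when α ≠ 90°.  `overlay.png` shows the fitted centerlines and the
projected path; `waypoints.csv` holds the world-frame path.

Other commands:

```sh
rowturn simulate --out fixtures --n 20 --seed 1     # fixture suite + truth
rowturn evaluate fixtures --out summary.json        # re-run + score vs truth
rowturn evaluate --deviations-csv devs.csv --out s.json
rowturn evaluate --localization-csv pairs.csv --out s.json
```

Exit codes: 0 success, 2 input error, 3 config error, 4 pipeline-stage
failure.  All commands accept `--config` (YAML; schema in
`rowturn/config.py`, unknown keys rejected).

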