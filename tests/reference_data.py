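"""Published benchmark values used as test inputs.

``LOCALIZATION_ROWS``: ten (true, measured, dX, dY, dZ, euclidean,
relative_pct) records from a stereo-localization accuracy experiment with
the target fixed at X=1 m, Y=2 m and Z swept from 1 to 10 m.

``ANGULAR_DEVIATIONS_DEG``: eleven signed angular deviations (degrees)
between fitted crop-row centerlines and their reference standard lines,
three image groups (a: V3-V4, b: V5-V6, c: V7-V8).
"""

LOCALIZATION_ROWS = [
    # (true, measured, dX, dY, dZ, euclidean, relative_pct) as printed
    ((1.000, 2.000, 1.000), (1.010, 1.990, 0.990), 0.010, 0.010, 0.010, 0.017, 0.707),
    ((1.000, 2.000, 2.000), (0.990, 2.030, 1.960), 0.010, 0.030, 0.040, 0.051, 1.700),
    ((1.000, 2.000, 3.000), (1.020, 2.030, 2.950), 0.020, 0.030, 0.050, 0.062, 1.657),
    ((1.000, 2.000, 4.000), (1.020, 2.040, 4.150), 0.020, 0.040, 0.150, 0.157, 3.424),
    ((1.000, 2.000, 5.000), (0.960, 2.070, 5.180), 0.040, 0.070, 0.180, 0.197, 3.597),
    ((1.000, 2.000, 6.000), (1.030, 1.920, 5.780), 0.030, 0.080, 0.220, 0.236, 3.686),
    ((1.000, 2.000, 7.000), (1.040, 1.930, 7.260), 0.040, 0.070, 0.260, 0.272, 3.702),
    ((1.000, 2.000, 8.000), (0.970, 2.080, 7.650), 0.030, 0.080, 0.350, 0.360, 4.333),
    ((1.000, 2.000, 9.000), (1.060, 2.110, 9.350), 0.060, 0.110, 0.350, 0.372, 4.011),
    ((1.000, 2.000, 10.000), (0.950, 2.120, 9.430), 0.050, 0.120, 0.570, 0.585, 5.709),
]

ANGULAR_DEVIATIONS_DEG = [
    -3.9, 0.9, 1.0, -5.0,  # group a
    4.8, 3.0, 3.9, 0.1,    # group b
    1.9, -7.0, -4.9,       # group c
]

# Published summary statistics of the eleven deviations
DEVIATION_MEAN = -0.473
DEVIATION_MAE = 3.309
DEVIATION_MAX = 7.000

# Relative-error band bounds (percent) by true-range band
ERROR_BANDS = [
    (0.0, 3.0, 2.0),
    (3.0, 7.0, 4.0),
    (7.0, 10.0, 6.0),
]
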