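"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives a quantity by a different route than the library:
set-based morphology, angular grid search for the orthogonal regression,
a direct tridiagonal solve for the natural cubic spline, and a scalar
term-by-term evaluation of the lens-distortion polynomial.
"""

from __future__ import annotations

import math

import numpy as np


# --- set-based binary morphology (pixels outside the image are 0) ---

def set_erode(mask: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """A pixel survives iff the whole (kh, kw) window centered on it is 1."""
    h, w = mask.shape
    oh, ow = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr in range(-oh, kh - oh):
                for dc in range(-ow, kw - ow):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def set_dilate(mask: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """A pixel turns on iff any pixel of the reflected window is 1."""
    h, w = mask.shape
    oh, ow = kh // 2, kw // 2
    out = np.zeros_like(mask, dtype=bool)
    rs, cs = np.nonzero(mask)
    for r, c in zip(rs, cs):
        for dr in range(-(kh - 1 - oh), oh + 1):
            for dc in range(-(kw - 1 - ow), ow + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    out[rr, cc] = True
    return out


def set_open_schedule(mask: np.ndarray, iterations=(1, 3, 5)) -> np.ndarray:
    out = mask.astype(bool)
    for i in iterations:
        e = 6 - i
        if e > 1:
            out = set_erode(out, e, e)
        if i > 1:
            out = set_dilate(out, i, i)
    return out


# --- angular grid search for perpendicular least squares ---

def grid_search_angle(points: np.ndarray, step_deg: float = 0.01) -> float:
    """Orientation in (-90, 90] minimizing the perpendicular SSE.

    Scans candidate directions and, for each, sums squared distances of the
    centered points to the line through the centroid.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    angles = np.arange(-90.0 + step_deg, 90.0 + step_deg, step_deg)
    rad = np.deg2rad(angles)
    # distance to line with direction (cos a, sin a): |(-sin a, cos a) . p|
    proj = np.outer(-np.sin(rad), centered[:, 0]) + np.outer(np.cos(rad), centered[:, 1])
    sse = (proj**2).sum(axis=1)
    return float(angles[int(np.argmin(sse))])


# --- minimal angle between two undirected lines ---

def minimal_angle_between(deg_a: float, deg_b: float) -> float:
    """Smallest angle between two undirected line orientations, in [0, 90]."""
    d = abs(deg_a - deg_b) % 180.0
    return min(d, 180.0 - d)


# --- natural cubic spline via a direct tridiagonal solve ---

def natural_spline_eval(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Evaluate the natural cubic interpolant by solving for the second
    derivatives M with the classical tridiagonal system (M_0 = M_n = 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    h = np.diff(x)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = 1.0
    A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2.0 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, rhs)
    out = np.empty_like(np.asarray(xq, dtype=float))
    for j, q in enumerate(np.atleast_1d(xq)):
        i = int(np.clip(np.searchsorted(x, q) - 1, 0, n - 2))
        dx1 = x[i + 1] - q
        dx0 = q - x[i]
        out[j] = (
            M[i] * dx1**3 / (6 * h[i])
            + M[i + 1] * dx0**3 / (6 * h[i])
            + (y[i] / h[i] - M[i] * h[i] / 6) * dx1
            + (y[i + 1] / h[i] - M[i + 1] * h[i] / 6) * dx0
        )
    return out


# --- scalar radial-tangential distortion, term by term ---

def distort_point_scalar(x: float, y: float, k1: float, k2: float,
                         p1: float, p2: float, k3: float) -> tuple[float, float]:
    r2 = x * x + y * y
    r4 = r2 * r2
    r6 = r4 * r2
    radial = 1.0 + k1 * r2 + k2 * r4 + k3 * r6
    xd = x * radial
    xd = xd + 2.0 * p1 * x * y
    xd = xd + p2 * (r2 + 2.0 * x * x)
    yd = y * radial
    yd = yd + p1 * (r2 + 2.0 * y * y)
    yd = yd + 2.0 * p2 * x * y
    return xd, yd
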