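"""Keypoint-to-circle estimation.

The supervised tracking route places five keypoints on the air-sac
outline.  Per frame, keypoints with pose-network likelihood strictly
above a threshold (default 0.6) are kept; if at least three survive, the
circle minimizing the geometric least-squares objective

    F(a, b, r) = sum_i (d_i - r)^2,   d_i = sqrt((x_i-a)^2 + (y_i-b)^2)

is estimated with Landau's fixed-point iteration.  With exactly three
non-collinear points the minimizer is the circumcircle (zero residual),
which is also provided in closed form.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import Circle, FitConfig, KeypointFrame, OUTLINE_PARTS, RadiusSeries


class DegenerateGeometryError(ValueError):
    """Raised when the input points are (numerically) collinear."""


class InsufficientPointsError(ValueError):
    """Raised when fewer than three points are available for a fit."""


def filter_outline_points(
    frame: KeypointFrame, cfg: FitConfig = FitConfig()
) -> list[tuple[float, float]]:
    """Return outline keypoints whose likelihood strictly exceeds the threshold.

    Only the five outline parts are fit inputs; facial keypoints (lips,
    nose, eye bridge) are excluded regardless of likelihood.  The
    comparison is strict (likelihood > threshold), so points at exactly
    the threshold are dropped.
    """
    out = []
    for part in OUTLINE_PARTS:
        if part not in frame.points:
            continue
        x, y, lik = frame.points[part]
        if lik > cfg.likelihood_threshold:
            out.append((float(x), float(y)))
    return out


def _check_collinear(pts: np.ndarray) -> None:
    centered = pts - pts.mean(axis=0)
    span = float(np.abs(centered).max())
    if span == 0.0:
        raise DegenerateGeometryError("all points coincide")
    # smallest singular value of the centered point cloud, relative to span
    s = np.linalg.svd(centered, compute_uv=False)
    if s[-1] ** 2 <= 1e-12 * span**2:
        raise DegenerateGeometryError("points are collinear")


def circumcircle(
    p1: Sequence[float], p2: Sequence[float], p3: Sequence[float]
) -> Circle:
    """Closed-form circle through three non-collinear points.

    Solves the perpendicular-bisector linear system; all three points lie
    on the returned circle to numerical precision.
    """
    pts = np.asarray([p1, p2, p3], dtype=np.float64)
    if len({tuple(p) for p in pts}) < 3:
        raise DegenerateGeometryError("points must be pairwise distinct")
    _check_collinear(pts)
    (x1, y1), (x2, y2), (x3, y3) = pts
    a = np.array([[x2 - x1, y2 - y1], [x3 - x1, y3 - y1]])
    b = 0.5 * np.array(
        [x2**2 - x1**2 + y2**2 - y1**2, x3**2 - x1**2 + y3**2 - y1**2]
    )
    cx, cy = np.linalg.solve(a, b)
    r = float(np.hypot(x1 - cx, y1 - cy))
    return Circle(float(cx), float(cy), r, n_points_used=3, converged=True)


def landau_fit(
    points: Sequence[Sequence[float]], cfg: FitConfig = FitConfig()
) -> Circle:
    """Geometric least-squares circle via Landau's fixed-point iteration.

    Starting from the arithmetic centroid of the points, each iteration
    sets r to the mean point-to-center distance and moves the center to
    the stationary point of F at that radius:

        c_new = mean(p_i) + r * mean(u_i),   u_i = (c - p_i) / d_i.

    Iteration stops when the center moves less than ``cfg.tol`` pixels
    (``converged=True``) or after ``cfg.max_iter`` iterations
    (``converged=False``; the last iterate is still returned).

    Raises
    ------
    InsufficientPointsError
        For fewer than three points.
    DegenerateGeometryError
        For collinear points.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise InsufficientPointsError(
            f"need >= 3 points, got {0 if pts.ndim != 2 else pts.shape[0]}"
        )
    _check_collinear(pts)
    if pts.shape[0] == 3:
        return circumcircle(*pts)

    c = pts.mean(axis=0)
    mean_p = c.copy()
    r = 0.0
    converged = False
    for _ in range(cfg.max_iter):
        diff = c - pts
        d = np.hypot(diff[:, 0], diff[:, 1])
        if np.any(d == 0.0):
            # center landed exactly on a data point; nudge off it
            d = np.maximum(d, 1e-12)
        r = float(d.mean())
        u = diff / d[:, None]
        c_new = mean_p + r * u.mean(axis=0)
        shift = float(np.hypot(*(c_new - c)))
        c = c_new
        if shift < cfg.tol:
            converged = True
            break
    return Circle(
        float(c[0]), float(c[1]), r, n_points_used=int(pts.shape[0]),
        converged=converged,
    )


def fit_objective(points: Sequence[Sequence[float]], circle: Circle) -> float:
    """Geometric least-squares objective sum_i (d_i - r)^2 for a circle."""
    pts = np.asarray(points, dtype=np.float64)
    d = np.hypot(pts[:, 0] - circle.x, pts[:, 1] - circle.y)
    return float(np.sum((d - circle.radius) ** 2))


def fit_frame(frame: KeypointFrame, cfg: FitConfig = FitConfig()) -> Circle | None:
    """Filter one frame's keypoints and fit a circle; None if < 3 survive."""
    pts = filter_outline_points(frame, cfg)
    if len(pts) < 3:
        return None
    try:
        return landau_fit(pts, cfg)
    except DegenerateGeometryError:
        return None


def fit_series(
    frames: Sequence[KeypointFrame], cfg: FitConfig = FitConfig(), fps: float = 25.0
) -> RadiusSeries:
    """Fit a circle per frame; frames with < 3 surviving keypoints are missing.

    ``frames`` must be ordered by frame index.  Returns one entry per
    input frame.
    """
    entries: list[tuple[int, Circle | None]] = []
    for frame in frames:
        entries.append((frame.frame_index, fit_frame(frame, cfg)))
    return RadiusSeries(fps=fps, entries=entries)
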