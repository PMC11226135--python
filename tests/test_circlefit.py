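import numpy as np
import pytest
from scipy import optimize

from sactrack.circlefit import (
    DegenerateGeometryError,
    InsufficientPointsError,
    circumcircle,
    filter_outline_points,
    fit_objective,
    fit_series,
    landau_fit,
)
from sactrack.types import Circle, FitConfig, KeypointFrame, OUTLINE_PARTS

from conftest import circle_points


def brute_force_circle(pts):
    """Independent geometric least-squares oracle: multi-start simplex over
    the center (radius eliminated in closed form as the mean distance)."""
    pts = np.asarray(pts, dtype=float)

    def obj(c):
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return float(np.sum((d - d.mean()) ** 2))

    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = max(hi - lo)
    starts = [pts.mean(axis=0)]
    for dx in (-2, 0, 2):
        for dy in (-2, 0, 2):
            starts.append(pts.mean(axis=0) + span * np.array([dx, dy]))
    best = None
    for s in starts:
        res = optimize.minimize(
            obj, s, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    d = np.hypot(pts[:, 0] - best.x[0], pts[:, 1] - best.x[1])
    return best.x, d.mean(), best.fun


def outline_frame(likelihoods, extras=None, frame_index=0):
    pts = {
        part: (float(i), float(i * 2), lik)
        for i, (part, lik) in enumerate(zip(OUTLINE_PARTS, likelihoods))
    }
    if extras:
        pts.update(extras)
    return KeypointFrame(frame_index, pts)


# ---------------------------------------------------------------------------
# likelihood filtering


def test_filter_strict_threshold_count():
    frame = outline_frame([0.9, 0.5, 0.7, 0.61, 0.3])
    assert len(filter_outline_points(frame)) == 3


def test_filter_at_threshold_drops_all():
    frame = outline_frame([0.6] * 5)
    assert filter_outline_points(frame) == []


def test_filter_excludes_facial_parts():
    frame = outline_frame([0.1] * 5, extras={"Nose": (50.0, 50.0, 0.99)})
    assert filter_outline_points(frame) == []


def test_filter_custom_threshold():
    frame = outline_frame([0.5, 0.5, 0.5, 0.5, 0.5])
    cfg = FitConfig(likelihood_threshold=0.4)
    assert len(filter_outline_points(frame, cfg)) == 5


# ---------------------------------------------------------------------------
# circumcircle


@pytest.mark.parametrize(
    "p1,p2,p3,center,radius",
    [
        (((0, 1)), ((1, 0)), ((0, -1)), (0, 0), 1.0),
        (((0, 0)), ((2, 0)), ((1, 1)), (1, 0), 1.0),
    ],
)
def test_circumcircle_known(p1, p2, p3, center, radius):
    c = circumcircle(p1, p2, p3)
    assert (c.x, c.y) == pytest.approx(center, abs=1e-12)
    assert c.radius == pytest.approx(radius, abs=1e-12)


def test_circumcircle_collinear():
    with pytest.raises(DegenerateGeometryError):
        circumcircle((0, 0), (1, 1), (2, 2))


def test_circumcircle_points_on_circle(rng):
    for _ in range(50):
        pts = rng.uniform(-10, 10, (3, 2))
        try:
            c = circumcircle(*pts)
        except DegenerateGeometryError:
            continue
        d = np.hypot(pts[:, 0] - c.x, pts[:, 1] - c.y)
        assert np.abs(d - c.radius).max() < 1e-9


# ---------------------------------------------------------------------------
# Landau fit


def test_landau_exact_on_circle():
    pts = circle_points(5, 5, 10, np.linspace(0, 2 * np.pi, 8, endpoint=False))
    c = landau_fit(pts)
    assert (c.x, c.y, c.radius) == pytest.approx((5, 5, 10), abs=1e-7)
    assert c.converged and c.n_points_used == 8


def test_landau_three_points_is_circumcircle():
    c1 = landau_fit([(0, 1), (1, 0), (0, -1)])
    c2 = circumcircle((0, 1), (1, 0), (0, -1))
    assert (c1.x, c1.y, c1.radius) == (c2.x, c2.y, c2.radius)


def test_landau_matches_brute_force_on_noisy_arc(rng):
    for _ in range(5):
        n = int(rng.integers(10, 30))
        th = rng.uniform(0, np.pi, n)
        pts = circle_points(40, 30, 25, th) + rng.normal(0, 1.0, (n, 2))
        fit = landau_fit(pts)
        _, _, f_oracle = brute_force_circle(pts)
        assert fit_objective(pts, fit) <= f_oracle + 1e-6


def test_landau_insufficient_points():
    with pytest.raises(InsufficientPointsError):
        landau_fit([(0, 0), (1, 1)])


def test_landau_collinear():
    with pytest.raises(DegenerateGeometryError):
        landau_fit([(0, 0), (1, 1), (2, 2), (3, 3)])


def test_landau_nonconvergence_flag(rng):
    th = rng.uniform(0, np.pi, 12)
    pts = circle_points(0, 0, 10, th) + rng.normal(0, 1.0, (12, 2))
    c = landau_fit(pts, FitConfig(tol=1e-15, max_iter=1))
    assert not c.converged
    assert c.radius > 0


def test_landau_translation_rotation_equivariance(rng):
    th = rng.uniform(0, np.pi, 15)
    pts = circle_points(0, 0, 12, th) + rng.normal(0, 0.5, (15, 2))
    base = landau_fit(pts)
    shift = np.array([17.0, -4.0])
    ang = 0.7
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = pts @ rot.T + shift
    c2 = landau_fit(moved)
    expected_center = rot @ np.array([base.x, base.y]) + shift
    assert (c2.x, c2.y) == pytest.approx(tuple(expected_center), abs=1e-6)
    assert c2.radius == pytest.approx(base.radius, abs=1e-6)


def test_landau_beats_subset_circumcircles(rng):
    # local optimality: the fit is at least as good as the circle through
    # any 3 of the points
    for _ in range(10):
        n = int(rng.integers(5, 10))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = circle_points(10, -3, 8, th) + rng.normal(0, 0.8, (n, 2))
        fit = landau_fit(pts)
        f_fit = fit_objective(pts, fit)
        for _ in range(10):
            idx = rng.choice(n, 3, replace=False)
            try:
                cc = circumcircle(*pts[idx])
            except DegenerateGeometryError:
                continue
            assert f_fit <= fit_objective(pts, cc) + 1e-9


def test_five_point_redundancy():
    # dropping any 2 of 5 noiseless outline points leaves the fit unchanged
    angles = np.deg2rad([180, 135, 90, 45, 0])
    pts = circle_points(100, 80, 60, angles)
    full = landau_fit(pts)
    for i in range(5):
        for j in range(i + 1, 5):
            keep = [k for k in range(5) if k not in (i, j)]
            sub = landau_fit(pts[keep])
            assert sub.radius == pytest.approx(full.radius, abs=1e-6)


# ---------------------------------------------------------------------------
# series fitting


def test_fit_series_counts_missing():
    frames = []
    for i in range(10):
        liks = [0.9] * 5 if i not in (3, 7) else [0.9, 0.9, 0.1, 0.1, 0.1]
        angles = np.deg2rad([180, 135, 90, 45, 0])
        pts = circle_points(50, 40, 30, angles)
        frames.append(
            KeypointFrame(
                i,
                {
                    part: (float(x), float(y), lik)
                    for part, (x, y), lik in zip(OUTLINE_PARTS, pts, liks)
                },
            )
        )
    series = fit_series(frames)
    missing = [f for f, c in series if c is None]
    assert missing == [3, 7]


def test_fit_series_empty():
    assert len(fit_series([])) == 0


def test_fit_series_recovers_planted_radii(small_cfg):
    from dataclasses import replace

    from sactrack.synthetic import generate_keypoints, simulate_trajectory

    cfg = replace(small_cfg, keypoint_jitter_sd=0.0, dropout_prob=0.0, n_frames=12)
    truth = simulate_trajectory(cfg)
    series = fit_series(generate_keypoints(truth, cfg))
    assert np.abs(series.radii() - truth.radii()).max() < 1e-6
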