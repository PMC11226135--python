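"""Kolmogorov-Zurbenko (KZ) smoothing with missing-frame handling.

KZ(m, k) is k successive applications of a centered moving average of odd
window m.  In the interior this equals convolution with the k-fold
self-convolution of the uniform kernel (for m=3, k=2: [1,2,3,2,1]/9).  At
run boundaries the window shrinks symmetrically to the available samples.
Gaps (NaN / missing frames) split a series into runs that are smoothed
independently; gaps are never imputed, so the filter cannot manufacture
radii for frames the tracker rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Circle, RadiusSeries


@dataclass(frozen=True)
class KZConfig:
    """KZ filter settings: odd window length and iteration count.

    The defaults (window 3, 2 iterations) are the settings used for
    smoothing tracked air-sac radii and centroids.
    """

    window: int = 3
    iterations: int = 2

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric shrinking end windows."""
    half = window // 2
    n = len(x)
    out = np.empty_like(x, dtype=np.float64)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def kz_filter(series, cfg: KZConfig = KZConfig()) -> np.ndarray:
    """Apply the KZ filter to a 1D sequence; NaNs mark gaps and are preserved.

    Contiguous non-NaN runs are smoothed independently; runs shorter than
    the window pass through unchanged.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("kz_filter expects a 1D sequence")
    out = x.copy()
    finite = np.isfinite(x)
    # split into contiguous finite runs
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        if run.size < cfg.window:
            continue
        seg = x[run[0] : run[-1] + 1]
        for _ in range(cfg.iterations):
            seg = _moving_average(seg, cfg.window)
        out[run[0] : run[-1] + 1] = seg
    return out


def smooth_series(s: RadiusSeries, cfg: KZConfig = KZConfig()) -> RadiusSeries:
    """KZ-smooth the x, y and radius tracks of a radius series.

    Each track is filtered independently; missing entries stay missing and
    split the series into independently smoothed runs.
    """
    xs = np.array([c.x if c else np.nan for _, c in s])
    ys = np.array([c.y if c else np.nan for _, c in s])
    rs = np.array([c.radius if c else np.nan for _, c in s])
    xs_s, ys_s, rs_s = (kz_filter(a, cfg) for a in (xs, ys, rs))
    entries: list[tuple[int, Circle | None]] = []
    for i, (f, c) in enumerate(s):
        if c is None:
            entries.append((f, None))
        else:
            entries.append(
                (
                    f,
                    Circle(
                        float(xs_s[i]),
                        float(ys_s[i]),
                        float(rs_s[i]),
                        n_points_used=c.n_points_used,
                        converged=c.converged,
                    ),
                )
            )
    return RadiusSeries(fps=s.fps, entries=entries)
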