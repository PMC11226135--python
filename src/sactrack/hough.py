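"""Unsupervised circle tracking with the circle Hough transform.

Each frame runs through a fixed preprocessing chain — grayscale,
brightness/contrast, median blur, Canny edge detection with adaptive
thresholds, dilation, median blur — before accumulator voting over a band
of candidate radii.  The Canny thresholds scale with the mean intensity of
the frame so one parameter set transfers across scenes with different
lighting.  The six chain parameters are tuned per dataset by exhaustive
grid search against manually tracked ground truth, scoring each
combination by the mean per-video Pearson correlation between tracked and
manual radii.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.morphology import dilation as _dilate, footprint_rectangle
from skimage.transform import hough_circle, hough_circle_peaks

from .io import iter_frames
from .types import Circle, GroundTruthAnnotation, RadiusSeries
from .validation import ValidationFilters, pair_frames, pearson

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid preprocessing/detection parameter combinations."""


@dataclass(frozen=True)
class HoughParams:
    """Preprocessing and detection parameters of the Hough tracker.

    Chain parameters (grid-searchable): ``alpha`` (gain) and ``beta``
    (offset) in out = alpha*in + beta; ``blur`` — odd median-blur kernel
    size, px; ``dilation`` — side of the square structuring element applied
    to the edge map (0 disables); ``canny1``/``canny2`` — unitless factors
    mapped to Canny thresholds as mean_intensity * c / 10.

    Detection parameters: ``r_min``/``r_max`` — radius band, px (defaults
    5 and 270); ``radius_step`` — accumulator radius resolution, px;
    ``vote_threshold`` — minimum normalized perimeter support for a peak
    (a clean semicircle scores ~0.5); ``tie_tol`` — relative support
    margin within which peaks count as tied.
    """

    alpha: float = 1.0
    beta: float = 0.0
    blur: int = 5
    dilation: int = 3
    canny1: float = 5.0
    canny2: float = 14.0
    r_min: int = 5
    r_max: int = 270
    radius_step: int = 6
    vote_threshold: float = 0.25
    tie_tol: float = 0.05
    max_peaks: int = 10
    refine: bool = True

    def __post_init__(self) -> None:
        if self.blur < 3 or self.blur % 2 == 0:
            raise ConfigError(f"blur kernel must be odd and >= 3, got {self.blur}")
        if self.r_min >= self.r_max:
            raise ConfigError("r_min must be < r_max")
        if self.canny1 >= self.canny2:
            raise ConfigError("canny1 must be < canny2 (low < high threshold)")
        if self.radius_step < 1:
            raise ConfigError("radius_step must be >= 1")


def siamang_best_params() -> HoughParams:
    """The best chain parameters found for 1920x1080 siamang closeups."""
    return HoughParams(alpha=2.0, beta=30.0, blur=27, dilation=5,
                       canny1=5.0, canny2=14.0)


@dataclass(frozen=True)
class ParamGrid:
    """Per-parameter value lists for exhaustive grid search."""

    alpha: Sequence[float]
    beta: Sequence[float]
    blur: Sequence[int]
    dilation: Sequence[int]
    canny1: Sequence[float]
    canny2: Sequence[float]

    FIELDS = ("alpha", "beta", "blur", "dilation", "canny1", "canny2")

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"empty value list for {name}")

    def __len__(self) -> int:
        return int(np.prod([len(getattr(self, f)) for f in self.FIELDS]))

    def combinations(self):
        lists = [getattr(self, f) for f in self.FIELDS]
        for values in itertools.product(*lists):
            yield dict(zip(self.FIELDS, values))


def default_grid() -> ParamGrid:
    """The published optimization grid (15000 combinations).

    alpha 0.5-3 step 0.5; beta 20-40 step 5; blur {25,27,29,35};
    dilation 3-7 step 1; canny1 4-12 step 2; canny2 {8,10,13,15,17}.
    """
    return ParamGrid(
        alpha=[0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
        beta=[20, 25, 30, 35, 40],
        blur=[25, 27, 29, 35],
        dilation=[3, 4, 5, 6, 7],
        canny1=[4, 6, 8, 10, 12],
        canny2=[8, 10, 13, 15, 17],
    )


# ---------------------------------------------------------------------------
# preprocessing


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """8-bit grayscale view of a frame (RGB/RGBA converted by luminance)."""
    a = np.asarray(frame)
    if a.ndim == 3:
        a = rgb2gray(a[..., :3]) * 255.0
    return np.clip(np.round(a), 0, 255).astype(np.uint8)


def adjust_brightness_contrast(
    frame: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Gain/offset intensity adjustment: clip(alpha*in + beta, 0, 255)."""
    a = np.asarray(frame, dtype=np.float64)
    return np.clip(np.round(alpha * a + beta), 0, 255).astype(np.uint8)


def adaptive_canny_thresholds(
    mean_intensity: float, canny1: float, canny2: float
) -> tuple[float, float]:
    """Map a frame's mean intensity to Canny hysteresis thresholds.

    low = clip(mean*canny1/10, 0, 255), high = clip(mean*canny2/10, 0, 255).
    With the published factors (5, 14) this gives the conventional
    0.5x/1.4x-mean threshold band.
    """
    if not (0.0 <= mean_intensity <= 255.0):
        raise ConfigError(f"mean intensity out of range: {mean_intensity}")
    low = float(np.clip(mean_intensity * canny1 / 10.0, 0, 255))
    high = float(np.clip(mean_intensity * canny2 / 10.0, 0, 255))
    if low >= high:
        raise ConfigError(
            f"degenerate Canny thresholds (low={low}, high={high}); "
            "frame too dark or canny1/canny2 misconfigured"
        )
    return low, high


def preprocess_frame(frame: np.ndarray, p: HoughParams) -> np.ndarray:
    """Run the full preprocessing chain; returns a boolean edge map.

    Order: grayscale -> brightness/contrast -> median blur -> Canny with
    adaptive thresholds -> dilation -> median blur.  Output has the same
    height/width as the input.
    """
    gray = to_grayscale(frame)
    adj = adjust_brightness_contrast(gray, p.alpha, p.beta)
    blurred = median_filter(adj, size=p.blur)
    low, high = adaptive_canny_thresholds(float(blurred.mean()), p.canny1, p.canny2)
    edges = canny(blurred.astype(np.float64), sigma=1.0,
                  low_threshold=low, high_threshold=high)
    if p.dilation > 0:
        edges = _dilate(edges, footprint_rectangle((p.dilation, p.dilation)))
    edges = median_filter(edges.astype(np.uint8), size=p.blur) > 0
    return edges


# ---------------------------------------------------------------------------
# detection


def _best_peak(
    processed: np.ndarray,
    radii: np.ndarray,
    p: HoughParams,
    previous: Circle | None,
) -> tuple[float, float, float] | None:
    acc = hough_circle(processed, radii)
    # rank by raw accumulator votes (support x circumference): normalized
    # support alone lets tiny circles sitting inside a dilated edge blob
    # score a perfect 1.0 and crowd out the real structure.
    weighted = acc * (2.0 * np.pi * radii)[:, None, None]
    votes, cx, cy, rad = hough_circle_peaks(
        weighted, radii, total_num_peaks=p.max_peaks
    )
    support = votes / (2.0 * np.pi * rad)
    keep = support >= p.vote_threshold
    if not keep.any():
        return None
    votes, cx, cy, rad = (a[keep] for a in (votes, cx, cy, rad))
    best = float(votes.max())
    idx = np.flatnonzero(votes >= (1.0 - p.tie_tol) * best)
    if previous is not None and len(idx) > 1:
        dist = np.hypot(cx[idx] - previous.x, cy[idx] - previous.y)
        pick = idx[int(np.argmin(dist))]
    else:
        pick = idx[int(np.argmax(votes[idx]))]
    return float(cx[pick]), float(cy[pick]), float(rad[pick])


def detect_circle(
    processed: np.ndarray, p: HoughParams, previous: Circle | None = None
) -> Circle | None:
    """Best-supported circle in an edge map, or None.

    Votes over radii r_min..r_max at step ``radius_step``, then (when
    ``refine`` is set) re-votes at 1 px resolution around the winning
    radius, so detections resolve single pixels without paying for a
    dense radius sweep.  Peaks below ``vote_threshold`` normalized
    perimeter support are rejected; among survivors the peak with the
    most raw accumulator votes wins, with ties (within ``tie_tol``)
    broken by proximity to ``previous``'s center when given.
    """
    if not processed.any():
        return None
    coarse_radii = np.arange(p.r_min, p.r_max + 1, p.radius_step)
    hit = _best_peak(processed, coarse_radii, p, previous)
    if hit is None:
        return None
    cx, cy, rad = hit
    if p.refine and p.radius_step > 1:
        lo = max(p.r_min, int(rad) - p.radius_step + 1)
        hi = min(p.r_max, int(rad) + p.radius_step - 1)
        fine = _best_peak(processed, np.arange(lo, hi + 1), p, previous)
        if fine is not None:
            cx, cy, rad = fine
    return Circle(cx, cy, rad)


def track_video(
    frames,
    p: HoughParams = HoughParams(),
    fps: float = 25.0,
    crop: tuple[int, int, int, int] | None = None,
) -> RadiusSeries:
    """Track one circle per frame through a frame source.

    ``crop`` is an optional (x, y, w, h) region of interest applied before
    preprocessing; detections are reported in full-frame coordinates.
    Cropping so the circular structure fills the frame improves detection.
    Frames that fail to decode or detect are recorded as missing.
    """
    entries: list[tuple[int, Circle | None]] = []
    previous: Circle | None = None
    for i, frame in enumerate(iter_frames(frames)):
        circle: Circle | None = None
        try:
            img = frame
            if crop is not None:
                x0, y0, w, h = crop
                img = img[y0 : y0 + h, x0 : x0 + w]
            if img.size > 0:
                edges = preprocess_frame(img, p)
                circle = detect_circle(edges, p, previous)
        except ConfigError as exc:
            # frame-dependent degeneracy (e.g. an all-black frame collapses
            # the adaptive Canny band): no detection for this frame
            log.warning("frame %d: %s", i, exc)
            circle = None
        except Exception:  # unreadable/corrupt frame: log and move on
            log.exception("frame %d could not be processed", i)
            circle = None
        if circle is not None and crop is not None:
            circle = Circle(circle.x + crop[0], circle.y + crop[1],
                            circle.radius, circle.n_points_used,
                            circle.converged)
        entries.append((i, circle))
        if circle is not None:
            previous = (
                Circle(circle.x - crop[0], circle.y - crop[1], circle.radius)
                if crop is not None
                else circle
            )
    if not entries:
        raise ValueError("frame source yielded no frames")
    return RadiusSeries(fps=fps, entries=entries)


# ---------------------------------------------------------------------------
# grid optimization


def optimize_params(
    videos: Sequence,
    truth: Sequence[Sequence[GroundTruthAnnotation]],
    grid: ParamGrid | None = None,
    base: HoughParams = HoughParams(),
    filters: ValidationFilters | None = None,
    fps: float = 25.0,
    min_pairs: int = 10,
) -> tuple[HoughParams, pd.DataFrame]:
    """Exhaustive grid search of the preprocessing chain against ground truth.

    Every combination in ``grid`` is scored by the mean over videos of the
    Pearson correlation between tracked and manual radii (validation
    filters applied first).  A video contributing fewer than ``min_pairs``
    usable frame pairs, or an undefined correlation, scores NaN; a
    combination with any NaN video scores NaN overall and ranks below every
    finite score.  Returns the best parameters and the full score table
    (one row per combination, columns for each parameter, per-video r,
    mean r and pair counts).
    """
    if grid is None:
        grid = default_grid()
    if filters is None:
        filters = ValidationFilters()
    if len(truth) != len(videos):
        raise ValueError("truth must align with videos")
    # decode frames once; the grid re-reads them many times
    frame_sets = [list(iter_frames(v)) for v in videos]
    rows = []
    for combo in grid.combinations():
        try:
            p = replace(base, **combo)
        except ConfigError:
            rows.append({**combo, "mean_r": np.nan, "n_pairs": 0})
            continue
        rs, ns = [], []
        for frames, gt in zip(frame_sets, truth):
            try:
                series = track_video(frames, p, fps=fps)
                pairs = pair_frames(series, gt, filters)
            except ConfigError:
                pairs = []
            if len(pairs) < max(min_pairs, 3):
                rs.append(np.nan)
                ns.append(len(pairs))
                continue
            auto, manual = zip(*pairs)
            try:
                r, _ = pearson(auto, manual)
            except ValueError:
                r = np.nan
            rs.append(r)
            ns.append(len(pairs))
        row = dict(combo)
        for i, (r, n) in enumerate(zip(rs, ns)):
            row[f"r_video{i}"] = r
            row[f"n_video{i}"] = n
        row["mean_r"] = float(np.mean(rs)) if not np.any(np.isnan(rs)) else np.nan
        row["n_pairs"] = int(np.sum(ns))
        rows.append(row)
    table = pd.DataFrame(rows)
    scores = table["mean_r"].to_numpy()
    if np.all(np.isnan(scores)):
        best_i = 0
    else:
        best_i = int(np.nanargmax(scores))
    best_combo = {f: table.iloc[best_i][f] for f in ParamGrid.FIELDS}
    for f in ("blur", "dilation"):
        best_combo[f] = int(best_combo[f])
    best = replace(base, **best_combo)
    return best, table
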