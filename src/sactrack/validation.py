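"""Validation of automatic radius tracking against manual ground truth.

Automatic and manual radii are paired frame by frame, radius filters are
applied (radii at or above the tracker's 270 px ceiling and radii below
100 px are discarded, for both sources), and Pearson correlations are
reported per video and pooled over all videos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import GroundTruthAnnotation, RadiusSeries


@dataclass(frozen=True)
class ValidationFilters:
    """Radius band for the comparison: keep radii in [r_min_px, r_max_px).

    Defaults: 100 px floor (smaller radii are not regarded, for either
    dataset) and 270 px ceiling (the tracker's maximum detectable radius,
    which also bounds the manual annotations).
    """

    r_max_px: float = 270.0
    r_min_px: float = 100.0

    def __post_init__(self) -> None:
        if self.r_min_px >= self.r_max_px:
            raise ValueError("r_min_px must be < r_max_px")

    def passes(self, radius: float) -> bool:
        return self.r_min_px <= radius < self.r_max_px


@dataclass(frozen=True)
class ValidationReport:
    """Per-video and pooled correlation between automatic and manual radii.

    ``per_video`` maps video id -> (r, n) with r None where fewer than 3
    usable pairs exist.  ``pooled`` is computed on the concatenation of all
    pairs; ``mean_per_video`` averages the defined per-video coefficients.
    """

    per_video: Mapping[str, tuple[float | None, int]]
    pooled: tuple[float | None, int]
    mean_per_video: float | None


def pair_frames(
    auto: RadiusSeries,
    manual: Sequence[GroundTruthAnnotation],
    f: ValidationFilters = ValidationFilters(),
) -> list[tuple[float, float]]:
    """Frame-matched (auto_radius, manual_radius) pairs after filtering.

    A frame contributes a pair only when the manual annotation exists and
    is trackable, the automatic radius exists, and both radii lie in
    [r_min_px, r_max_px).
    """
    manual_by_frame = {a.frame_index: a for a in manual}
    pairs = []
    for frame, circle in auto:
        ann = manual_by_frame.get(frame)
        if ann is None or not ann.trackable or circle is None:
            continue
        if f.passes(circle.radius) and f.passes(ann.radius):
            pairs.append((circle.radius, ann.radius))
    return pairs


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Requires equal lengths >= 3 and non-zero variance in both inputs.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def validate(
    auto: Mapping[str, RadiusSeries],
    manual: Mapping[str, Sequence[GroundTruthAnnotation]],
    f: ValidationFilters = ValidationFilters(),
) -> ValidationReport:
    """Correlate automatic against manual radii per video and pooled.

    The pooled coefficient concatenates every video's filtered pairs (the
    headline statistic for the keypoint route); the mean of per-video
    coefficients is the convention used for the Hough route — both are
    reported.  Videos with fewer than 3 pairs get a missing per-video
    entry and do not affect the pooled statistic.
    """
    if not auto:
        raise ValueError("need at least one video")
    if set(auto) != set(manual):
        raise ValueError("auto and manual must cover the same video ids")
    per_video: dict[str, tuple[float | None, int]] = {}
    all_pairs: list[tuple[float, float]] = []
    for vid in auto:
        pairs = pair_frames(auto[vid], manual[vid], f)
        all_pairs.extend(pairs)
        if len(pairs) < 3:
            per_video[vid] = (None, len(pairs))
            continue
        xs, ys = zip(*pairs)
        try:
            r, _ = pearson(xs, ys)
        except ValueError:
            per_video[vid] = (None, len(pairs))
            continue
        per_video[vid] = (r, len(pairs))
    pooled: tuple[float | None, int]
    if len(all_pairs) >= 3:
        xs, ys = zip(*all_pairs)
        try:
            pooled = (pearson(xs, ys)[0], len(all_pairs))
        except ValueError:
            pooled = (None, len(all_pairs))
    else:
        pooled = (None, len(all_pairs))
    defined = [r for r, _ in per_video.values() if r is not None]
    mean_r = float(np.mean(defined)) if defined else None
    return ValidationReport(per_video=per_video, pooled=pooled,
                            mean_per_video=mean_r)
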