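"""Core domain types shared across the toolkit.

Coordinate convention: image coordinates — origin at the top-left corner,
x increasing rightward, y increasing downward, units pixels.  Frame indices
are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

#: The five air-sac outline keypoints used for circle fitting.  Two fixed
#: arc ends, the lowest point of the sac, and the two mid-arc points.
OUTLINE_PARTS = (
    "Start_outline_outer_left",
    "Start_outline_outer_right",
    "LowestPoint_outline",
    "MidLowleft_outline",
    "MidLowright_outline",
)

#: Facial keypoints tracked alongside the outline but never used as circle
#: fit inputs.
FACE_PARTS = ("UpperLip", "LowerLip", "Nose", "EyeBridge")

CALL_TYPES = ("boom", "bark", "other")


@dataclass(frozen=True)
class Circle:
    """A circle in image coordinates.

    Parameters
    ----------
    x, y : float
        Center, pixels.
    radius : float
        Radius, pixels; must be positive.
    n_points_used : int
        Number of points that entered the fit (0 when the circle does not
        come from a point fit, e.g. a Hough detection).
    converged : bool
        Whether the producing iteration converged (always True for
        closed-form constructions).
    """

    x: float
    y: float
    radius: float
    n_points_used: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite([self.x, self.y, self.radius]).all():
            raise ValueError("circle parameters must be finite")
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class KeypointFrame:
    """Named 2D keypoints with likelihoods for one video frame.

    ``points`` maps part name -> (x, y, likelihood) with likelihood in
    [0, 1].  Coordinates must be finite whenever likelihood > 0.
    """

    frame_index: int
    points: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        for name, (x, y, lik) in self.points.items():
            if not (0.0 <= lik <= 1.0):
                raise ValueError(
                    f"likelihood for part {name!r} out of [0, 1]: {lik}"
                )
            if lik > 0 and not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(
                    f"non-finite coordinates for part {name!r} at likelihood {lik}"
                )


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """A manually annotated circle for one frame.

    Annotators mark untrackable frames (occlusion, no visible sac) with a
    deliberately tiny circle at the frame edge; such sentinel rows carry
    ``trackable=False``.
    """

    frame_index: int
    center: tuple[float, float]
    radius: float
    trackable: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class CallSegment:
    """A manually annotated call, in frame units.

    ``call_type`` is one of 'boom', 'bark', 'other'.  Within a great-call
    sequence (same ``sequence_id``) segments are non-overlapping and
    ordered.
    """

    call_type: str
    start_frame: int
    end_frame: int
    individual: str = ""
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")

    @property
    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)


class RadiusSeries:
    """Time-indexed circle detections with missing-frame support.

    Entries are an ordered list of ``(frame_index, Circle | None)`` with
    strictly increasing frame indices; ``None`` marks frames where no
    circle could be estimated.  ``fps`` is the video frame rate.
    """

    def __init__(self, fps: float, entries: Iterable[tuple[int, Circle | None]]):
        if fps <= 0:
            raise ValueError("fps must be positive")
        self.fps = float(fps)
        self.entries: list[tuple[int, Circle | None]] = [
            (int(f), c) for f, c in entries
        ]
        idx = [f for f, _ in self.entries]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RadiusSeries):
            return NotImplemented
        return self.fps == other.fps and self.entries == other.entries

    def __repr__(self) -> str:
        return (
            f"RadiusSeries(fps={self.fps}, n={len(self)}, "
            f"valid={sum(c is not None for _, c in self.entries)})"
        )

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f for f, _ in self.entries], dtype=int)

    def radii(self) -> np.ndarray:
        """Radii as a float array, NaN where missing."""
        return np.array(
            [c.radius if c is not None else np.nan for _, c in self.entries]
        )

    def get(self, frame_index: int) -> Circle | None:
        for f, c in self.entries:
            if f == frame_index:
                return c
        return None

    def as_dict(self) -> dict[int, Circle | None]:
        return dict(self.entries)

    @classmethod
    def from_circles(
        cls, fps: float, circles: Iterable[Circle | None], start: int = 0
    ) -> "RadiusSeries":
        return cls(fps, [(start + i, c) for i, c in enumerate(circles)])


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the keypoint-to-circle estimator.

    ``likelihood_threshold`` drops keypoints with pose-network confidence
    not strictly above it (default 0.6).  ``tol`` is the center-displacement
    convergence tolerance of the fixed-point circle fit, in pixels.
    """

    likelihood_threshold: float = 0.6
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.likelihood_threshold <= 1.0):
            raise ValueError("likelihood_threshold must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class AcousticFrameFeatures:
    """Per-video-frame acoustic features.

    ``amplitude`` is linear RMS of the window; ``f0`` is the fundamental
    frequency in Hz or None when the window is unvoiced; ``spectral_centroid``
    is the power-weighted mean frequency in Hz; ``wiener_entropy`` is spectral
    flatness in [0, 1]; ``shannon_entropy`` is the normalized entropy of the
    power spectrum in [0, 1].  Spectral statistics are None for silent
    windows.  ``extra`` carries externally supplied per-frame features.
    """

    frame_index: int
    amplitude: float
    f0: float | None
    spectral_centroid: float | None
    wiener_entropy: float | None
    shannon_entropy: float | None
    extra: Mapping[str, float] = field(default_factory=dict)

    CORE_FEATURES = ("amplitude", "f0", "spectral_centroid",
                     "wiener_entropy", "shannon_entropy")

    def value(self, name: str) -> float | None:
        if name in self.CORE_FEATURES:
            return getattr(self, name)
        return self.extra.get(name)
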