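"""Readers and writers for the toolkit's tabular and media formats.

Supported formats
-----------------
* keypoint tables: the three-header-row pose-table CSV dialect
  (scorer / bodyparts / coords rows, one x,y,likelihood triplet per part),
  plus a flat fallback dialect with columns frame,part,x,y,likelihood;
* manual ground-truth circle annotations exported from Fiji measurements
  (frame id, center x/y, diameter), with a configurable column mapping;
* radius time series as plain CSV with an fps header comment;
* call-segment annotation tables;
* mono PCM WAV audio (scipy);
* frame sources: a directory of numbered PNG/JPEG images, a single image
  file, or an in-memory sequence of arrays.
"""

from __future__ import annotations

import os
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import CallSegment, Circle, GroundTruthAnnotation, KeypointFrame, RadiusSeries


class FormatError(ValueError):
    """Raised when a file does not parse as the declared dialect."""


# ---------------------------------------------------------------------------
# keypoint tables


def _parse_cell(raw, row: int, col: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise FormatError(
            f"non-numeric cell {raw!r} at row {row}, column {col!r}"
        ) from None


def read_keypoint_table(path: str | os.PathLike) -> list[KeypointFrame]:
    """Read a pose-estimation keypoint table into KeypointFrames.

    The primary dialect is the three-header-row CSV written by markerless
    pose trackers (rows: scorer, bodyparts, coords; first column the frame
    index; then x, y, likelihood per body part).  A flat dialect with
    columns ``frame,part,x,y,likelihood`` is also accepted.

    Raises
    ------
    FormatError
        If the header rows are missing/malformed, a cell is non-numeric, or
        a likelihood lies outside [0, 1].
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    head_cols = [c.strip() for c in first.rstrip("\n").split(",")]
    if {"frame", "part", "x", "y", "likelihood"} <= set(head_cols):
        return _read_flat_keypoints(path)
    return _read_pose_table(path)


def _read_pose_table(path: Path) -> list[KeypointFrame]:
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed pose table header: {exc}") from None
    if df.columns.nlevels != 3:
        raise FormatError("expected three header rows: scorer, bodyparts, coords")
    coords_level = [c[-1] for c in df.columns]
    if not {"x", "y", "likelihood"} <= set(coords_level):
        raise FormatError(
            "missing 'coords' header row with x, y, likelihood entries"
        )
    parts: list[str] = []
    for _, part, _ in df.columns:
        if part not in parts:
            parts.append(part)
    frames: list[KeypointFrame] = []
    for row_pos, (idx, row) in enumerate(df.iterrows()):
        pts = {}
        for part in parts:
            triplet = {}
            for scorer, p, coord in df.columns:
                if p != part:
                    continue
                triplet[coord] = _parse_cell(
                    row[(scorer, p, coord)], row_pos, f"{part}/{coord}"
                )
            if not {"x", "y", "likelihood"} <= set(triplet):
                raise FormatError(f"part {part!r} lacks an x,y,likelihood triplet")
            lik = triplet["likelihood"]
            if not (0.0 <= lik <= 1.0):
                raise FormatError(
                    f"likelihood {lik} out of [0, 1] at row {row_pos}, part {part!r}"
                )
            pts[part] = (triplet["x"], triplet["y"], lik)
        frame_index = int(_parse_cell(idx, row_pos, "frame"))
        frames.append(KeypointFrame(frame_index=frame_index, points=pts))
    return frames


def _read_flat_keypoints(path: Path) -> list[KeypointFrame]:
    df = pd.read_csv(path)
    frames: list[KeypointFrame] = []
    for frame_index, grp in df.groupby("frame", sort=True):
        pts = {}
        for row_pos, row in grp.iterrows():
            lik = _parse_cell(row["likelihood"], row_pos, "likelihood")
            if not (0.0 <= lik <= 1.0):
                raise FormatError(
                    f"likelihood {lik} out of [0, 1] at row {row_pos}"
                )
            pts[str(row["part"])] = (
                _parse_cell(row["x"], row_pos, "x"),
                _parse_cell(row["y"], row_pos, "y"),
                lik,
            )
        frames.append(KeypointFrame(frame_index=int(frame_index), points=pts))
    return frames


def write_keypoint_table(
    frames: Sequence[KeypointFrame], path: str | os.PathLike, scorer: str = "sactrack"
) -> None:
    """Write KeypointFrames in the three-header-row pose-table dialect."""
    parts: list[str] = []
    for fr in frames:
        for p in fr.points:
            if p not in parts:
                parts.append(p)
    cols = pd.MultiIndex.from_tuples(
        [(scorer, p, c) for p in parts for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = []
    index = []
    for fr in frames:
        row = []
        for p in parts:
            x, y, lik = fr.points.get(p, (np.nan, np.nan, 0.0))
            row.extend([x, y, lik])
        data.append(row)
        index.append(fr.frame_index)
    pd.DataFrame(data, index=index, columns=cols).to_csv(path)


# ---------------------------------------------------------------------------
# ground truth

#: Default Fiji-export column mapping; override for other layouts.
DEFAULT_GT_COLUMNS = {
    "frame": "frame",
    "x": "cx",
    "y": "cy",
    "diameter": "diameter",
}


def read_ground_truth(
    path: str | os.PathLike,
    image_size: tuple[int, int],
    columns: Mapping[str, str] | None = None,
    sentinel_radius_px: float = 5.0,
    sentinel_border_px: float = 10.0,
) -> list[GroundTruthAnnotation]:
    """Read manual circle annotations (Fiji measurement export).

    Diameters are halved to radii.  An annotation is flagged
    ``trackable=False`` when its radius is below ``sentinel_radius_px``
    (under the minimum detectable radius) *and* its center lies within
    ``sentinel_border_px`` of an image border — the annotators' convention
    of marking untrackable frames with a tiny circle at the frame edge.
    Rows are returned sorted by frame index.

    Parameters
    ----------
    image_size : (width, height) in pixels, used for the border test.
    columns : optional mapping with keys frame, x, y, diameter giving the
        CSV column names (default: frame, cx, cy, diameter).
    """
    cols = dict(DEFAULT_GT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise FormatError(f"ground-truth table lacks columns: {missing}")
    w, h = image_size
    out = []
    for _, row in df.iterrows():
        diameter = float(row[cols["diameter"]])
        if diameter <= 0:
            raise FormatError(
                f"non-positive diameter {diameter} at frame {row[cols['frame']]}"
            )
        x, y = float(row[cols["x"]]), float(row[cols["y"]])
        radius = diameter / 2.0
        near_border = (
            x <= sentinel_border_px
            or y <= sentinel_border_px
            or x >= w - sentinel_border_px
            or y >= h - sentinel_border_px
        )
        trackable = not (radius < sentinel_radius_px and near_border)
        out.append(
            GroundTruthAnnotation(
                frame_index=int(row[cols["frame"]]),
                center=(x, y),
                radius=radius,
                trackable=trackable,
            )
        )
    out.sort(key=lambda a: a.frame_index)
    return out


def write_ground_truth(
    annotations: Sequence[GroundTruthAnnotation], path: str | os.PathLike
) -> None:
    """Write annotations in the Fiji-export dialect (diameter, not radius)."""
    pd.DataFrame(
        {
            "frame": [a.frame_index for a in annotations],
            "cx": [a.center[0] for a in annotations],
            "cy": [a.center[1] for a in annotations],
            "diameter": [2.0 * a.radius for a in annotations],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# radius series


def write_radius_series(series: RadiusSeries, path: str | os.PathLike) -> None:
    """Write a radius series as CSV with an fps header comment.

    Layout: ``# fps=<fps>`` then columns frame,x,y,radius,valid; missing
    frames carry empty numeric fields and valid=0.
    """
    with open(path, "w") as fh:
        fh.write(f"# fps={series.fps:g}\n")
        fh.write("frame,x,y,radius,valid\n")
        for f, c in series:
            if c is None:
                fh.write(f"{f},,,,0\n")
            else:
                fh.write(f"{f},{c.x:.6f},{c.y:.6f},{c.radius:.6f},1\n")


def read_radius_series(path: str | os.PathLike) -> RadiusSeries:
    """Read a radius series written by :func:`write_radius_series`."""
    with open(path) as fh:
        header = fh.readline()
        m = re.match(r"#\s*fps=([0-9.eE+-]+)", header)
        if not m:
            raise FormatError("radius series file lacks the '# fps=' header")
        fps = float(m.group(1))
        df = pd.read_csv(fh)
    entries: list[tuple[int, Circle | None]] = []
    seen: set[int] = set()
    for _, row in df.iterrows():
        f = int(row["frame"])
        if f in seen:
            raise FormatError(f"duplicate frame index {f}")
        seen.add(f)
        if int(row["valid"]) == 0 or np.isnan(row["radius"]):
            entries.append((f, None))
        else:
            entries.append(
                (f, Circle(float(row["x"]), float(row["y"]), float(row["radius"])))
            )
    entries.sort(key=lambda e: e[0])
    return RadiusSeries(fps=fps, entries=entries)


# ---------------------------------------------------------------------------
# call segments


def read_call_segments(path: str | os.PathLike) -> list[CallSegment]:
    """Read a call-segment annotation table.

    Expected columns: call_type, start_frame, end_frame and optionally
    individual, sequence_id.
    """
    df = pd.read_csv(path)
    for col in ("call_type", "start_frame", "end_frame"):
        if col not in df.columns:
            raise FormatError(f"segment table lacks column {col!r}")
    segs = [
        CallSegment(
            call_type=str(row["call_type"]),
            start_frame=int(row["start_frame"]),
            end_frame=int(row["end_frame"]),
            individual=str(row.get("individual", "") or ""),
            sequence_id=str(row.get("sequence_id", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    return segs


def write_call_segments(
    segments: Sequence[CallSegment], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "call_type": [s.call_type for s in segments],
            "start_frame": [s.start_frame for s in segments],
            "end_frame": [s.end_frame for s in segments],
            "individual": [s.individual for s in segments],
            "sequence_id": [s.sequence_id for s in segments],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# audio


def read_wav(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV file; returns (float waveform in [-1, 1], rate)."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        raise FormatError("expected mono audio, got multi-channel")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, int(sr)


def write_wav(path: str | os.PathLike, waveform: np.ndarray, sr: int) -> None:
    """Write a float waveform in [-1, 1] as 16-bit mono PCM WAV."""
    clipped = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, sr, (clipped * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# frame sources

_FRAME_RE = re.compile(r"(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


def iter_frames(
    source: str | os.PathLike | Sequence[np.ndarray],
) -> Iterator[np.ndarray]:
    """Yield frames from a frame source as 2D (grayscale) or 3D arrays.

    Accepts a directory of numbered PNG/JPEG images (sorted by the number
    in the filename), a single image file, or any in-memory sequence of
    arrays (yielded as-is).
    """
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if path.is_dir():
            named = []
            for p in sorted(path.iterdir()):
                m = _FRAME_RE.search(p.name)
                if m:
                    named.append((int(m.group(1)), p))
            named.sort(key=lambda t: t[0])
            if not named:
                raise FormatError(f"no numbered PNG/JPEG frames in {path}")
            for _, p in named:
                yield np.asarray(iio.imread(p))
        elif path.is_file():
            suffix = path.suffix.lower()
            if suffix in (".png", ".jpg", ".jpeg"):
                yield np.asarray(iio.imread(path))
            else:
                raise FormatError(
                    f"unsupported frame container {suffix!r}: decode the video "
                    "to a directory of numbered PNG/JPEG frames first"
                )
        else:
            raise FileNotFoundError(path)
    else:
        for frame in source:
            yield np.asarray(frame)


def write_frames(
    frames: Iterable[np.ndarray], out_dir: str | os.PathLike, prefix: str = "frame"
) -> list[Path]:
    """Write frames as numbered PNGs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"{prefix}{i:05d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths
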