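"""Frame-windowed acoustic features and kinematic-acoustic correlation.

The acoustic analysis window equals the duration of one video frame, so
every acoustic feature lines up with one tracked radius and the two can
be joined frame by frame.  Four core features are computed natively —
RMS amplitude, fundamental frequency (autocorrelation), spectral centroid
and entropy (both Wiener/spectral-flatness and normalized Shannon) —
and arbitrary additional per-frame features can be merged from external
tables.  Two analyses are provided: per-frame correlation of radius with
the features of co-occurring calls, and the carry-over analysis relating
the last trackable radius of a boom call to aggregated features of the
immediately following bark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .types import AcousticFrameFeatures, CallSegment, RadiusSeries
from .validation import pearson

log = logging.getLogger(__name__)

#: Per-frame join of radius and acoustic features: columns ``frame``,
#: ``radius`` and one column per feature.
AlignedTable = pd.DataFrame

CORE_FEATURES = ("amplitude", "f0", "spectral_centroid",
                 "wiener_entropy", "shannon_entropy")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one acoustic parameter with air-sac radius."""

    parameter: str
    r: float | None
    p: float | None
    n: int
    aggregation: str | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


# ---------------------------------------------------------------------------
# feature extraction


def _window_spectrum(x: np.ndarray, sr: int) -> tuple[np.ndarray, np.ndarray]:
    # Welch-averaged PSD: averaging tames the chi^2 bin noise of a single
    # periodogram, which would bias spectral flatness of noise well below 1.
    nperseg = min(512, len(x))
    freqs, psd = signal.welch(x, fs=sr, nperseg=nperseg)
    return freqs[1:], psd[1:]  # drop DC


def _autocorr_f0(
    x: np.ndarray, sr: int, band: tuple[float, float], voicing_threshold: float
) -> float | None:
    n = len(x)
    spec = np.fft.rfft(x, 2 * n)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        return None
    lag_min = max(2, int(np.ceil(sr / band[1])))
    lag_max = min(n - 2, int(np.floor(sr / band[0])))
    if lag_min >= lag_max:
        return None
    seg = ac[lag_min : lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    if ac[k] / ac[0] < voicing_threshold:
        return None
    # parabolic interpolation around the peak for sub-sample lag accuracy
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    lag = k + float(np.clip(delta, -1, 1))
    return float(sr / lag)


def frame_features(
    audio: np.ndarray,
    sr: int,
    fps: float,
    f0_band: tuple[float, float] = (20.0, 1000.0),
    voicing_threshold: float = 0.3,
    extra: Mapping[int, Mapping[str, float]] | None = None,
) -> list[AcousticFrameFeatures]:
    """Acoustic features over non-overlapping windows of one frame duration.

    The waveform is partitioned into windows of round(sr/fps) samples
    aligned to frame starts (a trailing partial window is dropped).  Per
    window: RMS amplitude; f0 from the autocorrelation peak within
    ``f0_band`` (None when the peak falls below ``voicing_threshold``
    relative to lag 0); power-weighted spectral centroid; Wiener entropy
    (spectral flatness, geometric/arithmetic mean ratio of the PSD); and
    normalized Shannon entropy of the PSD.  Spectral statistics are None
    for digitally silent windows.  ``extra`` optionally supplies
    externally computed per-frame features keyed by frame index.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    audio = np.asarray(audio, dtype=np.float64)
    n = int(round(sr / fps))
    if n < 2 or len(audio) < n:
        raise ValueError("audio shorter than one frame window")
    out: list[AcousticFrameFeatures] = []
    for i in range(len(audio) // n):
        w = audio[i * n : (i + 1) * n]
        amplitude = float(np.sqrt(np.mean(w**2)))
        ext = dict(extra.get(i, {})) if extra else {}
        if amplitude == 0.0:
            out.append(
                AcousticFrameFeatures(i, 0.0, None, None, None, None, ext)
            )
            continue
        x = w - w.mean()
        freqs, psd = _window_spectrum(x, sr)
        total = psd.sum()
        if total <= 0:
            out.append(
                AcousticFrameFeatures(i, amplitude, None, None, None, None, ext)
            )
            continue
        centroid = float(np.sum(freqs * psd) / total)
        flatness = float(
            np.exp(np.mean(np.log(psd + 1e-30))) / (total / len(psd))
        )
        q = psd / total
        q = q[q > 0]
        shannon = float(-np.sum(q * np.log2(q)) / np.log2(len(psd)))
        f0 = _autocorr_f0(x, sr, f0_band, voicing_threshold)
        out.append(
            AcousticFrameFeatures(
                i, amplitude, f0, centroid,
                min(flatness, 1.0), shannon, ext,
            )
        )
    return out


def features_to_frame(features: Sequence[AcousticFrameFeatures]) -> pd.DataFrame:
    """Tabulate features, one row per frame (None becomes NaN)."""
    extra_names: list[str] = []
    for f in features:
        for k in f.extra:
            if k not in extra_names:
                extra_names.append(k)
    rows = []
    for f in features:
        row = {"frame": f.frame_index}
        for name in CORE_FEATURES:
            v = getattr(f, name)
            row[name] = np.nan if v is None else v
        for name in extra_names:
            row[name] = f.extra.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignment


def downsample_series(s: RadiusSeries) -> RadiusSeries:
    """Halve a 50 fps radius series to 25 fps by keeping even frames.

    Entries at original frames 0, 2, 4, ... are kept and reindexed to
    0, 1, 2, ...; downsampling happens after tracking, on the level of
    analyzed frames.  Series at any other rate are returned unchanged
    with a warning.
    """
    if s.fps != 50.0:
        log.warning("downsample_series expects 50 fps input, got %s; no-op", s.fps)
        return s
    entries = [(f // 2, c) for f, c in s if f % 2 == 0]
    return RadiusSeries(fps=25.0, entries=entries)


def _segment_frames(
    segments: Sequence[CallSegment], call_type: str | None
) -> set[int]:
    frames: set[int] = set()
    for seg in segments:
        if call_type is None or seg.call_type == call_type:
            frames.update(seg.frames)
    return frames


def align(
    radius: RadiusSeries,
    features: Sequence[AcousticFrameFeatures],
    segments: Sequence[CallSegment] | None = None,
    call_type: str | None = "boom",
) -> AlignedTable:
    """Inner-join radius and acoustic features on frame index.

    Frames lacking a valid radius or a feature row are dropped.  When
    ``segments`` is given the table is restricted to frames inside
    segments of ``call_type`` (all segments if ``call_type`` is None).
    Radius and features must share the same fps basis.
    """
    feat_df = features_to_frame(features).set_index("frame")
    keep = _segment_frames(segments, call_type) if segments is not None else None
    rows = []
    for frame, circle in radius:
        if circle is None or frame not in feat_df.index:
            continue
        if keep is not None and frame not in keep:
            continue
        row = {"frame": frame, "radius": circle.radius}
        row.update(feat_df.loc[frame].to_dict())
        rows.append(row)
    cols = ["frame", "radius", *feat_df.columns]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# correlation analyses


def correlate_features(t: AlignedTable) -> list[CorrelationResult]:
    """Pearson correlation of every feature column against radius.

    Rows with a missing feature value are dropped per feature; n is
    reported per feature.  Features with zero variance (or fewer than 3
    usable rows) yield an undefined result (r=None) rather than an error.
    """
    if len(t) < 3:
        raise ValueError(f"need at least 3 aligned rows, got {len(t)}")
    results = []
    feature_cols = [c for c in t.columns if c not in ("frame", "radius")]
    for col in feature_cols:
        sub = t[["radius", col]].dropna()
        if len(sub) < 3:
            results.append(CorrelationResult(col, None, None, len(sub)))
            continue
        try:
            r, p = pearson(sub["radius"], sub[col])
        except ValueError:
            results.append(CorrelationResult(col, None, None, len(sub)))
            continue
        results.append(CorrelationResult(col, r, p, len(sub)))
    return results


def last_trackable_radius(
    radius: RadiusSeries, segment: CallSegment
) -> float | None:
    """Radius of the last non-missing frame within a segment, or None."""
    best = None
    for frame, circle in radius:
        if circle is not None and segment.start_frame <= frame <= segment.end_frame:
            best = circle.radius
    return best


def boom_bark_pairs(
    segments: Sequence[CallSegment],
) -> list[tuple[CallSegment, CallSegment]]:
    """Boom segments immediately followed by a bark in the same sequence."""
    pairs = []
    by_seq: dict[str, list[CallSegment]] = {}
    for seg in segments:
        by_seq.setdefault(seg.sequence_id, []).append(seg)
    for seq_segments in by_seq.values():
        seq_segments = sorted(seq_segments, key=lambda s: s.start_frame)
        for a, b in zip(seq_segments, seq_segments[1:]):
            if a.call_type == "boom" and b.call_type == "bark":
                pairs.append((a, b))
    return pairs


def boom_bark_analysis(
    radius: RadiusSeries,
    features: Sequence[AcousticFrameFeatures],
    segments: Sequence[CallSegment],
    aggregations: Sequence[str] = ("mean", "min", "max"),
) -> list[CorrelationResult]:
    """Carry-over analysis: boom inflation vs features of the following bark.

    For every boom immediately followed by a bark within a great-call
    sequence, the predictor is the last trackable (non-missing) radius of
    the boom and the responses are the mean, minimum and maximum of each
    acoustic feature over the bark's frames.  Booms with no trackable
    radius are skipped.  Boom frames never contribute acoustic responses —
    only the bark's frames are aggregated.  One correlation is reported
    per (feature, aggregation).
    """
    feat_df = features_to_frame(features).set_index("frame")
    feature_cols = list(feat_df.columns)
    agg_funcs = {"mean": np.nanmean, "min": np.nanmin, "max": np.nanmax}
    for a in aggregations:
        if a not in agg_funcs:
            raise ValueError(f"unknown aggregation {a!r}")
    predictors: list[float] = []
    responses: dict[tuple[str, str], list[float]] = {
        (c, a): [] for c in feature_cols for a in aggregations
    }
    for boom, bark in boom_bark_pairs(segments):
        r_last = last_trackable_radius(radius, boom)
        if r_last is None:
            log.info("boom %s-%s has no trackable radius; pair skipped",
                     boom.start_frame, boom.end_frame)
            continue
        bark_frames = [f for f in bark.frames if f in feat_df.index]
        if not bark_frames:
            continue
        predictors.append(r_last)
        block = feat_df.loc[bark_frames]
        for col in feature_cols:
            vals = block[col].to_numpy(dtype=float)
            for a in aggregations:
                if np.all(np.isnan(vals)):
                    responses[(col, a)].append(np.nan)
                else:
                    responses[(col, a)].append(float(agg_funcs[a](vals)))
    results = []
    x = np.asarray(predictors)
    for (col, a), ys in responses.items():
        y = np.asarray(ys)
        ok = ~np.isnan(y)
        if ok.sum() < 3:
            results.append(CorrelationResult(col, None, None, int(ok.sum()), a))
            continue
        try:
            r, p = pearson(x[ok], y[ok])
        except ValueError:
            results.append(CorrelationResult(col, None, None, int(ok.sum()), a))
            continue
        results.append(CorrelationResult(col, r, p, int(ok.sum()), a))
    return results
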