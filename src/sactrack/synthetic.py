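"""Ground-truthed synthetic fixtures for the whole pipeline.

Generates the three kinds of data the trackers and analyses consume,
with known truth and full determinism under a fixed seed:

* rendered inflation videos — one bright semicircular sac (flat chord on
  top, arc below, matching the air-sac silhouette) of known time-varying
  radius over a cluttered background;
* five-point outline keypoint tracks with Gaussian jitter, likelihood
  values and seeded dropout, following the outline labeling geometry
  (two fixed arc ends, the lowest point, two mid-arc points);
* audio whose amplitude, fundamental frequency, harmonic brightness and
  noisiness covary linearly with the planted radius trajectory, plus
  call-segment layouts for the boom and boom-to-bark analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from skimage.draw import disk as _disk, line as _line

from .types import (
    CallSegment,
    Circle,
    FACE_PARTS,
    GroundTruthAnnotation,
    KeypointFrame,
    OUTLINE_PARTS,
    RadiusSeries,
)


@dataclass(frozen=True)
class SacSimConfig:
    """Study conditions for the synthetic air-sac world.

    ``radius_trajectory`` is 'constant', 'linear', 'sinusoidal' or a
    callable frame_index -> radius; radii stay within [r_lo, r_hi], inside
    the detectable band.  ``clutter_density`` is clutter elements per
    kilopixel.  ``acoustic_coupling`` maps the four synthesis controls to
    (slope, noise_sd) pairs in normalized-radius units; slopes of zero give
    the null (uncoupled) condition.
    """

    image_size: tuple[int, int] = (512, 384)
    n_frames: int = 50
    fps: float = 25.0
    radius_trajectory: str | Callable[[int], float] = "sinusoidal"
    r_lo: float = 80.0
    r_hi: float = 200.0
    center: tuple[float, float] = (256.0, 150.0)
    center_drift: float = 0.0
    clutter_density: float = 0.0
    keypoint_jitter_sd: float = 2.0
    dropout_prob: float = 0.1
    low_likelihood_value: float = 0.3
    sac_intensity: int = 220
    background_intensity: int = 30
    sr: int = 48000
    acoustic_coupling: dict = field(
        default_factory=lambda: {
            "amplitude": (0.5, 0.02),   # RMS gain per unit rho
            "f0": (100.0, 4.0),         # Hz per unit rho
            "brightness": (-0.45, 0.02),  # harmonic decay per unit rho
            "noise": (-0.3, 0.015),     # noise fraction per unit rho
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_lo < 5 or self.r_hi > 270:
            raise ValueError("radius range must stay within [5, 270] px")
        if self.r_lo > self.r_hi:
            raise ValueError("r_lo must be <= r_hi")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")

    def rho(self, radius: float) -> float:
        """Normalized inflation in [0, 1]."""
        if self.r_hi == self.r_lo:
            return 0.5
        return float(np.clip((radius - self.r_lo) / (self.r_hi - self.r_lo), 0, 1))


# ---------------------------------------------------------------------------
# trajectory


def simulate_trajectory(cfg: SacSimConfig) -> RadiusSeries:
    """Planted circle trajectory: deterministic given the config."""
    n = cfg.n_frames
    cx0, cy = cfg.center
    if callable(cfg.radius_trajectory):
        radii = [float(cfg.radius_trajectory(i)) for i in range(n)]
    elif cfg.radius_trajectory == "constant":
        radii = [(cfg.r_lo + cfg.r_hi) / 2.0] * n
    elif cfg.radius_trajectory == "linear":
        radii = list(np.linspace(cfg.r_lo, cfg.r_hi, n))
    elif cfg.radius_trajectory == "sinusoidal":
        phase = 2.0 * np.pi * np.arange(n) / max(n - 1, 1)
        radii = list(cfg.r_lo + (cfg.r_hi - cfg.r_lo) * (1 - np.cos(phase)) / 2.0)
    else:
        raise ValueError(f"unknown trajectory {cfg.radius_trajectory!r}")
    entries = [
        (i, Circle(cx0 + cfg.center_drift * i, cy, r))
        for i, r in enumerate(radii)
    ]
    return RadiusSeries(fps=cfg.fps, entries=entries)


# ---------------------------------------------------------------------------
# rendered frames


def _add_clutter(img: np.ndarray, rng: np.random.Generator, density: float) -> None:
    h, w = img.shape
    n = int(round(density * h * w / 1000.0))
    for _ in range(n):
        shade = int(rng.integers(0, 256))
        if rng.random() < 0.5:
            r0, c0 = int(rng.integers(0, h)), int(rng.integers(0, w))
            r1 = int(np.clip(r0 + rng.integers(-60, 61), 0, h - 1))
            c1 = int(np.clip(c0 + rng.integers(-60, 61), 0, w - 1))
            rr, cc = _line(r0, c0, r1, c1)
            img[rr, cc] = shade
        else:
            r0, c0 = int(rng.integers(0, h)), int(rng.integers(0, w))
            rad = int(rng.integers(2, 15))
            rr, cc = _disk((r0, c0), rad, shape=img.shape)
            img[rr, cc] = shade


def render_frames(
    truth: RadiusSeries, cfg: SacSimConfig
) -> tuple[list[np.ndarray], list[GroundTruthAnnotation]]:
    """Render the planted trajectory as grayscale frames plus annotations.

    The sac is a filled semicircle: flat chord at the top through the
    center, arc bulging downward.  Backgrounds carry seeded clutter (line
    segments and small disks) at ``clutter_density`` elements per
    kilopixel.  Raises if any planted sac leaves the frame bounds.
    """
    w, h = cfg.image_size
    rng = np.random.default_rng(cfg.seed)
    yy, xx = np.mgrid[0:h, 0:w]
    frames: list[np.ndarray] = []
    annotations: list[GroundTruthAnnotation] = []
    for frame_index, circle in truth:
        img = np.full((h, w), cfg.background_intensity, dtype=np.uint8)
        _add_clutter(img, rng, cfg.clutter_density)
        if circle is not None:
            cx, cy, r = circle.x, circle.y, circle.radius
            if cx - r < 0 or cx + r >= w or cy < 0 or cy + r >= h:
                raise ValueError(
                    f"sac (r={r:.0f} at {cx:.0f},{cy:.0f}) outside {w}x{h} frame"
                )
            mask = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r) & (yy >= cy)
            img[mask] = cfg.sac_intensity
            annotations.append(
                GroundTruthAnnotation(frame_index, (cx, cy), r, trackable=True)
            )
        frames.append(img)
    return frames, annotations


# ---------------------------------------------------------------------------
# keypoints

#: Outline parts in placement order with their arc angles (degrees from the
#: +x axis, y downward): left end, mid-low left, lowest point, mid-low
#: right, right end.
_OUTLINE_ANGLES = {
    "Start_outline_outer_left": 180.0,
    "MidLowleft_outline": 135.0,
    "LowestPoint_outline": 90.0,
    "MidLowright_outline": 45.0,
    "Start_outline_outer_right": 0.0,
}


def generate_keypoints(
    truth: RadiusSeries, cfg: SacSimConfig
) -> list[KeypointFrame]:
    """Five-point outline tracks with jitter, likelihoods and dropout.

    Noiseless placement (jitter 0) puts all five points exactly on the
    planted circle.  Each point independently drops out with probability
    ``dropout_prob``, receiving likelihood ``low_likelihood_value``;
    surviving points get likelihoods drawn from U(0.85, 0.99).  Facial
    keypoints (never fit inputs) are included at plausible positions to
    exercise downstream filtering.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    frames: list[KeypointFrame] = []
    for frame_index, circle in truth:
        if circle is None:
            frames.append(KeypointFrame(frame_index, {}))
            continue
        cx, cy, r = circle.x, circle.y, circle.radius
        pts: dict[str, tuple[float, float, float]] = {}
        for part in OUTLINE_PARTS:
            theta = np.deg2rad(_OUTLINE_ANGLES[part])
            x = cx + r * np.cos(theta) + rng.normal(0, cfg.keypoint_jitter_sd)
            y = cy + r * np.sin(theta) + rng.normal(0, cfg.keypoint_jitter_sd)
            if rng.random() < cfg.dropout_prob:
                lik = cfg.low_likelihood_value
            else:
                lik = float(rng.uniform(0.85, 0.99))
            pts[part] = (float(x), float(y), lik)
        for j, part in enumerate(FACE_PARTS):
            pts[part] = (
                float(cx + (j - 1.5) * 10.0),
                float(cy - 30.0 - 5.0 * j),
                float(rng.uniform(0.85, 0.99)),
            )
        frames.append(KeypointFrame(frame_index, pts))
    return frames


# ---------------------------------------------------------------------------
# call-sequence layouts


def simulate_call_study(
    cfg: SacSimConfig,
    n_sequences: int = 25,
    boom_frames: int | Sequence[int] = 7,
    bark_frames: int = 0,
    pairs_per_sequence: int = 1,
    gap_frames: int = 2,
    individual: str = "Pelangi",
) -> tuple[RadiusSeries, list[CallSegment]]:
    """Radius trajectory plus call segments for the correlation analyses.

    Each sequence holds ``pairs_per_sequence`` boom(-bark) units separated
    by gaps.  Radius is trackable only during booms, rising linearly from
    a random start in the lower half of [r_lo, r_hi] to a random end in
    the upper half (the sac inflates during the boom and is not tracked
    during barks or gaps).  ``boom_frames`` may be one length or a
    per-sequence list.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if isinstance(boom_frames, int):
        boom_lengths = [boom_frames] * n_sequences
    else:
        boom_lengths = list(boom_frames)
        if len(boom_lengths) != n_sequences:
            raise ValueError("boom_frames list must match n_sequences")
    mid = (cfg.r_lo + cfg.r_hi) / 2.0
    entries: list[tuple[int, Circle | None]] = []
    segments: list[CallSegment] = []
    frame = 0
    cx, cy = cfg.center
    for s in range(n_sequences):
        seq_id = f"seq{s:03d}"
        for _ in range(pairs_per_sequence):
            nb = boom_lengths[s]
            r_start = float(rng.uniform(cfg.r_lo, mid))
            r_end = float(rng.uniform(mid, cfg.r_hi))
            radii = np.linspace(r_start, r_end, nb)
            segments.append(
                CallSegment("boom", frame, frame + nb - 1, individual, seq_id)
            )
            for r in radii:
                entries.append((frame, Circle(cx, cy, float(r))))
                frame += 1
            if bark_frames > 0:
                segments.append(
                    CallSegment(
                        "bark", frame, frame + bark_frames - 1, individual, seq_id
                    )
                )
                for _ in range(bark_frames):
                    entries.append((frame, None))  # sac deflated during bark
                    frame += 1
            for _ in range(gap_frames):
                entries.append((frame, None))
                frame += 1
    return RadiusSeries(fps=cfg.fps, entries=entries), segments


# ---------------------------------------------------------------------------
# audio


def _tone(n: int, sr: int, f0: float, brightness: float,
          rng: np.random.Generator, n_harmonics: int = 5) -> np.ndarray:
    t = np.arange(n) / sr
    out = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        fk = k * f0
        if fk >= sr / 2:
            break
        out += brightness ** (k - 1) * np.sin(
            2 * np.pi * fk * t + rng.uniform(0, 2 * np.pi)
        )
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def synthesize_audio(
    truth: RadiusSeries,
    segments: Sequence[CallSegment] | None,
    cfg: SacSimConfig,
) -> tuple[np.ndarray, int, pd.DataFrame]:
    """Audio whose per-frame features follow planted couplings to radius.

    Boom frames carry a harmonic tone in noise; the four synthesis
    controls follow rho, the normalized radius, with the slopes and noise
    from ``cfg.acoustic_coupling``: RMS amplitude (base 0.15), fundamental
    frequency (base 150 Hz), harmonic brightness (base 0.75; lower
    brightness pulls the spectral centroid down) and noise fraction (base
    0.45; less noise means lower spectral entropy).  Bark frames are
    low-pass-filtered noise bursts whose cutoff falls with the preceding
    boom's last radius, planting a negative radius-to-centroid carry-over.
    Frames outside any call are silent.  Returns the waveform, the sample
    rate and a table of the planted per-frame control values.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n_win = int(round(cfg.sr / cfg.fps))
    frames = truth.frame_indices
    n_frames = int(frames.max()) + 1 if len(frames) else 0
    by_frame = truth.as_dict()

    role = ["silence"] * n_frames
    bark_rho: dict[int, float] = {}
    if segments is None:
        for f, c in truth:
            if c is not None:
                role[f] = "boom"
    else:
        from .acoustics import boom_bark_pairs, last_trackable_radius

        for seg in segments:
            for f in seg.frames:
                if f < n_frames:
                    role[f] = seg.call_type if seg.call_type in ("boom", "bark") else "silence"
        for boom, bark in boom_bark_pairs(segments):
            r_last = last_trackable_radius(truth, boom)
            if r_last is None:
                continue
            for f in bark.frames:
                if f < n_frames:
                    bark_rho[f] = cfg.rho(r_last)

    coup = cfg.acoustic_coupling
    wave = np.zeros(n_frames * n_win)
    rows = []
    for f in range(n_frames):
        row = {"frame": f, "role": role[f], "amplitude": 0.0, "f0": np.nan,
               "brightness": np.nan, "noise_fraction": np.nan, "rho": np.nan}
        if role[f] == "boom":
            circle = by_frame.get(f)
            if circle is None:
                rows.append(row)
                continue
            rho = cfg.rho(circle.radius)
            amp = 0.15 + coup["amplitude"][0] * rho + rng.normal(0, coup["amplitude"][1])
            f0 = 150.0 + coup["f0"][0] * rho + rng.normal(0, coup["f0"][1])
            bright = 0.75 + coup["brightness"][0] * rho + rng.normal(0, coup["brightness"][1])
            noise_frac = 0.45 + coup["noise"][0] * rho + rng.normal(0, coup["noise"][1])
            amp = float(np.clip(amp, 0.01, 0.95))
            f0 = float(np.clip(f0, 40.0, 900.0))
            bright = float(np.clip(bright, 0.05, 0.95))
            noise_frac = float(np.clip(noise_frac, 0.02, 0.9))
            tone = _tone(n_win, cfg.sr, f0, bright, rng)
            noise = rng.standard_normal(n_win)
            noise /= np.sqrt(np.mean(noise**2))
            w = amp * ((1 - noise_frac) * tone + noise_frac * noise)
            wave[f * n_win : (f + 1) * n_win] = w
            row.update(amplitude=amp, f0=f0, brightness=bright,
                       noise_fraction=noise_frac, rho=rho)
        elif role[f] == "bark" and f in bark_rho:
            rho = bark_rho[f]
            cutoff = 9000.0 * (1.0 - 0.75 * rho) + rng.normal(0, 100.0)
            cutoff = float(np.clip(cutoff, 500.0, 0.45 * cfg.sr))
            sos = signal.butter(4, cutoff, fs=cfg.sr, output="sos")
            noise = signal.sosfilt(sos, rng.standard_normal(n_win))
            rms = np.sqrt(np.mean(noise**2))
            # bark level varies a little but is uncoupled from inflation
            amp_b = float(np.clip(0.3 + rng.normal(0, 0.02), 0.05, 0.9))
            w = amp_b * noise / rms if rms > 0 else noise
            wave[f * n_win : (f + 1) * n_win] = w
            row.update(amplitude=amp_b, noise_fraction=1.0, rho=rho)
        rows.append(row)
    return wave, cfg.sr, pd.DataFrame(rows)
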