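# sactrack

Tracking and kinematic-acoustic analysis of elastic semicircular
structures in video — laryngeal air sacs (the motivating case is the
siamang, whose throat sac inflates visibly during singing), frog vocal
sacs, bird gular pouches, and similar soft-tissue structures that
skeletal pose tracking ignores.

The package is for researchers who have closeup video (and optionally
synchronized audio) of such a structure and want a per-frame radius time
series plus statistics linking inflation to vocal acoustics.

## What it computes

**Two tracking routes**, both producing a per-frame circle (center x, y
and radius r in pixels) with explicit missing frames:

* **Keypoint route** — consumes a markerless pose tracker's CSV of five
  outline keypoints with likelihoods. Points with likelihood ≤ 0.6 are
  discarded; if ≥ 3 survive, the circle minimizing the geometric
  least-squares objective Σᵢ (dᵢ − r)², dᵢ = ‖pᵢ − c‖, is found by
  Landau's fixed-point iteration (the 3-point case is the closed-form
  circumcircle).
* **Hough route** — unsupervised: grayscale → gain/offset adjustment →
  median blur → Canny with brightness-adaptive thresholds → dilation →
  median blur, then circle-Hough voting over radii in [5, 270] px. The
  six chain parameters are tuned per dataset by exhaustive grid search
  against manual annotations.

**Downstream analysis**: Kolmogorov–Zurbenko smoothing (iterated moving
average, window 3 × 2 iterations by default) with gap preservation;
validation against manual ground truth with the 100/270 px radius
filters and both pooled and per-video-mean Pearson correlations;
frame-windowed acoustic features (RMS amplitude, autocorrelation f0,
spectral centroid, Wiener and Shannon entropy) joined 1:1 with radius by
frame; and the boom→bark carry-over analysis correlating the last
trackable inflation of a boom call with aggregated features of the
immediately following bark.

A fully seeded synthetic generator renders ground-truthed inflation
videos, keypoint tracks and radius-coupled audio, so the entire pipeline
is testable without field recordings. See `docs/methods.md` for the
models, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from sactrack import (SacSimConfig, simulate_trajectory, generate_keypoints,
                      fit_series, synthesize_audio, frame_features, align,
                      correlate_features)
from sactrack.synthetic import simulate_call_study

cfg = SacSimConfig(n_frames=50, seed=1)          # synthetic study world
truth = simulate_trajectory(cfg)

# keypoint route: jittered five-point tracks -> per-frame circles
dlc = fit_series(generate_keypoints(truth, cfg), fps=cfg.fps)
err = np.abs(dlc.radii() - truth.radii())
print(f"median radius error {np.nanmedian(err):.2f} px")

# kinematic-acoustic analysis on 10 boom sequences
radius, segments = simulate_call_study(cfg, n_sequences=10, boom_frames=7)
wave, sr, _ = synthesize_audio(radius, segments, cfg)
table = align(radius, frame_features(wave, sr, cfg.fps), segments, "boom")
for res in correlate_features(table):
    if res.defined:
        print(f"{res.parameter:18s} r = {res.r:+.2f}  p = {res.p:.2g}  n = {res.n}")
```

prints

```
median radius error 0.97 px
amplitude          r = +0.98  p = 3.2e-48  n = 70
f0                 r = +0.97  p = 4.2e-45  n = 70
spectral_centroid  r = -0.93  p = 2.9e-32  n = 70
wiener_entropy     r = -0.94  p = 3.3e-34  n = 70
shannon_entropy    r = -0.97  p = 1.4e-44  n = 70
```

The keypoint route recovers the planted radius to about a pixel under
2 px keypoint jitter, and the correlation analysis recovers the planted
coupling signs: amplitude and f0 rise with inflation while spectral
centroid and entropy fall (more energy in low frequencies, more tonal —
the inflated sac acting as a low-frequency radiator).

## Command line

```sh
sactrack simulate --config cfg.json --out simdir/
sactrack track-keypoints --keypoints dlc.csv --threshold 0.6 --out radii.csv
sactrack track-hough --video frames/ --crop 400,200,800,600 --smooth kz:window=3,iter=2 --out radii.csv
sactrack optimize --videos frames/ --truth truth.csv --out scores.csv
sactrack validate --auto radii.csv --truth truth.csv --rmin 100 --rmax 270 --out report.csv
sactrack correlate --radius radii.csv --audio call.wav --segments segs.csv --out corr.csv
sactrack boom-bark --radius radii.csv --audio call.wav --segments segs.csv --out carryover.csv
```

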