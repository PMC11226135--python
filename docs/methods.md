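# Methods

`sactrack` estimates the time-varying radius of an elastic semicircular
structure — the motivating case is the laryngeal air sac of the siamang,
visible as a bright semicircle under the chin during singing — from video,
and relates the resulting inflation series to the acoustics of concurrent
and subsequent calls. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic test world does and
does not establish.

## Coordinate and data conventions

Image coordinates: origin top-left, x rightward, y downward, pixels;
frame indices 0-based. A tracked result is a *radius series*: per frame
either a circle (center x, y and radius, px) or a missing entry. Missing
entries are first-class: both trackers refuse to guess, and every
downstream stage (smoothing, validation, alignment) preserves gaps rather
than imputing them.

Manual ground truth follows the annotators' convention of marking
untrackable frames with a deliberately tiny circle at the frame edge.
The reader operationalizes this sentinel as radius < 5 px (below the
minimum detectable radius) *and* center within 10 px of an image border;
both constants are configurable because the convention is a lab habit,
not a standard.

## Keypoint route: likelihood filter + geometric circle fit

A markerless pose tracker provides five keypoints on the sac outline —
two fixed arc ends, the lowest point, and two mid-arc points — each with
a confidence ("likelihood") in [0, 1]. Per frame:

1. keep outline points with likelihood strictly greater than 0.6 (facial
   keypoints are never fit inputs);
2. with fewer than 3 survivors, the frame has no radius estimate;
3. otherwise fit the circle minimizing the geometric least-squares
   objective F(a, b, r) = Σᵢ (dᵢ − r)², dᵢ = ‖pᵢ − (a, b)‖.

Five points for a three-parameter model buys dropout robustness: any two
points can vanish and the noiseless fit is unchanged (a tested property).

The fit is Landau's fixed-point scheme. The center starts at the
arithmetic centroid; each iteration sets r to the mean point-to-center
distance and moves the center to the stationarity condition
c ← mean(pᵢ) + r·mean(uᵢ) with uᵢ = (c − pᵢ)/dᵢ; iteration stops when the
center moves less than `tol` (default 1e-8 px, `max_iter` 1000 — the
citation for the method fixes neither, so correctness is enforced against
a brute-force multi-start Nelder–Mead minimizer of F rather than against
a particular iteration trace). With exactly three points the minimizer is
the closed-form circumcircle and the code short-circuits to it, making
the two routes bit-identical. Collinearity is declared when the smallest
singular value squared of the centered point matrix falls below
1e-12 × span²; the fit then raises a degenerate-geometry error rather
than returning an arbitrarily large circle.

## Hough route: preprocessing chain + accumulator voting

Each frame passes through a fixed chain, in this order: grayscale →
gain/offset intensity adjustment (out = α·in + β, clipped to [0, 255]) →
median blur (odd kernel `blur`) → Canny edge detection → dilation (square
element of side `dilation`, one iteration) → median blur again. The Canny
hysteresis thresholds adapt to scene brightness: low = mean·canny1/10,
high = mean·canny2/10 (clipped to [0, 255]), where mean is the mean
intensity of the blurred frame. The /10 scaling makes the published best
factors (canny1 = 5, canny2 = 14) the conventional 0.5×/1.4×-mean band;
the exact normalization was an open choice and the function is a single
replaceable unit. A frame whose adaptive band collapses (e.g. an
all-black frame) yields no detection rather than an error.

Circle detection votes over radii in [r_min, r_max] (defaults 5 and
270 px — the structure is a *semi*circle, so a clean detection carries
roughly half the perimeter support of a full ring). Two numerical
choices matter and were tuned on the synthetic suite:

* **Radius resolution.** The accumulator is evaluated at a coarse radius
  step (default 6 px), then re-voted at 1 px resolution around the
  winning radius. This resolves single pixels at a fraction of the cost
  of a dense sweep.
* **Peak ranking.** Candidate peaks must exceed a normalized perimeter
  support of 0.25. Among candidates, the peak with the most *raw* votes
  (support × circumference) wins: normalized support alone lets a 5 px
  circle sitting entirely inside a dilated edge blob score a perfect 1.0
  and outrank the real structure. Peaks tied within 5% are broken by
  proximity to the previous frame's center.

Tracking is otherwise per-frame independent; an optional crop region is
applied before preprocessing and detections are mapped back to full-frame
coordinates.

### Grid optimization

The six chain parameters are dataset-specific. `optimize_params` scores
every combination of a parameter grid by the mean over videos of the
Pearson correlation between tracked and manual radii (validation filters
applied first), and returns the arg-max plus the full score table. The
default grid is the published one — α 0.5–3 (step 0.5), β 20–40 (step 5),
blur {25, 27, 29, 35}, dilation 3–7, canny1 4–12 (step 2), canny2
{8, 10, 13, 15, 17} — 15000 combinations, enumerated exhaustively. A
video contributing fewer than `min_pairs` (default 10) usable pairs
scores missing, and a combination with any missing video ranks below
every finite score. Note the published table labels α "Brightness" and β
"Contrast"; given α's 0.5–3 range the conventional gain/offset reading is
implemented, following the printed ranges rather than the labels.

## KZ smoothing

KZ(m, k) is k iterations of a centered moving average of odd width m
(defaults m = 3, k = 2, the settings used for smoothing tracked radii
and centroids; interior impulse response [1, 2, 3, 2, 1]/9). Endpoints
use symmetrically shrinking windows. Gaps split the series into runs
smoothed independently — smoothing never manufactures radii for frames a
tracker rejected — and runs shorter than m pass through unchanged.
Smoothing is off by default for the keypoint route, which validates as
well or better unsmoothed.

## Validation

Automatic and manual radii are paired per frame, then filtered to the
band [100, 270) px applied to *both* sources: 270 px is the tracker's
detection ceiling (and about the manual maximum), and radii below 100 px
are not regarded. Whether the 100 px floor binds the automatic series,
the manual one, or both is ambiguous in the source material; both is the
default and the filters are configurable. Pair counts are reported so
filter effects stay auditable. Both correlation conventions are
reported: pooled over all videos' pairs (the keypoint route's headline
convention) and the mean of per-video coefficients (the Hough route's).

## Kinematic-acoustic analysis

The acoustic analysis window equals one video frame (1/fps s), giving a
1:1 frame join between radius and features. 50 fps series are first
halved to 25 fps by keeping even frames (after tracking, on the level of
analyzed frames). Four features are computed natively per window:

* **amplitude** — linear RMS (no SPL calibration: microphone distance is
  unknowable from the video);
* **f0** — autocorrelation peak within 20–1000 Hz, voiced when the peak
  exceeds 0.3 of lag 0 (the upstream acoustic package decides voicing
  internally; this threshold is the corresponding explicit knob), with
  parabolic lag interpolation;
* **spectral centroid** — power-weighted mean frequency;
* **entropy** — both Wiener entropy (spectral flatness, geometric over
  arithmetic mean of the PSD, 0 = pure tone, 1 = white noise) and
  normalized Shannon entropy of the PSD. The source analyses name
  "Wiener entropy" in one place and "(Shannon) entropy" in another, so
  both are computed and reported.

Spectral statistics use a Welch-averaged PSD (nperseg = min(512, window))
rather than one periodogram: single-periodogram bins are χ²₂-distributed,
which biases the flatness of white noise toward exp(−γ) ≈ 0.56; Welch
averaging restores values near 1. Silent windows report amplitude 0 and
missing spectral features. Additional per-frame features (e.g. a full
externally computed parameter set) can be merged via `extra` columns and
enter every correlation identically.

`correlate_features` reports Pearson r, two-sided p (t transform, n − 2
df) and per-feature n, dropping missing values per feature. No multiple-
testing correction is applied — raw p-values are the convention in the
exploratory analyses this mirrors — and the number of tests is visible
in the output so users can correct downstream. The boom→bark carry-over
analysis takes, for every boom immediately followed by a bark in the same
great-call sequence, the last trackable radius of the boom (from the
unsmoothed series by default, since smoothing can shift the last valid
frame) as predictor and the mean/min/max of each feature over the bark's
frames as responses; booms contribute no acoustic responses. All three
aggregations are always computed.

## Synthetic world

The generator plants known structure so every stage can be tested
without archived recordings or a trained pose network:

* **Videos**: one bright semicircle (flat chord on top, arc below — so
  the semicircle detection claim and the five-point scheme are exercised
  honestly, not a full disk) of known radius trajectory (constant, ramp,
  or sinusoidal sweep in [80, 200] px by default, inside the detectable
  band) on a flat background, 512×384 px, 50 frames, with optional
  seeded clutter (random line segments and disks) to stress the
  Canny/dilate chain.
* **Keypoints**: the five outline points placed exactly on the planted
  circle, plus facial points, with Gaussian jitter (default sd 2 px,
  consistent with the reported ~9.5 px test error at 1920×1080 scaled to
  the synthetic frame), per-point dropout (default 0.1) to likelihood
  0.3, survivors at likelihood U(0.85, 0.99).
* **Call layouts**: 25 boom sequences of mean length 7 frames (176
  frames total) for the per-frame correlation study, and 8 sequences ×
  2 boom–bark pairs (16 pairs) for the carry-over study — the sample
  sizes of the motivating analyses.
* **Audio** (48 kHz): boom frames are a harmonic tone in noise whose
  RMS, f0, harmonic brightness and noise fraction follow linear
  couplings to normalized radius (signs: +, +, −, −, matching the adult
  pattern of the motivating study); bark frames are low-pass noise whose
  cutoff falls with the preceding boom's last radius. Setting all slopes
  to zero gives the null condition.

What passing tests show: the estimators recover exactly what was
planted, at the stated sample sizes, under Gaussian jitter, flat-
background rendering, and linear feature couplings. What they do not
show: performance on real fur, lighting, occlusion, camera shake,
overlapping vocalizers, or reverberant audio — field-scale validation
numbers come from real recordings plus a trained pose network and are
not reproducible at desk scale. The synthetic clean-video tracking bar
(pooled r ≥ 0.9, ≤ 3 px error) is a correctness check of the
implementation, not a field performance claim.

## Problem sizes and determinism

Everything is seeded and deterministic given the seed. The standard
check sizes: 100 noisy arcs + 1000 random triples for the fit oracle;
300 frames for the dropout contract; 5 videos × 50 frames for Hough
tracking; a 2×2 reduced grid for the arg-max property (the 15000-entry
default grid is enumerated but only counted); 100 seeds × 176 frames for
coupling-sign recovery; 40 seeds × 16 pairs for the carry-over sign.
These sizes keep the full suite around six minutes on one core while
leaving the stochastic checks comfortable margins.

## Known limitations

* Single structure per frame; no multi-animal tracking, no ellipse or
  general conic fitting, no 3D triangulation.
* Video containers are not decoded; frames come as image directories or
  in-memory arrays.
* The Hough route's accuracy depends strongly on the preprocessing
  parameters; the defaults here are tuned for the synthetic renders, and
  real footage should be re-optimized per dataset via the grid search
  (the best settings found for 1920×1080 siamang closeups are available
  as `siamang_best_params()`).
* f0 search is bounded below by the window length (a 40 ms window cannot
  resolve periods longer than the window); the default 20–1000 Hz band
  is clamped accordingly.
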