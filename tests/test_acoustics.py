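import numpy as np
import pytest

from sactrack.acoustics import (
    align,
    boom_bark_analysis,
    correlate_features,
    downsample_series,
    frame_features,
    features_to_frame,
)
from sactrack.synthetic import SacSimConfig, simulate_call_study, synthesize_audio
from sactrack.types import AcousticFrameFeatures, CallSegment, Circle, RadiusSeries

SR = 48000
FPS = 25.0


def tone(freq, seconds, sr=SR, amp=0.5):
    t = np.arange(int(seconds * sr)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# feature extraction


def test_pure_tone_features():
    feats = frame_features(tone(220, 1.0), SR, FPS)
    assert len(feats) == 25  # exact partition: 1 s at 25 fps
    for f in feats:
        assert f.f0 == pytest.approx(220, abs=3)
        assert f.spectral_centroid == pytest.approx(220, abs=SR / 512)
        assert f.wiener_entropy < 0.05
        assert f.amplitude == pytest.approx(0.5 / np.sqrt(2), rel=0.01)


def test_white_noise_features(rng):
    feats = frame_features(rng.standard_normal(SR), SR, FPS)
    wiener = np.array([f.wiener_entropy for f in feats])
    assert np.median(wiener) > 0.8
    unvoiced = sum(f.f0 is None for f in feats)
    assert unvoiced >= 0.5 * len(feats)


def test_silence_features():
    feats = frame_features(np.zeros(SR // 5), SR, FPS)
    for f in feats:
        assert f.amplitude == 0.0
        assert f.f0 is None and f.spectral_centroid is None
        assert f.wiener_entropy is None and f.shannon_entropy is None


def test_window_partition_exact():
    n_win = int(round(SR / FPS))
    audio = np.ones(10 * n_win + n_win // 2)  # trailing partial window
    feats = frame_features(audio, SR, FPS)
    assert len(feats) == 10
    assert [f.frame_index for f in feats] == list(range(10))


def test_invalid_fps():
    with pytest.raises(ValueError):
        frame_features(np.zeros(1000), SR, 0)


def test_extra_features_carried():
    feats = frame_features(tone(220, 0.2), SR, FPS, extra={0: {"hnr": 12.5}})
    assert feats[0].extra["hnr"] == 12.5
    df = features_to_frame(feats)
    assert "hnr" in df.columns


# ---------------------------------------------------------------------------
# downsampling


def series_of(n, fps=50.0, missing=()):
    circles = [
        None if i in missing else Circle(10.0, 10.0, 100.0 + i) for i in range(n)
    ]
    return RadiusSeries.from_circles(fps, circles)


def test_downsample_keeps_even_frames():
    out = downsample_series(series_of(10))
    assert out.fps == 25.0
    assert list(out.frame_indices) == [0, 1, 2, 3, 4]
    assert [c.radius for _, c in out] == [100, 102, 104, 106, 108]


def test_downsample_gap_propagates():
    out = downsample_series(series_of(10, missing={2}))
    assert out.get(1) is None


def test_downsample_noop_at_25fps():
    s = series_of(10, fps=25.0)
    assert downsample_series(s) is s


def test_downsample_count_odd():
    out = downsample_series(series_of(11))
    assert len(out) == 6  # ceil(11/2)


# ---------------------------------------------------------------------------
# alignment


def feat_row(i, amp=0.5):
    return AcousticFrameFeatures(i, amp, 200.0, 300.0, 0.3, 0.4)


def test_align_inner_join_cardinality():
    radius = series_of(100, fps=25.0)
    feats = [feat_row(i) for i in range(10, 90)]  # 80 feature frames
    # radius missing on 10 of the overlapping frames
    radius = RadiusSeries(
        25.0,
        [(f, None if 10 <= f < 20 else c) for f, c in radius],
    )
    table = align(radius, feats, segments=None)
    assert len(table) == 70


def test_align_segment_restriction():
    radius = series_of(50, fps=25.0)
    feats = [feat_row(i) for i in range(50)]
    segs = [CallSegment("boom", 5, 14), CallSegment("bark", 20, 24)]
    table = align(radius, feats, segs, call_type="boom")
    assert len(table) <= 10
    assert set(table.frame) <= set(range(5, 15))


def test_align_no_overlap_empty():
    radius = series_of(5, fps=25.0)
    feats = [feat_row(i) for i in range(100, 105)]
    assert len(align(radius, feats)) == 0


# ---------------------------------------------------------------------------
# correlation


def test_correlate_requires_three_rows():
    radius = series_of(2, fps=25.0)
    feats = [feat_row(i) for i in range(2)]
    with pytest.raises(ValueError):
        correlate_features(align(radius, feats))


def test_correlate_zero_variance_flagged():
    radius = series_of(10, fps=25.0)
    feats = [feat_row(i, amp=0.5) for i in range(10)]  # constant amplitude
    results = {c.parameter: c for c in correlate_features(align(radius, feats))}
    assert not results["amplitude"].defined


def test_correlate_recovers_planted_coupling():
    cfg = SacSimConfig(seed=11)
    radius, segs = simulate_call_study(cfg, n_sequences=10, boom_frames=7)
    wave, sr, _ = synthesize_audio(radius, segs, cfg)
    feats = frame_features(wave, sr, cfg.fps)
    results = {
        c.parameter: c
        for c in correlate_features(align(radius, feats, segs, "boom"))
    }
    assert results["amplitude"].r > 0.8
    assert results["f0"].r > 0.8
    assert results["spectral_centroid"].r < -0.5
    assert results["wiener_entropy"].r < -0.5


def test_correlate_null_coupling_small_r():
    coupling = {k: (0.0, sd) for k, (_, sd) in
                SacSimConfig().acoustic_coupling.items()}
    cfg = SacSimConfig(seed=12, acoustic_coupling=coupling)
    radius, segs = simulate_call_study(cfg, n_sequences=29, boom_frames=7)
    wave, sr, _ = synthesize_audio(radius, segs, cfg)
    feats = frame_features(wave, sr, cfg.fps)
    table = align(radius, feats, segs, "boom")
    assert len(table) >= 200
    for c in correlate_features(table):
        if c.parameter in ("amplitude", "f0", "spectral_centroid",
                           "wiener_entropy") and c.defined:
            assert abs(c.r) < 0.2


# ---------------------------------------------------------------------------
# boom -> bark carry-over


def boom_bark_fixture(seed=13, n_sequences=8):
    cfg = SacSimConfig(seed=seed)
    radius, segs = simulate_call_study(
        cfg, n_sequences=n_sequences, boom_frames=6, bark_frames=4,
        pairs_per_sequence=2,
    )
    wave, sr, _ = synthesize_audio(radius, segs, cfg)
    feats = frame_features(wave, sr, cfg.fps)
    return radius, feats, segs


def test_boom_bark_negative_centroid_coupling():
    radius, feats, segs = boom_bark_fixture()
    results = {
        (c.parameter, c.aggregation): c
        for c in boom_bark_analysis(radius, feats, segs)
    }
    mean_centroid = results[("spectral_centroid", "mean")]
    assert mean_centroid.n == 16
    assert mean_centroid.r < -0.3


def test_boom_without_radius_skipped():
    radius, feats, segs = boom_bark_fixture()
    # blank out the radius inside the first boom: that pair must drop
    first_boom = next(s for s in segs if s.call_type == "boom")
    entries = [
        (f, None if first_boom.start_frame <= f <= first_boom.end_frame else c)
        for f, c in radius
    ]
    blanked = RadiusSeries(radius.fps, entries)
    results = boom_bark_analysis(blanked, feats, segs)
    n = {(c.parameter, c.aggregation): c.n for c in results}
    assert n[("spectral_centroid", "mean")] == 15


def test_single_frame_bark_mean_min_max_equal():
    radius = RadiusSeries(25.0, [(0, Circle(10, 10, 150)), (1, None)])
    feats = [feat_row(0), feat_row(1, amp=0.7)]
    segs = [
        CallSegment("boom", 0, 0, "P", "s0"),
        CallSegment("bark", 1, 1, "P", "s0"),
        CallSegment("boom", 2, 2, "P", "s1"),
        CallSegment("bark", 3, 3, "P", "s1"),
    ]
    radius2 = RadiusSeries(
        25.0,
        [(0, Circle(10, 10, 150)), (1, None), (2, Circle(10, 10, 200)), (3, None)],
    )
    feats2 = feats + [feat_row(2), feat_row(3, amp=0.9)]
    vals = {}
    for c in boom_bark_analysis(radius2, feats2, segs):
        if c.parameter == "amplitude":
            vals[c.aggregation] = c
    # with single-frame barks the three aggregations coincide
    assert vals["mean"].n == vals["min"].n == vals["max"].n == 2
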