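import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agidet.data_model import ChannelSeries, RawPhysioStream
from agidet.errors import DataError
from agidet.physio_features import (
    WindowSlice,
    decompose_eda,
    extract_feature_matrix,
    extract_features,
    feature_manifest,
    preprocess,
    rank_features,
    segment_windows,
    wavelet_energies,
    windows_to_frame,
)


def _stream(values, fs=4.0, name="eda", unit="uS"):
    ts = np.arange(len(values)) / fs
    return RawPhysioStream("t", {name: ChannelSeries(fs, ts, np.asarray(values, float), unit)})


class TestPreprocess:
    def test_constant_eda_unchanged(self):
        s = _stream(np.full(480, 5.0))
        out = preprocess(s)
        np.testing.assert_allclose(out.channels["eda"].values, 5.0, atol=1e-9)

    def test_short_gap_linear_interpolation(self):
        # pulse is clipped but not low-pass filtered, so interpolation on a
        # linear in-range signal is exact
        ts = np.concatenate([np.arange(0, 10.0), np.arange(13.0, 60.0)])
        vals = 60.0 + ts
        s = RawPhysioStream("t", {"pulse": ChannelSeries(1.0, ts, vals, "bpm")})
        out = preprocess(s)
        assert out.channels["pulse"].values.size == 60
        assert out.channels["pulse"].unusable == []
        np.testing.assert_allclose(
            out.channels["pulse"].values, 60.0 + np.arange(60.0), atol=1e-9)

    def test_long_gap_marked_unusable(self):
        ts = np.concatenate([np.arange(0, 10.0), np.arange(20.0, 60.0)])
        s = RawPhysioStream("t", {"temp": ChannelSeries(1.0, ts, np.ones_like(ts), "degC")})
        out = preprocess(s)
        assert out.channels["temp"].unusable == [(9.0, 20.0)]

    def test_acc_magnitude_345(self):
        fs = 32.0
        n = 64
        ts = np.arange(n) / fs
        chans = {
            "acc_x": ChannelSeries(fs, ts, np.full(n, 0.6), "g"),
            "acc_y": ChannelSeries(fs, ts, np.full(n, 0.8), "g"),
            "acc_z": ChannelSeries(fs, ts, np.zeros(n), "g"),
        }
        out = preprocess(RawPhysioStream("t", chans))
        np.testing.assert_allclose(out.channels["acc_mag"].values, 1.0, atol=1e-9)

    def test_empty_stream_rejected(self):
        with pytest.raises(DataError):
            preprocess(RawPhysioStream("t", {}))


class TestDecomposeEda:
    def test_constant_input(self):
        s = _stream(np.full(480, 3.0))
        tonic, phasic = decompose_eda(s.channels["eda"])
        np.testing.assert_allclose(tonic.values, 3.0, atol=1e-9)
        np.testing.assert_allclose(phasic.values, 0.0, atol=1e-9)

    def test_identity_always_holds(self, rng):
        vals = np.abs(rng.normal(2, 0.5, size=1200)).cumsum() * 0.001 + 2
        s = _stream(vals)
        tonic, phasic = decompose_eda(s.channels["eda"])
        assert np.max(np.abs(tonic.values + phasic.values - vals)) < 1e-9

    def test_ramp_plus_sine_recovery(self):
        fs = 4.0
        t = np.arange(0, 300.0, 1 / fs)
        ramp = 2.0 + 0.01 * t
        sine = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        tonic, phasic = decompose_eda(ChannelSeries(fs, t, ramp + sine, "uS"))
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(tonic.values - ramp) / rms(ramp) < 0.05
        assert rms(phasic.values - sine) / rms(sine) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            decompose_eda(ChannelSeries(4.0, np.arange(40) / 4.0, np.ones(40), "uS"))


class TestSegmentWindows:
    def test_600s_gives_10_windows(self):
        s = _stream(np.ones(600), fs=1.0, name="temp")
        assert len(segment_windows(s)) == 10

    def test_59s_gives_none(self):
        s = _stream(np.ones(59), fs=1.0, name="temp")
        assert segment_windows(s) == []

    def test_125s_gives_2(self):
        s = _stream(np.ones(125), fs=1.0, name="temp")
        wins = segment_windows(s, 60, 60)
        assert len(wins) == 2
        assert wins[-1].end == 120.0

    @given(
        T=st.integers(10, 500),
        W=st.integers(5, 120),
        S=st.integers(1, 90),
    )
    @settings(max_examples=60, deadline=None)
    def test_closed_form_count(self, T, W, S):
        s = _stream(np.ones(T), fs=1.0, name="temp")
        expected = 0 if T < W else int(np.floor((T - W) / S)) + 1
        assert len(segment_windows(s, float(W), float(S))) == expected

    def test_unusable_windows_dropped(self):
        ts = np.concatenate([np.arange(0, 100.0), np.arange(110.0, 300.0)])
        s = RawPhysioStream("t", {"temp": ChannelSeries(1.0, ts, np.ones_like(ts), "degC")})
        pre = preprocess(s)
        wins = segment_windows(pre)
        starts = [w.start for w in wins]
        assert 60.0 not in starts  # overlaps the [99, 110) gap


class TestExtractFeatures:
    def test_constant_window(self):
        w = WindowSlice(0, 60, {"eda": (4.0, np.full(240, 2.0))})
        f = extract_features(w).features
        assert f["eda_stat_sd"] == 0.0
        assert f["eda_time_zero_crossings"] == 0
        assert f["eda_freq_entropy"] == 0.0

    def test_pure_sine_dominant_frequency(self):
        fs = 4.0
        t = np.arange(240) / fs
        w = WindowSlice(0, 60, {"eda": (fs, np.sin(2 * np.pi * 1.0 * t))})
        f = extract_features(w).features
        resolution = fs / min(240, int(32 * fs))
        assert abs(f["eda_freq_dominant"] - 1.0) <= resolution

    def test_energy_identity(self, rng):
        x = rng.normal(size=240)
        w = WindowSlice(0, 60, {"eda": (4.0, x)})
        f = extract_features(w).features
        assert abs(f["eda_time_rms"] ** 2 * 240 - f["eda_time_energy"]) < 1e-6 * abs(
            f["eda_time_energy"])

    def test_all_values_finite(self, physio_session):
        stream, _, _ = physio_session
        windows = extract_feature_matrix(stream)
        df = windows_to_frame(windows)
        feats = df.drop(columns=["window_start", "window_end", "label"])
        assert np.isfinite(feats.to_numpy(dtype=float)).all()

    def test_manifest_order_identical_across_windows(self, physio_session):
        stream, _, _ = physio_session
        windows = extract_feature_matrix(stream)
        names = list(windows[0].features)
        assert all(list(w.features) == names for w in windows)
        assert names == feature_manifest()

    def test_manifest_size_near_150(self):
        n = len(feature_manifest())
        assert 120 <= n <= 180

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(2.0, 0.3, size=480)
        a = _stream(vals)
        ts = np.arange(480) / 4.0 + 12345.0
        b = RawPhysioStream("t", {"eda": ChannelSeries(4.0, ts, vals, "uS")})
        fa = windows_to_frame(extract_feature_matrix(a))
        fb = windows_to_frame(extract_feature_matrix(b))
        cols = [c for c in fa.columns if c not in ("window_start", "window_end", "label")]
        np.testing.assert_allclose(fa[cols].to_numpy(), fb[cols].to_numpy(), atol=1e-8)

    def test_pulse_has_no_spectral_features(self):
        names = feature_manifest()
        assert not any(n.startswith("pulse_freq") or n.startswith("pulse_tf") for n in names)


class TestWavelet:
    def test_energy_conservation_rough(self, rng):
        # db4 with periodic extension conserves total energy per level
        x = rng.normal(size=256)
        details, approx = wavelet_energies(x, levels=4)
        total = sum(details) + approx
        assert abs(total - np.sum(x**2)) / np.sum(x**2) < 0.05

    def test_constant_signal_energy_in_approximation(self):
        x = np.full(256, 2.0)
        details, approx = wavelet_energies(x, levels=4)
        assert sum(details) < 1e-9 * approx


class TestRankFeatures:
    class _FakeModel:
        def __init__(self, importances):
            self.feature_importances_ = np.asarray(importances)

    def test_descending_order_with_canonical_tiebreak(self):
        model = self._FakeModel([0.2, 0.5, 0.2, 0.1])
        ranked = rank_features(model, ["a", "b", "c", "d"])
        assert [n for n, _ in ranked] == ["b", "a", "c", "d"]

    def test_uniform_importances_keep_canonical_order(self):
        model = self._FakeModel([0.25] * 4)
        ranked = rank_features(model, ["w", "x", "y", "z"])
        assert [n for n, _ in ranked] == ["w", "x", "y", "z"]

    def test_dominant_eda_participant_has_tonic_feature_on_top(self, small_cohort,
                                                               small_cohort_features):
        from agidet import physio_models

        eda_pid = next(b.participant_id for b in small_cohort
                       if b.physio_config.dominant_channel == "eda")
        df = small_cohort_features[eda_pid]
        X, y, names = physio_models.frame_to_xy(df)
        model = physio_models.train_classifier(X, y, "extra_trees", seed=0)
        top10 = [n for n, _ in rank_features(model, names)[:10]]
        assert any(n.startswith("eda_tonic") for n in top10), top10

    def test_dominant_acc_participant_ranks_acc_first(self, small_cohort,
                                                      small_cohort_features):
        from agidet import physio_models

        acc_pid = next(b.participant_id for b in small_cohort
                       if b.physio_config.dominant_channel == "acc")
        df = small_cohort_features[acc_pid]
        X, y, names = physio_models.frame_to_xy(df)
        model = physio_models.train_classifier(X, y, "extra_trees", seed=0)
        first = rank_features(model, names)[0][0]
        assert first.startswith("acc"), first
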