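import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agidet.data_model import EpisodeLabel
from agidet.errors import ContractError
from agidet.pose_features import (
    FEATURE_NAMES,
    build_windows,
    extract_pose_features,
    frames_to_features,
    normalize_pose,
    reduce_features,
    trunk_length,
)
from agidet.synthetic import PoseFrame


def _frame(kps, t=0.0, pid="p1"):
    return PoseFrame(t, pid, np.asarray(kps, dtype=float))


def _random_frame(rng, t=0.0, pid="p1"):
    pts = rng.uniform(10, 300, size=(14, 2))
    conf = rng.uniform(0.5, 1.0, size=(14, 1))
    return _frame(np.hstack([pts, conf]), t, pid)


def brute_force_features(prev: PoseFrame, curr: PoseFrame) -> dict:
    """Independent recomputation with the math module only."""
    p, c = prev.keypoints, curr.keypoints
    hip = ((c[8][0] + c[9][0]) / 2, (c[8][1] + c[9][1]) / 2)
    trunk = math.hypot(c[0][0] - hip[0], c[0][1] - hip[1])
    out = {}
    for k in range(14):
        out[f"eu_{k + 1}"] = math.hypot(c[k][0] - p[k][0], c[k][1] - p[k][1])
    for j in range(2, 14):
        out[f"eu_1_{j + 1}"] = math.hypot(c[j][0] - c[0][0], c[j][1] - c[0][1])
    for i in range(1, 14):
        out[f"por_{i + 1}_1"] = math.hypot(c[i][0] - c[0][0], c[i][1] - c[0][1]) / trunk
    for j in range(1, 14):
        ang = math.degrees(math.atan2(-(c[j][1] - c[0][1]), c[j][0] - c[0][0])) % 360.0
        out[f"ang_1_{j + 1}"] = ang
    return out


class TestNormalizePose:
    def test_root_at_origin(self, rng):
        f = _random_frame(rng)
        n = normalize_pose(f)
        np.testing.assert_allclose(n.keypoints[0, :2], 0.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        f = _random_frame(rng)
        scaled = _frame(np.hstack([f.keypoints[:, :2] * 2.0 + 17.0, f.keypoints[:, 2:]]))
        np.testing.assert_allclose(normalize_pose(f).keypoints[:, :2],
                                   normalize_pose(scaled).keypoints[:, :2], atol=1e-9)

    def test_normalized_trunk_length_one(self, rng):
        for _ in range(20):
            n = normalize_pose(_random_frame(rng))
            assert trunk_length(n) == pytest.approx(1.0, abs=1e-9)

    def test_missing_root_unusable(self, rng):
        f = _random_frame(rng)
        f.keypoints[0, 2] = 0.0
        assert normalize_pose(f) is None

    def test_zero_trunk_unusable(self, rng):
        f = _random_frame(rng)
        f.keypoints[8, :2] = f.keypoints[0, :2]
        f.keypoints[9, :2] = f.keypoints[0, :2]
        assert normalize_pose(f) is None


class TestExtractPoseFeatures:
    def test_identical_frames_zero_displacement(self, rng):
        f = _random_frame(rng)
        feats = extract_pose_features(f, f)
        for k in range(1, 15):
            assert feats[f"eu_{k}"] == 0.0

    def test_345_distance(self, rng):
        f = _random_frame(rng)
        f.keypoints[0, :2] = (0.0, 0.0)
        f.keypoints[4, :2] = (3.0, 4.0)
        feats = extract_pose_features(f, f)
        assert feats["eu_1_5"] == pytest.approx(5.0)

    def test_straight_above_is_90_degrees(self, rng):
        f = _random_frame(rng)
        f.keypoints[1, 0] = f.keypoints[0, 0]
        f.keypoints[1, 1] = f.keypoints[0, 1] - 25.0  # above = smaller image y
        feats = extract_pose_features(f, f)
        assert feats["ang_1_2"] == pytest.approx(90.0)

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(100):
            prev, curr = _random_frame(rng, 0.0), _random_frame(rng, 0.2)
            got = extract_pose_features(prev, curr)
            want = brute_force_features(prev, curr)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-9), name

    def test_person_mismatch_rejected(self, rng):
        with pytest.raises(ContractError):
            extract_pose_features(_random_frame(rng, pid="a"), _random_frame(rng, pid="b"))

    def test_missing_keypoint_gives_nan(self, rng):
        f = _random_frame(rng)
        f.keypoints[5, 2] = 0.0
        feats = extract_pose_features(f, f)
        assert math.isnan(feats["eu_6"])
        assert math.isnan(feats["eu_1_6"])
        assert math.isnan(feats["por_6_1"])
        assert math.isnan(feats["ang_1_6"])

    def test_canonical_order(self, rng):
        f = _random_frame(rng)
        assert tuple(extract_pose_features(f, f)) == FEATURE_NAMES

    def test_por_scale_invariant_eu_scales_linearly(self, rng):
        prev, curr = _random_frame(rng, 0.0), _random_frame(rng, 0.2)
        s = 3.0
        prev2 = _frame(np.hstack([prev.keypoints[:, :2] * s, prev.keypoints[:, 2:]]), 0.0)
        curr2 = _frame(np.hstack([curr.keypoints[:, :2] * s, curr.keypoints[:, 2:]]), 0.2)
        f1 = extract_pose_features(prev, curr)
        f2 = extract_pose_features(prev2, curr2)
        for name in FEATURE_NAMES:
            if name.startswith("por"):
                assert f2[name] == pytest.approx(f1[name], abs=1e-9)
            elif name.startswith("eu"):
                assert f2[name] == pytest.approx(s * f1[name], rel=1e-9)


class TestReduceFeatures:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        assert reduce_features(df, 0.8) == ["a", "c"]

    def test_orthogonal_columns_all_retained(self, rng):
        X = rng.normal(size=(500, 8))
        corr = np.corrcoef(X.T)
        assert np.abs(corr - np.eye(8)).max() < 0.8  # premise of the test
        assert reduce_features(X, 0.8) == [f"f{i}" for i in range(8)]

    def test_greedy_result_is_prefix_valid(self, rng):
        """Brute-force check: feature j retained iff no earlier retained
        feature correlates above the threshold."""
        base = rng.normal(size=(200, 4))
        X = np.column_stack([base, base[:, 0] + 0.05 * rng.normal(size=200),
                             base[:, 1] * -1.0, rng.normal(size=200)])
        names = [f"f{i}" for i in range(X.shape[1])]
        retained = reduce_features(X, 0.8, names=names)
        corr = pd.DataFrame(X, columns=names).corr().abs()
        kept = []
        for n in names:
            if all(corr.loc[n, k] <= 0.8 for k in kept):
                kept.append(n)
        assert retained == kept

    def test_idempotent(self, rng):
        X = rng.normal(size=(150, 10))
        X[:, 5] = X[:, 0] * 2 + 0.01 * rng.normal(size=150)
        names = [f"f{i}" for i in range(10)]
        once = reduce_features(X, 0.8, names=names)
        idx = [names.index(n) for n in once]
        twice = reduce_features(X[:, idx], 0.8, names=once)
        assert twice == once

    def test_no_retained_pair_above_threshold(self, pose_windows):
        mat = pd.DataFrame(np.vstack([w.frames for w in pose_windows]),
                           columns=list(FEATURE_NAMES))
        retained = reduce_features(mat, 0.8)
        # constant columns have undefined correlation, treated as 0
        corr = mat[retained].corr().abs().fillna(0.0).to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.8 + 1e-12

    def test_constant_columns_retained_unless_duplicated(self):
        X = np.column_stack([np.ones(50), np.ones(50), np.full(50, 2.0),
                             np.arange(50, dtype=float)])
        assert reduce_features(X, 0.8) == ["f0", "f2", "f3"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_idempotence_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 6))
        X[:, 3] = X[:, 1] + 0.1 * rng.normal(size=60)
        names = [f"f{i}" for i in range(6)]
        once = reduce_features(X, 0.8, names=names)
        idx = [names.index(n) for n in once]
        assert reduce_features(X[:, idx], 0.8, names=once) == once


class TestBuildWindows:
    def _features(self, T, fps):
        n = int(T * fps)
        ts = np.arange(n) / fps
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(n, 3)),
                          columns=["eu_1", "eu_2", "eu_3"])
        df.insert(0, "timestamp", ts)
        return df

    def test_60s_stream_gives_31_windows(self):
        df = self._features(60, 10.0)
        assert len(build_windows(df, [], fps=10.0)) == 31

    def test_30s_stream_gives_1_window(self):
        df = self._features(30, 10.0)
        assert len(build_windows(df, [], fps=10.0)) == 1

    def test_too_short_gives_none(self):
        df = self._features(20, 10.0)
        assert build_windows(df, [], fps=10.0) == []

    def test_positive_count_matches_bruteforce(self, pose_session, pose_cfg):
        frames, labels = pose_session
        df = frames_to_features(frames)
        windows = build_windows(df, labels, fps=pose_cfg.fps)
        agit = [e for e in labels if e.label == "agitation"]
        expected = sum(
            1 for w in windows
            if sum(max(0.0, min(w.end, e.end) - max(w.start, e.start)) for e in agit) >= 15.0
        )
        assert sum(w.label == "agitation" for w in windows) == expected
        assert expected > 0

    def test_uniform_frame_counts(self, pose_windows, pose_cfg):
        n = int(round(30.0 * pose_cfg.fps))
        assert all(w.frames.shape[0] == n for w in pose_windows)

    def test_windows_with_many_missing_frames_dropped(self):
        df = self._features(60, 10.0)
        df.loc[100:400, ["eu_1", "eu_2", "eu_3"]] = np.nan  # 30 s hole
        windows = build_windows(df, [], fps=10.0)
        assert len(windows) < 31

    def test_episode_label_on_windows(self):
        df = self._features(100, 10.0)
        eps = [EpisodeLabel("p1", 40, 80, "agitation", "synthetic_truth")]
        windows = build_windows(df, eps, fps=10.0)
        w = next(w for w in windows if w.start == 50.0)
        assert w.label == "agitation"  # fully inside the episode
        w0 = next(w for w in windows if w.start == 0.0)
        assert w0.label == "normal"
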