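"""Geometric features from 14-keypoint pose streams.

Per consecutive-frame pair the feature vector holds, in canonical order:

* ``eu_k`` (k = 1..14)  — temporal displacement of keypoint k between the
  previous and current frame, in pixels;
* ``eu_1_j`` (j = 3..14) — distance from keypoint 1 (the neck/torso root)
  to keypoint j, in pixels;
* ``por_i_1`` (i = 2..14) — trunk-normalized distance of keypoint i from
  keypoint 1 (scale-invariant relative position);
* ``ang_1_j`` (j = 2..14) — angle of keypoint j seen from keypoint 1
  against the image horizontal, degrees in [0, 360).

52 names total.  Keypoints reported with confidence 0 yield NaN features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EpisodeLabel, interval_overlap
from .errors import ContractError
from .synthetic import HIP_IDX, PoseFrame

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"eu_{k}" for k in range(1, 15)]
    + [f"eu_1_{j}" for j in range(3, 15)]
    + [f"por_{i}_1" for i in range(2, 15)]
    + [f"ang_1_{j}" for j in range(2, 15)]
)


def trunk_length(frame: PoseFrame) -> float:
    """Distance from keypoint 1 to the hip midpoint."""
    kp = frame.keypoints
    hip_mid = (kp[HIP_IDX[0], :2] + kp[HIP_IDX[1], :2]) / 2.0
    return float(np.linalg.norm(kp[0, :2] - hip_mid))


def normalize_pose(frame: PoseFrame) -> PoseFrame | None:
    """Translate keypoint 1 to the origin and scale by trunk length.

    Returns ``None`` for unusable frames (root missing or zero trunk).
    The caller keeps the original frame for pixel-space features.
    """
    kp = frame.keypoints
    if kp[0, 2] <= 0:
        return None
    trunk = trunk_length(frame)
    if trunk == 0:
        return None
    out = kp.copy()
    out[:, :2] = (kp[:, :2] - kp[0, :2]) / trunk
    return PoseFrame(frame.timestamp, frame.person_id, out)


def extract_pose_features(prev: PoseFrame, curr: PoseFrame) -> dict[str, float]:
    """Feature vector for one consecutive frame pair (canonical order)."""
    if prev.person_id != curr.person_id:
        raise ContractError("frames belong to different persons")
    p, c = prev.keypoints, curr.keypoints
    trunk = trunk_length(curr)
    feats: dict[str, float] = {}
    for k in range(14):
        ok = p[k, 2] > 0 and c[k, 2] > 0
        feats[f"eu_{k + 1}"] = float(np.linalg.norm(c[k, :2] - p[k, :2])) if ok else float("nan")
    root_ok = c[0, 2] > 0
    for j in range(2, 14):  # eu_1_3 .. eu_1_14
        ok = root_ok and c[j, 2] > 0
        feats[f"eu_1_{j + 1}"] = float(np.linalg.norm(c[j, :2] - c[0, :2])) if ok else float("nan")
    for i in range(1, 14):  # por_2_1 .. por_14_1
        ok = root_ok and c[i, 2] > 0 and trunk > 0
        feats[f"por_{i + 1}_1"] = (
            float(np.linalg.norm(c[i, :2] - c[0, :2]) / trunk) if ok else float("nan")
        )
    for j in range(1, 14):  # ang_1_2 .. ang_1_14
        ok = root_ok and c[j, 2] > 0
        if ok:
            dx = c[j, 0] - c[0, 0]
            dy = c[j, 1] - c[0, 1]  # image y grows downward; flip for math convention
            feats[f"ang_1_{j + 1}"] = float(np.degrees(np.arctan2(-dy, dx)) % 360.0)
        else:
            feats[f"ang_1_{j + 1}"] = float("nan")
    return feats


def frames_to_features(frames: list[PoseFrame]) -> pd.DataFrame:
    """Per-frame feature matrix for a time-ordered single-person stream.

    Row ``i`` pairs frame ``i`` with frame ``i-1``; the first frame is
    skipped.  Index column ``timestamp`` carries the current frame's time.
    """
    rows, ts = [], []
    for prev, curr in zip(frames, frames[1:]):
        rows.append(extract_pose_features(prev, curr))
        ts.append(curr.timestamp)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "timestamp", ts)
    return df


# ---------------------------------------------------------------------------
# Correlation-threshold reduction
# ---------------------------------------------------------------------------

def reduce_features(matrix: pd.DataFrame | np.ndarray, threshold: float = 0.8,
                    names: list[str] | None = None) -> list[str]:
    """Greedy correlation filter in canonical column order.

    A feature is dropped iff its absolute Pearson correlation with an
    already-retained feature exceeds ``threshold``.  Constant columns have
    undefined correlation, treated as 0 — retained unless an exact
    duplicate of a retained column.  The retained set never contains a
    pair above the threshold, and the operation is idempotent.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = names or [f"f{i}" for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("need >= 2 rows to estimate correlations")
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    retained: list[int] = []
    for j in range(X.shape[1]):
        drop = False
        for i in retained:
            if sd[i] == 0.0 or sd[j] == 0.0:
                corr = 1.0 if np.array_equal(X[:, i], X[:, j]) else 0.0
            else:
                corr = float(np.dot(Xc[:, i], Xc[:, j]) / (X.shape[0] * sd[i] * sd[j]))
            if abs(corr) > threshold or (corr == 1.0 and sd[j] == 0.0):
                drop = True
                break
        if not drop:
            retained.append(j)
    return [names[j] for j in retained]


# ---------------------------------------------------------------------------
# Sliding sequence windows
# ---------------------------------------------------------------------------

@dataclass
class PoseWindow:
    """One sliding window of per-frame feature vectors."""

    start: float
    end: float
    frames: np.ndarray  # (n_frames, n_features)
    label: str | None = None


def build_windows(
    features: pd.DataFrame,
    episodes: list[EpisodeLabel],
    fps: float,
    window_s: float = 30.0,
    stride_s: float = 1.0,
    overlap_fraction: float = 0.5,
    max_missing_frac: float = 0.2,
    feature_names: list[str] | None = None,
) -> list[PoseWindow]:
    """Cut labelled sliding windows out of a per-frame feature matrix.

    Window count over a stream of duration T is ``floor((T-W)/S) + 1``.
    Windows whose fraction of missing frames exceeds ``max_missing_frac``
    are dropped; remaining missing values are filled forward then backward
    within the window (last observation carried forward).
    """
    names = feature_names or [c for c in features.columns if c != "timestamp"]
    ts = features["timestamp"].to_numpy(dtype=float)
    vals = features[names].to_numpy(dtype=float)
    if ts.size == 0:
        return []
    t0 = float(ts[0])
    T = float(ts[-1] - ts[0]) + 1.0 / fps
    if T < window_s:
        return []
    n_per = int(round(window_s * fps))
    k_max = int(np.floor((T - window_s) / stride_s + 1e-9))
    agit = [(e.start, e.end) for e in episodes if e.label == "agitation"]
    out: list[PoseWindow] = []
    for k in range(k_max + 1):
        start = t0 + k * stride_s
        end = start + window_s
        i0, i1 = np.searchsorted(ts, [start - 1e-9, end - 1e-9])
        block = vals[i0:i1]
        if block.shape[0] < n_per:  # absent frames pad as missing rows
            pad = np.full((n_per - block.shape[0], block.shape[1]), np.nan)
            block = np.vstack([block, pad])
        elif block.shape[0] > n_per:
            block = block[:n_per]
        missing = np.isnan(block).any(axis=1).mean()
        if missing > max_missing_frac:
            continue
        block = pd.DataFrame(block).ffill().bfill().to_numpy()
        if np.isnan(block).any():
            continue  # a column with no observation at all in this window
        ov = sum(interval_overlap(start, end, a0, a1) for a0, a1 in agit)
        label = "agitation" if ov >= overlap_fraction * window_s else "normal"
        out.append(PoseWindow(start, end, block, label))
    return out
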