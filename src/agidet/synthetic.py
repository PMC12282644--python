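"""Synthetic wristband, biomarker, and skeletal-keypoint generators.

The generators emit the signal regimes the downstream pipeline is designed
for: agitation episodes 2-23 minutes long preceded by a pre-agitation lead
during which the affected channels ramp from their normal to their agitated
levels while the signal *pattern* (burst rate, short-term variability)
changes from the start of the lead.  Everything is deterministic under the
config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .data_model import (
    BiomarkerRecord,
    ChannelSeries,
    EpisodeLabel,
    RawPhysioStream,
    save_labels,
    save_physio_csv,
)
from .errors import ConfigError

# sampling rates (Hz) for the raw channels; wearable-device conventions
RATES = {"acc_x": 32.0, "acc_y": 32.0, "acc_z": 32.0, "eda": 4.0, "temp": 1.0, "pulse": 0.1}
UNITS = {"acc_x": "g", "acc_y": "g", "acc_z": "g", "eda": "uS", "temp": "degC", "pulse": "bpm"}


@dataclass
class PhysioSimConfig:
    duration_s: float = 3600.0
    n_episodes: int = 2
    episode_duration_range_s: tuple[float, float] = (120.0, 1380.0)
    preagitation_lead_s: float = 420.0
    pulse_normal: tuple[float, float] = (67.5, 12.4)    # (mean bpm, sd)
    pulse_agitated: tuple[float, float] = (100.0, 11.6)
    activity_counts_normal_range: tuple[float, float] = (0.0, 100.0)
    activity_counts_agitated_range: tuple[float, float] = (50.0, 140.0)
    eda_tonic_shift: float = 1.5     # uS added during episodes
    temp_shift: float = 0.4          # degC added during episodes
    seed: int = 0
    participant_id: str = "sim"
    #: channel whose agitated shift is amplified for this participant;
    #: the other shifted channels are attenuated (inter-individual variability)
    dominant_channel: str = "eda"    # 'eda' | 'acc' | 'temp'
    baseline_pulse_offset: float = 0.0

    def validate(self) -> "PhysioSimConfig":
        lo, hi = self.episode_duration_range_s
        if not (0 < lo <= hi):
            raise ConfigError("bad episode duration range")
        if self.dominant_channel not in ("eda", "acc", "temp"):
            raise ConfigError(f"unknown dominant channel {self.dominant_channel!r}")
        margin = 120.0
        need = self.n_episodes * (hi + self.preagitation_lead_s + margin) + margin
        if self.n_episodes and need > self.duration_s:
            raise ConfigError(
                f"{self.n_episodes} episodes (≤{hi:.0f}s each) plus "
                f"{self.preagitation_lead_s:.0f}s leads do not fit in {self.duration_s:.0f}s"
            )
        return self


@dataclass
class PoseSimConfig:
    duration_s: float = 600.0
    fps: float = 15.0
    behaviors_normal: tuple[str, ...] = ("idle", "walk")
    behaviors_agitated: tuple[str, ...] = ("pace", "rock", "kick", "flail")
    n_episodes: int = 1
    episode_duration_range_s: tuple[float, float] = (120.0, 240.0)
    preagitation_lead_s: float = 60.0
    noise_sd_px: float = 1.0
    seed: int = 0
    participant_id: str = "sim"

    def validate(self) -> "PoseSimConfig":
        known = {"idle", "walk", "pace", "rock", "kick", "flail"}
        for b in self.behaviors_normal + self.behaviors_agitated:
            if b not in known:
                raise ConfigError(f"unknown behavior {b!r}")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigError("fps and duration must be positive")
        margin = 30.0
        hi = self.episode_duration_range_s[1]
        need = self.n_episodes * (hi + self.preagitation_lead_s + margin) + margin
        if self.n_episodes and need > self.duration_s:
            raise ConfigError("episodes do not fit in pose duration")
        return self


# ---------------------------------------------------------------------------
# Episode scheduling (shared)
# ---------------------------------------------------------------------------

def schedule_episodes(
    rng: np.random.Generator,
    duration_s: float,
    n_episodes: int,
    dur_range: tuple[float, float],
    lead_s: float,
    margin_s: float = 120.0,
    snap_s: float = 60.0,
) -> list[tuple[float, float]]:
    """Place non-overlapping (onset, end) pairs leaving room for each lead.

    Onsets and durations snap to ``snap_s`` (minute-resolution, as clinical
    notes would be).  Raises :class:`ConfigError` when they cannot fit.
    """
    if n_episodes == 0:
        return []
    lo, hi = dur_range
    durs = []
    for _ in range(n_episodes):
        d = rng.uniform(lo, hi)
        durs.append(max(snap_s, round(d / snap_s) * snap_s))
    need = sum(durs) + n_episodes * (lead_s + margin_s) + margin_s
    if need > duration_s:
        raise ConfigError(f"episodes need {need:.0f}s, have {duration_s:.0f}s")
    slack = duration_s - need
    # distribute the slack randomly between the blocks
    cuts = np.sort(rng.uniform(0.0, slack, size=n_episodes))
    episodes = []
    t = margin_s
    prev_cut = 0.0
    for d, cut in zip(durs, cuts):
        t += lead_s + (cut - prev_cut)
        prev_cut = cut
        onset = round(t / snap_s) * snap_s
        episodes.append((onset, onset + d))
        t = onset + d + margin_s
    return episodes


# ---------------------------------------------------------------------------
# Physiological generator
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sd: float, coef: float = 0.95) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd`` on a 1-s lattice."""
    e = rng.normal(0.0, sd * np.sqrt(1.0 - coef**2), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = coef * x[i - 1] + e[i]
    return x


def _arousal_profiles(duration_s: float, episodes, lead_s: float):
    """Per-second arousal a(t) in [0,1] (linear ramp then plateau) and the
    binary pattern-change flag p(t) (set from lead start to episode end)."""
    n = int(round(duration_s))
    t = np.arange(n, dtype=float)
    a = np.zeros(n)
    p = np.zeros(n, dtype=bool)
    for onset, end in episodes:
        ramp = (t >= onset - lead_s) & (t < onset)
        a[ramp] = np.maximum(a[ramp], (t[ramp] - (onset - lead_s)) / lead_s)
        a[(t >= onset) & (t < end)] = 1.0
        p |= (t >= onset - lead_s) & (t < end)
    return a, p


def _phasic_bursts(rng, n_s: int, rate_per_min: np.ndarray, fs: float) -> np.ndarray:
    """Poisson burst train convolved with a rise/decay kernel, at ``fs`` Hz."""
    n = int(n_s * fs)
    prob = rate_per_min / 60.0 / fs
    impulses = (rng.uniform(size=n) < np.repeat(prob, int(fs))[:n]).astype(float)
    impulses *= rng.lognormal(mean=-1.2, sigma=0.4, size=n)  # burst amplitudes ~0.3 uS
    k_t = np.arange(0, 8.0, 1.0 / fs)
    kernel = (1 - np.exp(-k_t / 0.7)) * np.exp(-k_t / 3.0)
    out = fftconvolve(impulses, kernel)[:n]
    return out


def generate_physio(config: PhysioSimConfig):
    """Generate one participant session.

    Returns ``(RawPhysioStream, list[BiomarkerRecord], list[EpisodeLabel])``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    episodes = schedule_episodes(
        rng, config.duration_s, config.n_episodes,
        config.episode_duration_range_s, config.preagitation_lead_s,
    )
    n_s = int(round(config.duration_s))
    a, p = _arousal_profiles(config.duration_s, episodes, config.preagitation_lead_s)

    # dominant-channel gains: amplify one modality, attenuate the others
    gains = {"eda": 0.25, "acc": 0.25, "temp": 0.25}
    gains[config.dominant_channel] = 2.0

    # ---- pulse (0.1 Hz) ------------------------------------------------
    mu_n, sd_n = config.pulse_normal
    mu_a, sd_a = config.pulse_agitated
    mu_n = mu_n + config.baseline_pulse_offset
    # the movement-dominant phenotype expresses agitation in acc, not pulse
    pulse_scale = 0.4 if config.dominant_channel == "acc" else 1.0
    mean_t = mu_n + a * (mu_a - mu_n) * pulse_scale
    sd_t = sd_n + a * (sd_a - sd_n)
    pulse_sec = mean_t + _ar1(rng, n_s, 1.0) * sd_t * 0.35
    pulse_sec += p * rng.normal(0.0, 4.0, size=n_s)  # pattern change: extra variability
    idx = np.arange(5, n_s, 10)
    pulse_ts = idx.astype(float)
    pulse_vals = np.clip(pulse_sec[idx], 25.0, 240.0)

    # ---- EDA (4 Hz): tonic drift + shift + phasic bursts ---------------
    fs_eda = RATES["eda"]
    tonic_base = 2.0 + _ar1(rng, n_s, 0.15, coef=0.999)
    tonic = tonic_base + a * config.eda_tonic_shift * gains["eda"]
    burst_rate = np.where(a >= 1.0, 3.0, np.where(p, 2.0, 1.0))  # bursts/min
    phasic = _phasic_bursts(rng, n_s, burst_rate, fs_eda)
    eda_sec = np.repeat(tonic, int(fs_eda))[: int(n_s * fs_eda)] + phasic
    eda_sec += rng.normal(0.0, 0.01, size=eda_sec.size)
    eda_ts = np.arange(eda_sec.size) / fs_eda
    eda_vals = np.clip(eda_sec, 0.01, None)

    # ---- temperature (1 Hz) --------------------------------------------
    temp = 33.5 + _ar1(rng, n_s, 0.05, coef=0.999) + a * config.temp_shift * gains["temp"]
    temp += rng.normal(0.0, 0.01, size=n_s)
    temp_ts = np.arange(n_s, dtype=float)

    # ---- accelerometer (32 Hz) -----------------------------------------
    fs_acc = RATES["acc_x"]
    n_min = n_s // 60
    lo_n, hi_n = config.activity_counts_normal_range
    lo_a, hi_a = config.activity_counts_agitated_range
    a_min = np.array([a[m * 60:(m + 1) * 60].mean() for m in range(n_min)])
    counts = rng.uniform(lo_n, hi_n, size=n_min) * (1 - a_min) + rng.uniform(
        lo_a, hi_a, size=n_min) * a_min
    counts = np.round(counts).astype(int)
    # per-sample jitter SD scales with the minute's activity level; the
    # acc-dominant participant gets an extra arousal-locked jitter term
    # (count ranges alone overlap between regimes)
    sd_per_min = 0.01 + 0.0012 * counts * gains["acc"]
    sd_sec = np.repeat(sd_per_min, 60)[:n_s]
    if sd_sec.size < n_s:
        sd_sec = np.pad(sd_sec, (0, n_s - sd_sec.size), mode="edge")
    if gains["acc"] > 1.0:
        sd_sec = sd_sec + 0.25 * a
    n_acc = int(n_s * fs_acc)
    sd_acc = np.repeat(sd_sec, int(fs_acc))[:n_acc]
    if sd_acc.size < n_acc:
        sd_acc = np.pad(sd_acc, (0, n_acc - sd_acc.size), mode="edge")
    wobble = _ar1(rng, n_s, 0.02, coef=0.99)
    wobble_acc = np.repeat(wobble, int(fs_acc))[:n_acc]
    acc_ts = np.arange(n_acc) / fs_acc
    acc = {}
    for axis, g0 in (("acc_x", 0.0), ("acc_y", 0.0), ("acc_z", 1.0)):
        acc[axis] = g0 + wobble_acc + rng.normal(0.0, 1.0, size=n_acc) * sd_acc

    stream = RawPhysioStream(
        participant_id=config.participant_id,
        channels={
            "acc_x": ChannelSeries(fs_acc, acc_ts, acc["acc_x"], "g"),
            "acc_y": ChannelSeries(fs_acc, acc_ts, acc["acc_y"], "g"),
            "acc_z": ChannelSeries(fs_acc, acc_ts, acc["acc_z"], "g"),
            "eda": ChannelSeries(fs_eda, eda_ts, eda_vals, "uS"),
            "temp": ChannelSeries(RATES["temp"], temp_ts, temp, "degC"),
            "pulse": ChannelSeries(RATES["pulse"], pulse_ts, pulse_vals, "bpm"),
        },
    )

    # ---- minute-level biomarkers ---------------------------------------
    biomarkers = []
    for m in range(n_min):
        t0, t1 = m * 60.0, (m + 1) * 60.0
        pm = stream.channels["pulse"].slice(t0, t1)
        am = a[m * 60:(m + 1) * 60].mean()
        acc_mag = np.sqrt(
            stream.channels["acc_x"].slice(t0, t1) ** 2
            + stream.channels["acc_y"].slice(t0, t1) ** 2
            + stream.channels["acc_z"].slice(t0, t1) ** 2
        )
        biomarkers.append(
            BiomarkerRecord(
                minute_start=t0,
                pulse_rate=float(np.clip(pm.mean(), 20, 250)) if pm.size else None,
                pulse_rate_variability=float(
                    np.clip(50.0 - 20.0 * am + rng.normal(0, 4), 5, 200)
                ),
                respiratory_rate=float(np.clip(14.0 + 6.0 * am + rng.normal(0, 1), 4, 60)),
                activity_counts=int(counts[m]),
                steps=int(max(0, round(counts[m] * 0.5 + rng.normal(0, 3)))),
                acc_magnitude_sd=float(acc_mag.std()),
                activity_class="moving" if counts[m] > 30 else "stationary",
                skin_conductance_level=float(tonic[m * 60:(m + 1) * 60].mean()),
                wearing=True,
                temperature=float(np.clip(temp[m * 60:(m + 1) * 60].mean(), 20, 45)),
            )
        )

    labels = []
    for onset, end in episodes:
        labels.append(EpisodeLabel(config.participant_id, onset - config.preagitation_lead_s,
                                   onset, "preagitation", "synthetic_truth"))
        labels.append(EpisodeLabel(config.participant_id, onset, end,
                                   "agitation", "synthetic_truth"))
    labels.sort(key=lambda e: e.start)
    return stream, biomarkers, labels


# ---------------------------------------------------------------------------
# Pose generator
# ---------------------------------------------------------------------------

#: 1-based keypoint layout; keypoint 1 is the neck/torso root.
KEYPOINT_NAMES = (
    "neck", "head",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_wrist", "r_wrist",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle",
)

# base pose, pixel offsets from the neck (x right, y down)
_BASE = np.array([
    (0, 0), (0, -20),
    (-15, 5), (15, 5), (-20, 30), (20, 30), (-22, 55), (22, 55),
    (-10, 60), (10, 60), (-12, 95), (12, 95), (-13, 130), (13, 130),
], dtype=float)

HIP_IDX = (8, 9)        # 0-based indices of l_hip / r_hip
ANKLE_IDX = (12, 13)
WRIST_IDX = (6, 7)
ELBOW_IDX = (4, 5)
UPPER_BODY_IDX = (0, 1, 2, 3, 4, 5, 6, 7)


@dataclass
class PoseFrame:
    """14 keypoints (x, y, confidence) for one person at one frame."""

    timestamp: float
    person_id: str
    keypoints: np.ndarray  # shape (14, 3)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.shape != (14, 3):
            raise ValueError(f"expected (14, 3) keypoints, got {self.keypoints.shape}")


def _rotate_about(points: np.ndarray, center: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    d = points - center
    return center + d @ np.array([[c, -s], [s, c]]).T


def _behavior_frame(behavior: str, t: float, rng: np.random.Generator,
                    state: dict) -> np.ndarray:
    """Return the (14, 2) keypoint layout for one frame, pre-noise."""
    pts = _BASE.copy()
    if behavior == "idle":
        pass
    elif behavior in ("walk", "pace"):
        speed = 30.0 if behavior == "walk" else 60.0
        phase = 2 * np.pi * 1.5 * t
        swing = 8.0 * np.sin(phase)
        pts[ANKLE_IDX[0], 0] += swing
        pts[ANKLE_IDX[1], 0] -= swing
        pts[10, 0] += 0.5 * swing
        pts[11, 0] -= 0.5 * swing
        pts[WRIST_IDX[0], 0] -= swing
        pts[WRIST_IDX[1], 0] += swing
        pts[:, 1] += 2.0 * np.abs(np.sin(phase))
        if behavior == "pace" and t >= state["next_flip"]:
            state["direction"] *= -1.0
            state["next_flip"] = t + rng.uniform(2.0, 4.0)
        state["root_x"] += state["direction"] * speed * state["dt"]
        if not (40.0 <= state["root_x"] <= 280.0):  # bounce off frame edges
            state["direction"] *= -1.0
            state["root_x"] = float(np.clip(state["root_x"], 40.0, 280.0))
    elif behavior == "rock":
        theta = 0.3 * np.sin(2 * np.pi * state["rock_hz"] * t)
        hip_mid = pts[list(HIP_IDX)].mean(axis=0)
        upper = _rotate_about(pts[list(UPPER_BODY_IDX)], hip_mid, theta)
        pts[list(UPPER_BODY_IDX)] = upper
    elif behavior == "kick":
        period = 1.5
        ph = (t % period) / period
        if ph < 0.3:  # half-sine excursion of the kicking foot
            k = ANKLE_IDX[state["kick_side"]]
            direction = pts[k] - pts[0]
            norm = np.linalg.norm(direction)
            target = pts[0] + direction / norm * (norm * 2.2)
            pts[k] = pts[k] + (target - pts[k]) * np.sin(np.pi * ph / 0.3)
        elif ph > 0.9:
            state["kick_side"] = int(rng.integers(0, 2))
    elif behavior == "flail":
        for side, (wi, ei, si) in enumerate(((6, 4, 2), (7, 5, 3))):
            phi = state["flail_phi"][side] + rng.normal(0.0, 1.2)
            state["flail_phi"][side] = phi
            pts[ei] = pts[si] + 28.0 * np.array([np.cos(phi), np.sin(phi)])
            pts[wi] = pts[ei] + 30.0 * np.array([np.cos(phi * 1.3), np.sin(phi * 1.3)])
    else:  # pragma: no cover - validated upstream
        raise ConfigError(f"unknown behavior {behavior!r}")
    pts[:, 0] += state["root_x"]
    pts[:, 1] += state["root_y"]
    return pts


def generate_pose(config: PoseSimConfig):
    """Generate a 14-keypoint articulated figure performing scheduled behaviors.

    Returns ``(list[PoseFrame], list[EpisodeLabel])``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    episodes = schedule_episodes(
        rng, config.duration_s, config.n_episodes,
        config.episode_duration_range_s, config.preagitation_lead_s,
        margin_s=30.0, snap_s=10.0,
    )
    n_frames = int(round(config.fps * config.duration_s))
    dt = 1.0 / config.fps

    # behavior schedule: per-second behavior name
    n_s = int(round(config.duration_s))
    beh = np.empty(n_s, dtype=object)
    t = 0
    while t < n_s:
        seg = int(rng.uniform(10, 20))
        beh[t:t + seg] = rng.choice(config.behaviors_normal)
        t += seg
    for onset, end in episodes:
        beh[int(onset):int(end)] = rng.choice(config.behaviors_agitated)

    state = {
        "root_x": 160.0, "root_y": 100.0, "direction": 1.0, "next_flip": 0.0,
        "rock_hz": rng.uniform(0.8, 1.5), "kick_side": 0,
        "flail_phi": [0.0, np.pi], "dt": dt,
    }
    frames: list[PoseFrame] = []
    for i in range(n_frames):
        ts = i * dt
        behavior = beh[min(int(ts), n_s - 1)]
        pts = _behavior_frame(behavior, ts, rng, state)
        if config.noise_sd_px > 0:
            pts = pts + rng.normal(0.0, config.noise_sd_px, size=(1, 2))
        conf = rng.uniform(0.5, 1.0, size=(14, 1))
        frames.append(PoseFrame(ts, config.participant_id, np.hstack([pts, conf])))

    labels = []
    for onset, end in episodes:
        labels.append(EpisodeLabel(config.participant_id, onset - config.preagitation_lead_s,
                                   onset, "preagitation", "synthetic_truth"))
        labels.append(EpisodeLabel(config.participant_id, onset, end,
                                   "agitation", "synthetic_truth"))
    labels.sort(key=lambda e: e.start)
    return frames, labels


def save_pose_jsonl(frames, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in frames:
            fh.write(json.dumps({
                "timestamp": round(f.timestamp, 9),
                "person_id": f.person_id,
                "keypoints": [[round(float(v), 9) for v in kp] for kp in f.keypoints],
            }) + "\n")


def load_pose_jsonl(path) -> list[PoseFrame]:
    frames = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            frames.append(PoseFrame(float(obj["timestamp"]), str(obj["person_id"]),
                                    np.asarray(obj["keypoints"], dtype=float)))
    return frames


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

_DOMINANT_ROTATION = ("eda", "acc", "temp")


@dataclass
class ParticipantBundle:
    participant_id: str
    physio_config: PhysioSimConfig
    stream: RawPhysioStream
    biomarkers: list[BiomarkerRecord]
    physio_labels: list[EpisodeLabel]
    pose_config: PoseSimConfig | None = None
    pose_frames: list[PoseFrame] | None = None
    pose_labels: list[EpisodeLabel] | None = None


def generate_cohort(
    n_participants: int,
    physio_template: PhysioSimConfig | None = None,
    pose_template: PoseSimConfig | None = None,
    seed: int = 0,
    include_pose: bool = False,
    duration_jitter: tuple[float, float] = (0.5, 1.5),
) -> list[ParticipantBundle]:
    """Generate a cohort with deterministic per-participant seeds and jitter.

    Session length scales by a uniform draw from ``duration_jitter`` (the
    wear-time range relative to the template), baseline pulse jitters by
    up to ±8 bpm, and the dominant agitated channel rotates eda→acc→temp.
    """
    if n_participants < 1:
        raise ConfigError("need at least one participant")
    physio_template = physio_template or PhysioSimConfig()
    bundles = []
    for i in range(n_participants):
        rng = np.random.default_rng([seed, i])
        pid = f"p{i + 1:02d}"
        scale = rng.uniform(*duration_jitter)
        dur = max(physio_template.duration_s, round(physio_template.duration_s * scale / 60) * 60)
        pconf = replace(
            physio_template,
            participant_id=pid,
            duration_s=float(dur),
            seed=int(rng.integers(0, 2**31 - 1)),
            dominant_channel=_DOMINANT_ROTATION[i % 3],
            baseline_pulse_offset=float(rng.uniform(-8.0, 8.0)),
        )
        stream, biomarkers, labels = generate_physio(pconf)
        bundle = ParticipantBundle(pid, pconf, stream, biomarkers, labels)
        if include_pose:
            sconf = replace(
                pose_template or PoseSimConfig(),
                participant_id=pid,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            bundle.pose_config = sconf
            bundle.pose_frames, bundle.pose_labels = generate_pose(sconf)
        bundles.append(bundle)
    return bundles


def write_bundle(bundles: list[ParticipantBundle], outdir, seed: int | None = None) -> None:
    """Write a cohort to one directory per participant plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "participants": []}
    for b in bundles:
        pdir = outdir / b.participant_id
        pdir.mkdir(exist_ok=True)
        save_physio_csv(b.stream, pdir / "physio.csv")
        save_labels(b.physio_labels, pdir / "labels.csv")
        bm = [
            {k: (v if v is not None else "") for k, v in asdict(r).items()}
            for r in b.biomarkers
        ]
        import pandas as pd
        pd.DataFrame(bm).to_csv(pdir / "biomarkers.csv", index=False, float_format="%.12g")
        entry = {
            "participant_id": b.participant_id,
            "physio_config": asdict(b.physio_config),
        }
        if b.pose_frames is not None:
            save_pose_jsonl(b.pose_frames, pdir / "pose.jsonl")
            save_labels(b.pose_labels, pdir / "pose_labels.csv")
            entry["pose_config"] = asdict(b.pose_config)
        manifest["participants"].append(entry)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
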