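"""Core domain types, file IO, and window labelling shared by both channels.

Timestamps are seconds-since-epoch floats and every interval is half-open
``[start, end)``.  Streams are stored per channel because the wristband
channels run at different sampling rates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

#: Channel names a raw wristband stream may carry (before preprocessing).
RAW_CHANNELS = ("acc_x", "acc_y", "acc_z", "eda", "temp", "pulse")

#: Valid episode classes.
EPISODE_LABELS = ("agitation", "preagitation", "normal")

#: Valid label provenance values.
LABEL_SOURCES = ("nurse_note", "camera", "manual", "synthetic_truth")

#: Physiological plausibility ranges used by loaders and preprocessing.
PHYSIO_RANGES = {
    "pulse": (20.0, 250.0),
    "respiratory_rate": (4.0, 60.0),
    "temp": (20.0, 45.0),
    "eda": (0.0, 100.0),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ChannelSeries:
    """One uniformly sampled channel: timestamps, values and nominal rate."""

    sampling_rate_hz: float
    timestamps: np.ndarray
    values: np.ndarray
    unit: str = ""
    #: half-open intervals flagged unusable by preprocessing (long gaps)
    unusable: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise DataError("timestamps and values must have identical shape")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0)) + 1
            raise DataError(f"non-monotonic timestamps at sample {bad}")
        if np.any(~np.isfinite(self.values)):
            raise DataError("channel values contain NaN/inf after loading")
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        if self.timestamps.size == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.sampling_rate_hz

    def slice(self, start: float, end: float) -> np.ndarray:
        """Values with timestamps in [start, end)."""
        i0, i1 = np.searchsorted(self.timestamps, [start, end], side="left")
        return self.values[i0:i1]

    def check_rate(self, tol: float = 0.01) -> None:
        """Nominal rate must match the median inter-sample gap within ``tol``."""
        if self.timestamps.size < 3:
            return
        gap = float(np.median(np.diff(self.timestamps)))
        if abs(1.0 / gap - self.sampling_rate_hz) > tol * self.sampling_rate_hz:
            raise DataError(
                f"sampling rate {self.sampling_rate_hz} Hz inconsistent with "
                f"median gap {gap:.6g} s"
            )


@dataclass
class RawPhysioStream:
    """Timestamped multichannel wristband series at per-channel rates."""

    participant_id: str
    channels: dict[str, ChannelSeries]

    def validate(self) -> "RawPhysioStream":
        for series in self.channels.values():
            series.check_rate()
        return self

    @property
    def t0(self) -> float:
        return min(float(s.timestamps[0]) for s in self.channels.values() if s.timestamps.size)

    @property
    def t1(self) -> float:
        return max(
            float(s.timestamps[-1]) + 1.0 / s.sampling_rate_hz
            for s in self.channels.values()
            if s.timestamps.size
        )

    @property
    def duration_s(self) -> float:
        return self.t1 - self.t0


@dataclass
class BiomarkerRecord:
    """One minute-level digital-biomarker row."""

    minute_start: float
    pulse_rate: float | None
    pulse_rate_variability: float | None
    respiratory_rate: float | None
    activity_counts: int
    steps: int
    acc_magnitude_sd: float | None
    activity_class: str  # stationary | moving
    skin_conductance_level: float | None
    wearing: bool
    temperature: float | None

    def __post_init__(self) -> None:
        if self.activity_class not in ("stationary", "moving"):
            raise DataError(f"bad activity_class {self.activity_class!r}")
        if not self.wearing:
            # off-wrist minutes carry no physiology
            for f in ("pulse_rate", "pulse_rate_variability", "respiratory_rate",
                      "acc_magnitude_sd", "skin_conductance_level", "temperature"):
                if getattr(self, f) is not None:
                    raise DataError("wearing=False requires missing physiology fields")
            return
        checks = [
            ("pulse_rate", PHYSIO_RANGES["pulse"]),
            ("respiratory_rate", PHYSIO_RANGES["respiratory_rate"]),
            ("temperature", PHYSIO_RANGES["temp"]),
        ]
        for name, (lo, hi) in checks:
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise DataError(f"{name}={v} outside physiological range [{lo}, {hi}]")
        if self.activity_counts < 0 or self.steps < 0:
            raise DataError("counts/steps must be non-negative")


@dataclass(frozen=True)
class EpisodeLabel:
    """A labelled interval with provenance."""

    participant_id: str
    start: float
    end: float
    label: str
    source: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"episode end {self.end} <= start {self.start}")
        if self.label not in EPISODE_LABELS:
            raise FormatError(f"unknown label {self.label!r}")
        if self.source not in LABEL_SOURCES:
            raise FormatError(f"unknown source {self.source!r}")

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass
class FeatureWindow:
    """A fixed-duration window with an ordered feature vector and a label."""

    window_start: float
    window_end: float
    features: dict[str, float]
    label: str | None = None  # 'agitation' | 'normal' | None (unlabeled)

    @property
    def duration_s(self) -> float:
        return self.window_end - self.window_start


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelSpec:
    """Declared unit and nominal sampling rate for one CSV channel column."""

    unit: str
    sampling_rate_hz: float


def load_physio_csv(path, schema: Mapping[str, ChannelSpec],
                    participant_id: str = "unknown") -> RawPhysioStream:
    """Read a wide-format CSV (``timestamp`` plus one column per channel).

    Channels sampled slower than the fastest one leave blank cells; blanks
    are simply absent samples for that channel.  Rows with unparseable
    values are dropped per channel and counted in the log.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if "timestamp" not in df.columns:
        raise FormatError(f"{path}: missing 'timestamp' column")
    ts_all = pd.to_numeric(df["timestamp"], errors="coerce")
    channels: dict[str, ChannelSeries] = {}
    for name, spec in schema.items():
        if name not in df.columns:
            raise FormatError(f"{path}: missing channel column {name!r}")
        vals = pd.to_numeric(df[name], errors="coerce")
        mask = vals.notna() & ts_all.notna()
        n_bad = int((~vals.isna() & ts_all.isna()).sum())
        if n_bad:
            logger.warning("%s: dropped %d unparseable rows in %s", path, n_bad, name)
        ts = ts_all[mask].to_numpy(dtype=float)
        if ts.size and np.any(np.diff(ts) <= 0):
            bad = int(np.argmax(np.diff(ts) <= 0)) + 1
            raise DataError(f"{path}: non-monotonic timestamps (channel {name}, row {bad})")
        channels[name] = ChannelSeries(
            sampling_rate_hz=spec.sampling_rate_hz,
            timestamps=ts,
            values=vals[mask].to_numpy(dtype=float),
            unit=spec.unit,
        )
    return RawPhysioStream(participant_id=participant_id, channels=channels).validate()


def save_physio_csv(stream: RawPhysioStream, path) -> None:
    """Write the wide-format CSV read back by :func:`load_physio_csv`."""
    frames = []
    for name, series in stream.channels.items():
        frames.append(pd.DataFrame({"timestamp": series.timestamps, name: series.values}))
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on="timestamp", how="outer")
    out = out.sort_values("timestamp")
    out.to_csv(path, index=False, float_format="%.12g")


def physio_schema(stream: RawPhysioStream) -> dict[str, ChannelSpec]:
    return {
        name: ChannelSpec(unit=s.unit, sampling_rate_hz=s.sampling_rate_hz)
        for name, s in stream.channels.items()
    }


def _check_overlaps(labels: Sequence[EpisodeLabel]) -> None:
    by_key: dict[tuple[str, str], list[EpisodeLabel]] = {}
    for lab in labels:
        by_key.setdefault((lab.participant_id, lab.label), []).append(lab)
    for (pid, name), group in by_key.items():
        group = sorted(group, key=lambda e: e.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise DataError(
                    f"overlapping {name!r} episodes for {pid}: "
                    f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
                )


def load_labels(path) -> list[EpisodeLabel]:
    """Read episode labels from CSV or JSON-lines, sorted by start."""
    path = str(path)
    rows: list[dict] = []
    if path.endswith((".jsonl", ".ndjson")):
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise FormatError(f"{path}: empty file") from exc
        required = {"participant_id", "start", "end", "label", "source"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        rows = df.to_dict("records")
    labels = [
        EpisodeLabel(
            participant_id=str(r["participant_id"]),
            start=float(r["start"]),
            end=float(r["end"]),
            label=str(r["label"]),
            source=str(r["source"]),
        )
        for r in rows
    ]
    labels.sort(key=lambda e: (e.start, e.participant_id))
    _check_overlaps(labels)
    return labels


def save_labels(labels: Iterable[EpisodeLabel], path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "start": e.start,
                "end": e.end,
                "label": e.label,
                "source": e.source,
            }
            for e in labels
        ]
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Window labelling
# ---------------------------------------------------------------------------

def interval_overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    """Length of the intersection of half-open intervals [a0,a1) and [b0,b1)."""
    return max(0.0, min(a1, b1) - max(a0, b0))


def label_windows(
    windows: Sequence[FeatureWindow],
    episodes: Sequence[EpisodeLabel],
    overlap_fraction: float = 0.5,
    preagitation: str = "exclude",
) -> list[FeatureWindow]:
    """Label windows against episode intervals by summed-overlap fraction.

    A window is positive iff its summed overlap with positive episodes is at
    least ``overlap_fraction`` of the window length.  ``preagitation`` is
    either ``"exclude"`` (pre-agitation-dominated windows are removed from
    the output — the default binary protocol) or ``"merge"`` (they count as
    agitation, the early-warning protocol).
    """
    if not 0.0 < overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in (0, 1]")
    if preagitation not in ("exclude", "merge"):
        raise ValueError(f"unknown preagitation mode {preagitation!r}")
    agit = [e for e in episodes if e.label == "agitation"]
    pre = [e for e in episodes if e.label == "preagitation"]
    out: list[FeatureWindow] = []
    for w in windows:
        need = overlap_fraction * w.duration_s
        agit_ov = sum(interval_overlap(w.window_start, w.window_end, e.start, e.end) for e in agit)
        pre_ov = sum(interval_overlap(w.window_start, w.window_end, e.start, e.end) for e in pre)
        if preagitation == "merge":
            agit_ov += pre_ov
            pre_ov = 0.0
        if agit_ov >= need:
            out.append(replace(w, label="agitation"))
        elif pre_ov >= need:
            continue  # held out of binary training
        else:
            out.append(replace(w, label="normal"))
    return out
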