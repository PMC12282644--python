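"""Episode assembly, context buffers, lead-time analysis, and the
alert/review/retrain loop.

Streaming per-window decisions become discrete detection events: a run of
at least ``min_consecutive`` positive windows opens an event, events closer
than ``merge_gap_s`` merge, and every event carries pre/post context
buffers (5 minutes by default) clipped to the stream bounds.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

from .data_model import EpisodeLabel, interval_overlap
from .errors import ContractError

logger = logging.getLogger(__name__)

_event_counter = itertools.count()


@dataclass
class WindowDecision:
    """One classified window in a decision stream."""

    start: float
    end: float
    probability: float
    positive: bool


@dataclass
class DetectionEvent:
    participant_id: str
    channel: str                      # wristband | video | fused
    onset: float
    offset: float
    decisions: list[WindowDecision] = field(default_factory=list)
    buffer_pre_s: float = 300.0
    buffer_post_s: float = 300.0
    buffered_start: float | None = None
    buffered_end: float | None = None
    clipped: bool = False
    review_status: str = "pending"    # pending | confirmed | rejected
    event_id: int = field(default_factory=lambda: next(_event_counter))

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ContractError("event offset precedes onset")

    @property
    def buffered(self) -> tuple[float, float]:
        if self.buffered_start is None:
            return (self.onset - self.buffer_pre_s, self.offset + self.buffer_post_s)
        return (self.buffered_start, self.buffered_end)

    @property
    def max_probability(self) -> float:
        return max((d.probability for d in self.decisions), default=float("nan"))


@dataclass
class LeadTimeRecord:
    participant_id: str
    truth_onset: float
    truth_end: float
    first_alert: float | None       # None = missed episode
    lead_s: float | None            # truth_onset - first_alert (positive = early)

    @property
    def missed(self) -> bool:
        return self.first_alert is None


def assemble_episodes(
    decisions: list[WindowDecision],
    min_consecutive: int = 2,
    merge_gap_s: float = 60.0,
    participant_id: str = "unknown",
    channel: str = "wristband",
) -> list[DetectionEvent]:
    """Turn a time-ordered decision stream into merged detection events."""
    for a, b in zip(decisions, decisions[1:]):
        if b.start < a.start:
            raise ContractError("decision stream is not time-ordered")
    runs: list[list[WindowDecision]] = []
    current: list[WindowDecision] = []
    for d in decisions:
        if d.positive:
            current.append(d)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    runs = [r for r in runs if len(r) >= min_consecutive]
    merged: list[list[WindowDecision]] = []
    for r in runs:
        if merged and r[0].start - merged[-1][-1].end <= merge_gap_s:
            merged[-1].extend(r)
        else:
            merged.append(list(r))
    return [
        DetectionEvent(
            participant_id=participant_id,
            channel=channel,
            onset=r[0].start,
            offset=r[-1].end,
            decisions=r,
        )
        for r in merged
    ]


def attach_buffers(event: DetectionEvent, stream_start: float, stream_end: float) -> DetectionEvent:
    """Clip the buffered interval to the stream bounds, recording clipping."""
    lo = event.onset - event.buffer_pre_s
    hi = event.offset + event.buffer_post_s
    event.buffered_start = max(lo, stream_start)
    event.buffered_end = min(hi, stream_end)
    event.clipped = event.buffered_start > lo or event.buffered_end < hi
    return event


def fuse_events(per_channel: list[list[DetectionEvent]], merge_gap_s: float = 0.0,
                participant_id: str = "unknown") -> list[DetectionEvent]:
    """Simple OR fusion: union of per-channel events, overlap-merged."""
    flat = sorted((e for evs in per_channel for e in evs), key=lambda e: e.onset)
    out: list[DetectionEvent] = []
    for e in flat:
        if out and e.onset - out[-1].offset <= merge_gap_s:
            out[-1].offset = max(out[-1].offset, e.offset)
            out[-1].decisions.extend(e.decisions)
        else:
            out.append(DetectionEvent(participant_id, "fused", e.onset, e.offset,
                                      list(e.decisions)))
    return out


def compute_lead_times(
    events: list[DetectionEvent],
    truth: list[EpisodeLabel],
    match_window_s: float = 900.0,
) -> list[LeadTimeRecord]:
    """Match each ground-truth agitation episode to the earliest event whose
    buffered interval intersects ``[onset - match_window_s, end)``."""
    records = []
    for ep in truth:
        if ep.label != "agitation":
            continue
        lo = ep.start - match_window_s
        candidates = [
            e for e in events
            if interval_overlap(e.buffered[0], e.buffered[1], lo, ep.end) > 0
        ]
        if not candidates:
            records.append(LeadTimeRecord(ep.participant_id, ep.start, ep.end, None, None))
            continue
        first = min(candidates, key=lambda e: e.onset)
        records.append(
            LeadTimeRecord(ep.participant_id, ep.start, ep.end, first.onset,
                           ep.start - first.onset)
        )
    return records


# ---------------------------------------------------------------------------
# Alerts and the review/retrain store
# ---------------------------------------------------------------------------

class AlertLog:
    """Append-only, idempotent-per-event alert record."""

    def __init__(self, path=None):
        self.records: list[dict] = []
        self._seen: set[int] = set()
        self.path = path

    def emit(self, event: DetectionEvent) -> dict | None:
        if event.event_id in self._seen:
            logger.warning("duplicate alert for event %d ignored", event.event_id)
            return None
        self._seen.add(event.event_id)
        prob = event.max_probability
        record = {
            "event_id": event.event_id,
            "timestamp": event.onset,
            "participant_id": event.participant_id,
            "channel": event.channel,
            "max_probability": None if prob != prob else prob,  # NaN -> null
        }
        self.records.append(record)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record) + "\n")
        return record

    def replay(self) -> list[dict]:
        """Reconstruct history from disk (or memory when no path is set)."""
        if self.path is None:
            return list(self.records)
        out = []
        with open(self.path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    out.append(json.loads(line))
        return out


class TrainingStore:
    """Versioned store of reviewed windows feeding the retraining loop."""

    def __init__(self):
        self.version = 0
        self.windows: list[tuple[WindowDecision, str]] = []
        self._reviewed: set[int] = set()

    def incorporate(self, event: DetectionEvent, decision: str) -> int:
        """Append the event's windows under the reviewed label.

        Confirmed events contribute agitation labels, rejected ones normal.
        Returns the new store version.  Retraining is a separate call.
        """
        if decision not in ("confirmed", "rejected"):
            raise ContractError(f"unknown review decision {decision!r}")
        if event.event_id in self._reviewed:
            raise ContractError(f"event {event.event_id} already reviewed")
        self._reviewed.add(event.event_id)
        event.review_status = decision
        label = "agitation" if decision == "confirmed" else "normal"
        for d in event.decisions:
            self.windows.append((d, label))
        self.version += 1
        return self.version
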