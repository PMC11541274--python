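"""Event sequences and event-based post-processing filters.

Sample-wise classification fragments easily under noise: a single
super-threshold sample splits one fixation into two.  The post-processing
stage removes physiologically implausible detections at the event level:

* a *micro-saccade filter* deletes gaps that are smaller than a minimum
  saccade amplitude ``a_thr`` OR shorter than a minimum saccade duration
  ``t_thr``, merging the flanking fixations;
* a *short-fixations filter* relabels fixations shorter than a minimum
  duration ``d_min`` as gaps.

Ground-truth annotation uses a stricter merge rule (amplitude < 2 deg AND
duration < 50 ms) to absorb micro-saccades into fixations; both rules are
implemented literally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signal import GazeRecording

__all__ = [
    "Event",
    "EventSequence",
    "samples_to_events",
    "microsaccade_filter",
    "short_fixation_filter",
    "postprocess",
    "merge_groundtruth_microsaccades",
    "event_amplitude",
]

log = logging.getLogger(__name__)

FIXATION = "fixation"
GAP = "gap"


@dataclass
class Event:
    """Half-open labeled interval [start_s, end_s) on the recording."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.start_s > self.end_s:
            raise ValueError("event must have start_s <= end_s")
        if self.label not in (FIXATION, GAP):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EventSequence:
    """Ordered, non-overlapping, alternating events covering a recording.

    A zero-extent trailing event (single-sample final run) is tolerated and
    dropped before metric computation.
    """

    events: list[Event] = field(default_factory=list)
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if b.start_s != a.end_s:
                raise ValueError(
                    f"events must tile the recording: gap/overlap between "
                    f"{a.end_s} and {b.start_s}")
            if b.label == a.label:
                raise ValueError("event labels must strictly alternate")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def fixations(self) -> list[Event]:
        return [e for e in self.events if e.label == FIXATION and
                e.duration_s > 0]

    def gaps(self) -> list[Event]:
        return [e for e in self.events if e.label == GAP and
                e.duration_s > 0]

    def total_time(self) -> float:
        return sum(e.duration_s for e in self.events)


def samples_to_events(labels) -> EventSequence:
    """Aggregate maximal runs of identical sample labels into events.

    Each event starts at the timestamp of its first sample and ends at the
    timestamp of the first sample of the next run; the last event ends at
    the final timestamp (and so has zero nominal extent if its run holds a
    single sample).
    """
    t = np.asarray(labels.t, dtype=float)
    lab = np.asarray(labels.label)
    if len(t) == 0:
        raise ValueError("empty label series")
    change = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    starts = np.concatenate([[0], change])
    events = []
    for k, s in enumerate(starts):
        end_t = t[starts[k + 1]] if k + 1 < len(starts) else t[-1]
        events.append(Event(float(t[s]), float(end_t), str(lab[s])))
    return EventSequence(events=events,
                         recording_id=getattr(labels, "recording_id", ""))


def event_amplitude(ev: Event, gaze: GazeRecording,
                    deg_per_px: float | None = None) -> float:
    """Angular distance (degrees) between gaze at event start and end."""
    if deg_per_px is None:
        deg_per_px = gaze.deg_per_px
    i = int(np.searchsorted(gaze.t, ev.start_s))
    j = int(np.searchsorted(gaze.t, ev.end_s))
    i = min(i, len(gaze) - 1)
    j = min(j, len(gaze) - 1)
    return float(np.hypot(gaze.x[j] - gaze.x[i],
                          gaze.y[j] - gaze.y[i]) * deg_per_px)


def _coalesce(events: list[Event]) -> list[Event]:
    """Merge adjacent events with identical labels."""
    out: list[Event] = []
    for e in events:
        if out and out[-1].label == e.label:
            out[-1] = Event(out[-1].start_s, e.end_s, e.label)
        else:
            out.append(Event(e.start_s, e.end_s, e.label))
    return out


def _merge_gaps(seq: EventSequence, gaze: GazeRecording,
                remove) -> EventSequence:
    """Remove interior gaps for which ``remove(gap)`` is true, merging the
    flanking fixations; single left-to-right pass."""
    events = list(seq.events)
    out: list[Event] = []
    for k, e in enumerate(events):
        interior = (e.label == GAP and out and out[-1].label == FIXATION
                    and k + 1 < len(events)
                    and events[k + 1].label == FIXATION)
        if e.label == GAP and not interior and remove(e):
            log.debug("edge gap at %.3f s retained: no flanking fixation",
                      e.start_s)
        if interior and remove(e):
            # deletion extends the left fixation up to the gap's end; the
            # following fixation then coalesces with it
            out[-1] = Event(out[-1].start_s, e.end_s, FIXATION)
        else:
            out.append(e)
    return EventSequence(events=_coalesce(out),
                         recording_id=seq.recording_id)


def microsaccade_filter(seq: EventSequence, gaze: GazeRecording,
                        a_thr: float, t_thr_ms: float,
                        mode: str = "or") -> EventSequence:
    """Delete small/brief interior gaps and merge their flanking fixations.

    A gap is removed when its amplitude is below ``a_thr`` (degrees) *or*
    its duration is below ``t_thr_ms`` (the detection-side rule);
    ``mode='and'`` requires both, mirroring the ground-truth merge rule.
    Amplitudes are computed from the gaze positions at the gap's first and
    last samples (pass the smoothed recording for consistency with the
    detectors).
    """
    if mode not in ("or", "and"):
        raise ValueError("mode must be 'or' or 'and'")
    t_thr_s = t_thr_ms / 1000.0

    def remove(gap: Event) -> bool:
        small = event_amplitude(gap, gaze) < a_thr
        brief = gap.duration_s < t_thr_s
        return (small or brief) if mode == "or" else (small and brief)

    return _merge_gaps(seq, gaze, remove)


def short_fixation_filter(seq: EventSequence, d_min_ms: float) -> EventSequence:
    """Relabel fixations shorter than ``d_min_ms`` as gaps."""
    d_min_s = d_min_ms / 1000.0
    out = [Event(e.start_s, e.end_s,
                 GAP if e.label == FIXATION and e.duration_s < d_min_s
                 else e.label)
           for e in seq.events]
    return EventSequence(events=_coalesce(out), recording_id=seq.recording_id)


def postprocess(seq: EventSequence, gaze: GazeRecording, a_thr: float,
                t_thr_ms: float, d_min_ms: float,
                mode: str = "or") -> EventSequence:
    """Micro-saccade filter followed by short-fixations filter, once each."""
    seq = microsaccade_filter(seq, gaze, a_thr, t_thr_ms, mode=mode)
    return short_fixation_filter(seq, d_min_ms)


def merge_groundtruth_microsaccades(seq: EventSequence, gaze: GazeRecording,
                                    amp_deg: float = 2.0,
                                    dur_ms: float = 50.0) -> EventSequence:
    """Annotation-side rule: merge fixations separated by gaps smaller than
    ``amp_deg`` *and* shorter than ``dur_ms`` (conjunction)."""
    dur_s = dur_ms / 1000.0

    def remove(gap: Event) -> bool:
        return (event_amplitude(gap, gaze) < amp_deg
                and gap.duration_s < dur_s)

    return _merge_gaps(seq, gaze, remove)
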