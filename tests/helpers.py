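"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from gazefix import GazeRecording
from gazefix.events import FIXATION, GAP, Event, EventSequence


def seq_from(spec, t0: float = 0.0, recording_id: str = "") -> EventSequence:
    """EventSequence from a list of (duration_s, label) pairs."""
    events = []
    t = t0
    for dur, lab in spec:
        events.append(Event(t, t + dur, lab))
        t += dur
    return EventSequence(events=events, recording_id=recording_id)


def seq_equal(a: EventSequence, b: EventSequence, tol: float = 0.0) -> bool:
    if len(a.events) != len(b.events):
        return False
    return all(abs(x.start_s - y.start_s) <= tol
               and abs(x.end_s - y.end_s) <= tol and x.label == y.label
               for x, y in zip(a.events, b.events))


def step_gaze(n: int = 400, rate_hz: float = 200.0, step_at: float | None = None,
              amp_px: float = 40.0) -> GazeRecording:
    """Piecewise-constant gaze: x jumps by amp_px at time step_at."""
    t = np.arange(n) / rate_hz
    if step_at is None:
        step_at = t[n // 2]
    x = np.where(t >= step_at, amp_px, 0.0)
    return GazeRecording(t=t, x=x, y=np.zeros(n))


def random_alternating(rng: np.random.Generator, span: float = 10.0,
                       max_events: int = 6) -> EventSequence:
    """Random alternating fixation/gap sequence covering [0, span]."""
    n_ev = int(rng.integers(1, max_events + 1))
    cuts = np.sort(rng.uniform(0.05, span - 0.05, size=n_ev - 1))
    bounds = np.concatenate([[0.0], cuts, [span]])
    first = FIXATION if rng.random() < 0.5 else GAP
    events = []
    for k in range(n_ev):
        lab = first if k % 2 == 0 else (GAP if first == FIXATION else FIXATION)
        events.append(Event(float(bounds[k]), float(bounds[k + 1]), lab))
    return EventSequence(events=events)


def random_recording(rng: np.random.Generator, n: int = 200,
                     rate_hz: float = 200.0, scale: float = 5.0
                     ) -> GazeRecording:
    t = np.arange(n) / rate_hz
    x = np.cumsum(rng.normal(0.0, scale, n))
    y = np.cumsum(rng.normal(0.0, scale, n))
    return GazeRecording(t=t, x=x, y=y)
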