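"""Agreement metrics for fixation detection.

Two levels of evaluation are provided:

* sample level -- Cohen's kappa, kappa = (p0 - pc) / (1 - pc), with p0 the
  raw agreement and pc the chance agreement of a random baseline with the
  marginal class probabilities;
* event level -- predicted and ground-truth fixations are matched one-to-one
  by temporal intersection-over-union (greedy, largest IoU first, minimum
  criterion 0.7), and precision / recall / F1 are computed over the matching.

Event-level F1 penalizes fragmentation and erroneous merging three-fold: a
fixation split into two sub-criterion pieces converts one true positive into
two false positives plus one false negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import Event, EventSequence, FIXATION, GAP
from .signal import GazeRecording, gaze_velocity, speed

__all__ = [
    "MatchResult",
    "cohens_kappa",
    "iou",
    "match_events",
    "event_f1",
    "timing_differences",
    "binned_event_metrics",
    "confusion_matrix_events",
    "descriptive_stats",
]

log = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """One-to-one IoU matching between ground-truth and predicted events."""

    pairs: list[tuple[Event, Event, float]]
    fn_events: list[Event]  # unmatched ground-truth events
    fp_events: list[Event]  # unmatched predicted events
    iou_min: float = 0.7

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_events)

    @property
    def fn(self) -> int:
        return len(self.fn_events)


def cohens_kappa(pred, gt) -> float:
    """Sample-level Cohen's kappa between two aligned label series."""
    p = np.asarray(pred.label)
    g = np.asarray(gt.label)
    if len(p) != len(g):
        raise ValueError("label series must have equal length")
    n = len(p)
    p0 = float(np.mean(p == g))
    classes = np.union1d(p, g)
    pc = float(sum(np.mean(p == c) * np.mean(g == c) for c in classes))
    if pc == 1.0:
        return 1.0 if p0 == 1.0 else 0.0
    return (p0 - pc) / (1.0 - pc)


def iou(a: Event, b: Event) -> float:
    """Temporal intersection-over-union of two events; 0 when disjoint."""
    inter = min(a.end_s, b.end_s) - max(a.start_s, b.start_s)
    if inter <= 0:
        return 0.0
    union = max(a.end_s, b.end_s) - min(a.start_s, b.start_s)
    return inter / union


def match_events(gt: EventSequence, pred: EventSequence,
                 label: str = FIXATION, iou_min: float = 0.7) -> MatchResult:
    """Greedy one-to-one matching of same-label events by descending IoU.

    Only pairs with IoU >= ``iou_min`` are eligible; ties are broken by
    earlier ground-truth onset, then earlier predicted onset.  Unmatched
    predictions become false positives, unmatched ground truths false
    negatives.  With ``iou_min=0`` any positive overlap is eligible.
    """
    gt_ev = [e for e in gt if e.label == label and e.duration_s > 0]
    pr_ev = [e for e in pred if e.label == label and e.duration_s > 0]
    cands = []
    for i, a in enumerate(gt_ev):
        for j, b in enumerate(pr_ev):
            s = iou(a, b)
            if s >= iou_min and s > 0:
                cands.append((-s, a.start_s, b.start_s, i, j))
    cands.sort()
    used_gt: set[int] = set()
    used_pr: set[int] = set()
    pairs = []
    for negs, _, _, i, j in cands:
        if i in used_gt or j in used_pr:
            continue
        used_gt.add(i)
        used_pr.add(j)
        pairs.append((gt_ev[i], pr_ev[j], -negs))
    fn = [e for i, e in enumerate(gt_ev) if i not in used_gt]
    fp = [e for j, e in enumerate(pr_ev) if j not in used_pr]
    return MatchResult(pairs=pairs, fn_events=fn, fp_events=fp,
                       iou_min=iou_min)


def event_f1(match: MatchResult) -> tuple[float, float, float]:
    """(f1, precision, recall) from a match result; 0 on empty denominators."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp == 0 and fp == 0 and fn == 0:
        log.warning("no events on either side; scores set to 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return f1, precision, recall


def timing_differences(match: MatchResult) -> dict:
    """Onset/offset differences (pred - gt) in ms over matched pairs.

    Positive values mean the prediction is late.  Returns mean/sd/min/max
    per boundary; empty stats (NaN) with a warning when nothing matched.
    """
    if not match.pairs:
        log.warning("timing_differences: no matched pairs")
        nan = dict(mean=np.nan, sd=np.nan, min=np.nan, max=np.nan, n=0)
        return {"onset": dict(nan), "offset": dict(nan)}
    on = np.array([(p.start_s - g.start_s) * 1000 for g, p, _ in match.pairs])
    off = np.array([(p.end_s - g.end_s) * 1000 for g, p, _ in match.pairs])
    def stats(d):
        return dict(mean=float(np.mean(d)), sd=float(np.std(d, ddof=0)),
                    min=float(np.min(d)), max=float(np.max(d)), n=len(d))
    return {"onset": stats(on), "offset": stats(off)}


def _max_flow_speed(ev: Event, flow) -> float:
    t = np.asarray(flow.t)
    m = (t >= ev.start_s) & (t <= ev.end_s)
    if not np.any(m):
        u = np.interp(0.5 * (ev.start_s + ev.end_s), t, flow.u)
        v = np.interp(0.5 * (ev.start_s + ev.end_s), t, flow.v)
        return float(np.hypot(u, v))
    return float(np.max(np.hypot(flow.u[m], flow.v[m])))


def _event_property(ev: Event, bin_by: str, gaze, flow) -> float:
    if bin_by == "saccade_amplitude":
        from .events import event_amplitude
        return event_amplitude(ev, gaze)
    if bin_by == "fixation_duration":
        return ev.duration_s * 1000.0
    if bin_by == "max_flow_speed":
        return _max_flow_speed(ev, flow)
    raise ValueError(f"unknown bin_by {bin_by!r}")


def binned_event_metrics(gt: EventSequence, pred: EventSequence,
                         bin_edges, bin_by: str = "max_flow_speed",
                         gaze: GazeRecording | None = None, flow=None,
                         iou_min: float = 0.7) -> list[dict]:
    """Per-bin event precision/recall/F1, binned by an event property.

    ``bin_by`` selects the property: gap amplitude (degrees, requires
    ``gaze``) for the saccade analysis -- conventionally run with
    ``iou_min=0`` -- fixation duration (ms), or maximum flow speed during
    the event (requires ``flow``).  Bins with no event on either side are
    reported with metrics set to None rather than zero.
    """
    label = GAP if bin_by == "saccade_amplitude" else FIXATION
    match = match_events(gt, pred, label=label, iou_min=iou_min)
    edges = np.asarray(bin_edges, dtype=float)

    def bin_of(ev):
        k = int(np.searchsorted(edges, _event_property(ev, bin_by, gaze, flow),
                                side="right")) - 1
        return k if 0 <= k < len(edges) - 1 else None

    rows = []
    for k in range(len(edges) - 1):
        tp_p = sum(1 for _, p, _ in match.pairs if bin_of(p) == k)
        tp_g = sum(1 for g, _, _ in match.pairs if bin_of(g) == k)
        fp = sum(1 for e in match.fp_events if bin_of(e) == k)
        fn = sum(1 for e in match.fn_events if bin_of(e) == k)
        row = {"bin_lo": float(edges[k]), "bin_hi": float(edges[k + 1]),
               "tp": tp_g, "fp": fp, "fn": fn}
        if tp_p + fp == 0 and tp_g + fn == 0:
            row.update(precision=None, recall=None, f1=None)
        else:
            row["precision"] = tp_p / (tp_p + fp) if tp_p + fp else 0.0
            row["recall"] = tp_g / (tp_g + fn) if tp_g + fn else 0.0
            denom = 2 * tp_g + fp + fn
            row["f1"] = 2 * tp_g / denom if denom else 0.0
        rows.append(row)
    return rows


def confusion_matrix_events(gt: EventSequence, pred: EventSequence,
                            iou_min: float = 0.7):
    """3x3 event confusion counts over {fixation, gap, None}.

    Matching is run separately per label; matched pairs land on the
    diagonal, unmatched ground-truth events in the None column, unmatched
    predictions in the None row.  Rows index ground truth, columns
    predictions.
    """
    labels = [FIXATION, GAP, "None"]
    mat = np.zeros((3, 3), dtype=int)
    for k, lab in enumerate((FIXATION, GAP)):
        m = match_events(gt, pred, label=lab, iou_min=iou_min)
        mat[k, k] = m.tp
        mat[k, 2] = m.fn
        mat[2, k] = m.fp
    return mat, labels


def descriptive_stats(seq: EventSequence, gaze: GazeRecording,
                      peak_smooth_ms: float = 25.0) -> dict:
    """Dataset-style descriptive statistics of an event sequence.

    Returns the fixation-time fraction, per-gap amplitudes (deg) and peak
    speeds (deg/s), and the log-log least-squares fit of peak speed against
    amplitude (the saccadic main sequence is a power law, peak = k * A^b).
    The fit is omitted (None) with fewer than two usable gaps.

    Peak speeds come from the forward-difference velocity after a short
    Savitzky--Golay smoothing (``peak_smooth_ms``, default 25 ms): long
    enough to suppress estimation noise, but shorter than the briefest
    physiological saccade so peaks are not attenuated.  Pass 0 to disable.
    """
    from .events import event_amplitude
    from .signal import smooth_gaze

    fix_t = sum(e.duration_s for e in seq.fixations())
    total = seq.total_time()
    frac = fix_t / total if total > 0 else 0.0

    work = smooth_gaze(gaze, 3, peak_smooth_ms) if peak_smooth_ms > 0 else gaze
    v = gaze_velocity(work)
    sp = speed(v) * gaze.deg_per_px
    amps, peaks = [], []
    for gap in seq.gaps():
        i = int(np.searchsorted(gaze.t, gap.start_s))
        j = int(np.searchsorted(gaze.t, gap.end_s))
        j = max(j, i + 1)
        a = event_amplitude(gap, gaze)
        pk = float(np.max(sp[i:j]))
        if a > 0 and pk > 0:
            amps.append(a)
            peaks.append(pk)
    out = {"fixation_time_fraction": frac,
           "gap_amplitudes_deg": np.asarray(amps),
           "gap_peak_speeds_dps": np.asarray(peaks),
           "main_sequence_slope": None,
           "main_sequence_intercept": None}
    if len(amps) >= 2:
        b, a0 = np.polyfit(np.log(amps), np.log(peaks), 1)
        out["main_sequence_slope"] = float(b)
        out["main_sequence_intercept"] = float(a0)
    return out
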