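"""Coherent (global) parameter tuning by grid search with cross-validation.

The detection threshold and the post-processing parameters are not
independent: a lower velocity threshold fragments the output more, which the
micro-saccade filter must then repair with larger ``a_thr``/``t_thr``.
All parameters are therefore tuned jointly, maximizing the mean
per-recording event-level fixation F1 over an exhaustive Cartesian grid,
with k-fold cross-validation over recordings (folds stratified to balance
static and dynamic conditions).

Expensive shared work (smoothing, differentiation, flow resampling, o_RMS)
is cached per recording across grid points, which makes full grids feasible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .detectors import DetectorParams, SampleLabels, classifier_input
from .events import FIXATION, GAP, postprocess, samples_to_events
from .metrics import cohens_kappa, event_f1, match_events
from .signal import smooth_gaze

__all__ = ["GridSpec", "FoldSpec", "Dataset", "grid_search", "make_folds",
           "cross_validate", "tuning_curve", "evaluate_params"]

log = logging.getLogger(__name__)

#: default grid ranges; reconstructions spanning the values visible in the
#: tuning analyses, overridable per call.
DEFAULT_GRID = {
    "threshold": [20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120],
    "gain": [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5],
    "window_ms": [55, 105, 205, 305],
    "a_thr": [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5],
    "t_thr_ms": [0, 25, 50, 75, 100, 125, 150],
    "d_min_ms": [0, 20, 40, 60, 80, 100, 120],
}

PARAM_ORDER = ("threshold", "gain", "window_ms", "a_thr", "t_thr_ms",
               "d_min_ms")


@dataclass
class GridSpec:
    """Ordered candidate values per tunable parameter."""

    threshold: list = field(default_factory=lambda: list(DEFAULT_GRID["threshold"]))
    gain: list = field(default_factory=lambda: [0.0])
    window_ms: list = field(default_factory=lambda: [205.0])
    a_thr: list = field(default_factory=lambda: list(DEFAULT_GRID["a_thr"]))
    t_thr_ms: list = field(default_factory=lambda: list(DEFAULT_GRID["t_thr_ms"]))
    d_min_ms: list = field(default_factory=lambda: list(DEFAULT_GRID["d_min_ms"]))

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            vals = sorted(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"grid for {name!r} must be nonempty")
            setattr(self, name, vals)

    def points(self):
        """Cartesian product, lexicographic in PARAM_ORDER."""
        axes = [getattr(self, name) for name in PARAM_ORDER]
        for combo in itertools.product(*axes):
            yield dict(zip(PARAM_ORDER, combo))


@dataclass
class FoldSpec:
    """Assignment of recordings to cross-validation folds (1..k)."""

    assignment: dict  # recording_id -> fold index
    k: int

    def held_out(self, fold: int) -> set:
        return {r for r, f in self.assignment.items() if f == fold}


@dataclass
class Dataset:
    """Recordings with flow and ground truth, keyed by recording_id."""

    items: list  # list of (GazeRecording, FlowSeries | None, EventSequence)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def subset(self, ids) -> "Dataset":
        return Dataset([it for it in self.items
                        if it[0].recording_id in ids])


class _RecordingCache:
    """Per-recording precomputation shared across grid points.

    Stores, keyed on (variant, compensation, o_RMS window), the per-sample
    signal the variant thresholds (in degrees) plus the o_RMS series, and
    the smoothed recording used for amplitude computations.
    """

    def __init__(self, rec, flow, gt, params: DetectorParams, variant: str):
        self.rec = rec
        self.gt = gt
        self.params = params
        self.variant = variant
        self.smoothed = smooth_gaze(rec, params.smooth_order,
                                    params.smooth_window_ms) \
            if params.smooth else rec
        self._signals: dict = {}
        self.flow = flow

    def signal(self, window_ms: float):
        key = float(window_ms)
        if key not in self._signals:
            p = replace(self.params, window_ms=window_ms)
            self._signals[key] = classifier_input(self.rec, self.flow, p,
                                                  self.variant)
        return self._signals[key]

    def labels(self, point: dict) -> SampleLabels:
        t, values, o_rms = self.signal(point["window_ms"])
        thr = point["threshold"]
        if o_rms is not None:
            thr = thr + point["gain"] * o_rms
        lab = np.where(values < thr, FIXATION, GAP)
        return SampleLabels(t=t, label=lab, detector_name=self.variant,
                            recording_id=self.rec.recording_id)

    def events(self, point: dict):
        seq = samples_to_events(self.labels(point))
        return postprocess(seq, self.smoothed, point["a_thr"],
                           point["t_thr_ms"], point["d_min_ms"],
                           mode=self.params.microsaccade_mode)


def _params_from_point(point: dict, base: DetectorParams) -> DetectorParams:
    return replace(base, threshold=point["threshold"], gain=point["gain"],
                   window_ms=point["window_ms"], a_thr=point["a_thr"],
                   t_thr_ms=point["t_thr_ms"], d_min_ms=point["d_min_ms"])


def evaluate_params(dataset: Dataset, params: DetectorParams, variant: str,
                    iou_min: float = 0.7) -> dict:
    """Mean per-recording fixation F1 (and kappa) of one parameter vector."""
    point = {name: getattr(params, name) for name in PARAM_ORDER}
    f1s, kappas, per_rec = [], [], {}
    for rec, flow, gt in dataset:
        cache = _RecordingCache(rec, flow, gt, params, variant)
        pred = cache.events(point)
        f1, prec, recall = event_f1(match_events(gt, pred, iou_min=iou_min))
        lab = cache.labels(point)
        gt_lab = _events_to_labels(gt, lab.t)
        kap = cohens_kappa(lab, gt_lab)
        f1s.append(f1)
        kappas.append(kap)
        per_rec[rec.recording_id] = dict(f1=f1, precision=prec,
                                         recall=recall, kappa=kap)
    return dict(f1=float(np.mean(f1s)) if f1s else 0.0,
                kappa=float(np.mean(kappas)) if kappas else 0.0,
                per_recording=per_rec)


def _events_to_labels(seq, t: np.ndarray) -> SampleLabels:
    """Sample-wise labels implied by an event sequence on timestamps t."""
    lab = np.full(len(t), GAP, dtype=object)
    for e in seq:
        if e.label == FIXATION:
            i = int(np.searchsorted(t, e.start_s, side="left"))
            j = int(np.searchsorted(t, e.end_s, side="left"))
            lab[i:j] = FIXATION
    # the final sample belongs to the last event
    if len(seq.events) and seq.events[-1].label == FIXATION:
        lab[-1] = FIXATION
    return SampleLabels(t=t, label=lab)


def grid_search(dataset: Dataset, grid: GridSpec, variant: str = "IVT",
                base_params: DetectorParams | None = None,
                iou_min: float = 0.7) -> tuple[DetectorParams, list[dict]]:
    """Exhaustive grid search maximizing mean per-recording fixation F1.

    Returns the argmax parameter vector (ties resolved to the
    lexicographically smallest point) and the full score table.  Recordings
    whose ground truth holds no fixation are skipped with a warning.
    """
    base = base_params or DetectorParams()
    usable = []
    for rec, flow, gt in dataset:
        if not gt.fixations():
            log.warning("recording %s has no ground-truth fixations; skipped",
                        rec.recording_id)
            continue
        usable.append(_RecordingCache(rec, flow, gt, base, variant))
    if not usable:
        raise ValueError("no usable recordings with ground truth")

    table = []
    best_score = -1.0
    best_point = None
    for point in grid.points():
        f1s = [event_f1(match_events(c.gt, c.events(point),
                                     iou_min=iou_min))[0]
               for c in usable]
        score = float(np.mean(f1s))
        table.append({**point, "f1": score})
        if score > best_score:  # first-seen wins ties: lexicographic order
            best_score = score
            best_point = point
    return _params_from_point(best_point, base), table


def make_folds(recordings, k: int = 5, seed: int = 0) -> FoldSpec:
    """Seeded random fold assignment stratified by recording condition.

    Recordings are shuffled within each condition and dealt round-robin, so
    every fold's static:dynamic ratio is within one recording of the global
    ratio.
    """
    recs = list(recordings)
    if k > len(recs):
        raise ValueError(f"cannot make {k} folds from {len(recs)} recordings")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    offset = 0
    for cond in sorted({r.condition for r in recs}):
        ids = sorted(r.recording_id for r in recs if r.condition == cond)
        rng.shuffle(ids)
        for i, rid in enumerate(ids):
            assignment[rid] = (i + offset) % k + 1
        offset += len(ids)
    return FoldSpec(assignment=assignment, k=k)


def cross_validate(dataset: Dataset, grid: GridSpec, variant: str,
                   folds: FoldSpec, base_params: DetectorParams | None = None,
                   iou_min: float = 0.7) -> dict:
    """k-fold cross-validation: tune on k-1 folds, score the held-out fold.

    Reports per-fold validation F1 (overall and per condition), kappa, the
    selected parameters per fold, and their mean/sd over folds (the per-fold
    parameter means correspond to an "average optimal parameter set").
    """
    base = base_params or DetectorParams()
    fold_rows = []
    for fold in range(1, folds.k + 1):
        held = folds.held_out(fold)
        if not held:
            raise ValueError(f"fold {fold} holds no recordings")
        train = dataset.subset(set(folds.assignment) - held)
        val = dataset.subset(held)
        params, _ = grid_search(train, grid, variant, base, iou_min)
        res = evaluate_params(val, params, variant, iou_min)
        row = {"fold": fold, "f1": res["f1"], "kappa": res["kappa"],
               "params": params}
        for cond in ("static", "dynamic"):
            sub = Dataset([it for it in val if it[0].condition == cond])
            row[f"f1_{cond}"] = (evaluate_params(sub, params, variant,
                                                 iou_min)["f1"]
                                 if len(sub) else None)
        fold_rows.append(row)
    f1s = np.array([r["f1"] for r in fold_rows])
    kappas = np.array([r["kappa"] for r in fold_rows])
    mean_params = {name: float(np.mean([getattr(r["params"], name)
                                        for r in fold_rows]))
                   for name in PARAM_ORDER}
    return {"folds": fold_rows,
            "f1_mean": float(f1s.mean()), "f1_sd": float(f1s.std(ddof=0)),
            "kappa_mean": float(kappas.mean()),
            "kappa_sd": float(kappas.std(ddof=0)),
            "mean_params": mean_params}


def tuning_curve(dataset: Dataset, variant: str, swept_param: str,
                 values, grid: GridSpec,
                 base_params: DetectorParams | None = None,
                 iou_min: float = 0.7) -> list[dict]:
    """Optimized F1 as a function of one pinned parameter.

    For each swept value the remaining parameters are re-optimized by grid
    search; returns (value, best F1, best co-parameters) triples.
    """
    if swept_param not in PARAM_ORDER:
        raise ValueError(f"unknown parameter {swept_param!r}")
    rows = []
    for value in values:
        g = replace(grid, **{swept_param: [float(value)]})
        params, table = grid_search(dataset, g, variant, base_params, iou_min)
        best = max(t["f1"] for t in table)
        rows.append({"value": float(value), "f1": best, "params": params})
    return rows
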