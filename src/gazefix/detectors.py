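"""Sample-wise fixation/gap classifiers: I-VT, I-DT, I-VAT, I-DAT.

The fixed-threshold detectors label a sample as part of a fixation when gaze
speed (I-VT) or windowed dispersion (I-DT) falls strictly below a threshold.
The adaptive variants (I-VAT, I-DAT) raise the threshold linearly with the
windowed RMS optic-flow magnitude o_RMS, a proxy for head-motion intensity:

    T(t) = T0 + g * o_RMS(t)

Each variant can additionally run on head-motion-compensated ("relative")
signals; with zero flow every compensated/adaptive variant reduces exactly to
its plain counterpart.

Thresholds in :class:`DetectorParams` are stored in degrees (per second) for
portability across cameras and converted to pixels internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import signal as sig
from .opticflow import FlowSeries, flow_intensity, resample_flow
from .events import FIXATION, GAP

__all__ = [
    "SampleLabels",
    "DetectorParams",
    "ivt_classify",
    "idt_classify",
    "adaptive_threshold",
    "detect",
    "VARIANTS",
]

VARIANTS = ("IVT", "IDT", "IVAT", "IDAT")


@dataclass
class SampleLabels:
    """Per-sample binary fixation/gap classification."""

    t: np.ndarray
    label: np.ndarray  # array of {"fixation", "gap"}
    detector_name: str = ""
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        if len(self.t) != len(self.label):
            raise ValueError("t and label must have equal length")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class DetectorParams:
    """Coherently tuned detector + post-processing parameter vector.

    ``threshold`` is v_thr for velocity variants (deg/s) or d_thr for
    dispersion variants (deg); for adaptive variants it is the baseline
    threshold T0.  Defaults are the mean optimal parameter set of the
    adaptive, compensated velocity detector: T0 = 42 deg/s, gain 0.70,
    o_RMS window 205 ms, a_thr = 1.7 deg, t_thr = 42 ms, d_min = 54 ms.
    """

    threshold: float = 42.0
    gain: float = 0.70
    window_ms: float = 205.0
    a_thr: float = 1.7
    t_thr_ms: float = 42.0
    d_min_ms: float = 54.0
    compensation: bool = True
    smooth: bool = True
    smooth_order: int = 3
    smooth_window_ms: float = 55.0
    dispersion_window_ms: float = 25.0
    microsaccade_mode: str = "or"

    def __post_init__(self) -> None:
        if self.threshold < 0 or self.gain < 0:
            raise ValueError("threshold and gain must be nonnegative")


def _check_finite(values: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite {name} values")


def ivt_classify(speed_values: np.ndarray, t: np.ndarray,
                 v_thr) -> SampleLabels:
    """Velocity thresholding: fixation iff speed < v_thr (strict).

    ``v_thr`` may be a scalar or a per-sample array (adaptive threshold).
    """
    speed_values = np.asarray(speed_values, dtype=float)
    _check_finite(speed_values, "speed")
    if np.any(np.asarray(v_thr) <= 0):
        raise ValueError("v_thr must be positive")
    lab = np.where(speed_values < v_thr, FIXATION, GAP)
    return SampleLabels(t=t, label=lab, detector_name="IVT")


def idt_classify(disp_values: np.ndarray, t: np.ndarray,
                 d_thr) -> SampleLabels:
    """Dispersion thresholding: fixation iff dispersion < d_thr (strict)."""
    disp_values = np.asarray(disp_values, dtype=float)
    _check_finite(disp_values, "dispersion")
    if np.any(np.asarray(d_thr) <= 0):
        raise ValueError("d_thr must be positive")
    lab = np.where(disp_values < d_thr, FIXATION, GAP)
    return SampleLabels(t=t, label=lab, detector_name="IDT")


def adaptive_threshold(intensity, T0: float, g: float) -> np.ndarray:
    """Linearly adaptive threshold T(t) = T0 + g * o_RMS(t)."""
    if T0 <= 0 or g < 0:
        raise ValueError("require T0 > 0 and g >= 0")
    return T0 + g * np.asarray(intensity.o_rms, dtype=float)


def classifier_input(rec: sig.GazeRecording, flow: FlowSeries | None,
                     params: DetectorParams, variant: str):
    """The per-sample signal a variant thresholds, in degrees(/s).

    Returns ``(t, values, o_rms_deg)`` where ``values`` is speed (deg/s) for
    velocity variants or dispersion (deg) for dispersion variants, computed
    on compensated signals when ``params.compensation`` and flow are given,
    and ``o_rms_deg`` is the flow-intensity series (None without flow).
    Shared by :func:`detect` and the optimizer's caching layer.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    adaptive = variant in ("IVAT", "IDAT")
    if (adaptive or params.compensation) and flow is not None:
        flow_g = resample_flow(flow, rec.t)
    else:
        flow_g = None
    if adaptive and flow_g is None:
        raise ValueError(f"{variant} requires a flow series")
    if params.compensation and flow_g is None:
        raise ValueError("head-motion compensation requires a flow series")

    work = sig.smooth_gaze(rec, params.smooth_order,
                           params.smooth_window_ms) if params.smooth else rec

    if variant in ("IVT", "IVAT"):
        v = sig.gaze_velocity(work)
        if params.compensation:
            v = sig.relative_velocity(v, flow_g)
        values = sig.speed(v) * rec.deg_per_px
    else:
        if params.compensation:
            d = sig.relative_dispersion(work, flow_g,
                                        params.dispersion_window_ms)
        else:
            d = sig.dispersion(work, params.dispersion_window_ms)
        values = d.d * rec.deg_per_px

    o_rms = None
    if adaptive:
        inten = flow_intensity(flow_g, params.window_ms, rate_hz=rec.rate_hz)
        o_rms = inten.o_rms * rec.deg_per_px
        if variant == "IDAT":
            # dispersion thresholds are lengths (deg), o_RMS is a speed
            # (deg/s): scale by the dispersion window to keep units coherent
            o_rms = o_rms * (params.dispersion_window_ms / 1000.0)
    return work.t, values, o_rms


def detect(rec: sig.GazeRecording, flow: FlowSeries | None,
           params: DetectorParams, variant: str = "IVAT") -> SampleLabels:
    """Run the full sample-wise pipeline for one detector variant.

    smoothing -> (relative) velocity or dispersion -> fixed or adaptive
    threshold.  Event aggregation and post-processing live in
    :mod:`gazefix.events` and are applied separately.
    """
    t, values, o_rms = classifier_input(rec, flow, params, variant)
    if o_rms is not None:
        thr = params.threshold + params.gain * o_rms
    else:
        thr = params.threshold
    if variant in ("IVT", "IVAT"):
        labels = ivt_classify(values, t, thr)
    else:
        labels = idt_classify(values, t, thr)
    suffix = "+rel" if params.compensation else ""
    labels.detector_name = variant + suffix
    labels.recording_id = rec.recording_id
    return labels
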