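"""Gaze-trace preprocessing: smoothing, differentiation, dispersion.

Head-mounted eye trackers report gaze in the pixel space of a forward-facing
scene camera.  This module turns a raw 2-D gaze trace into the signals that
threshold-based fixation detectors operate on: a Savitzky--Golay-smoothed
position trace, a forward-difference velocity series, a windowed dispersion
series, and -- when a global optic-flow estimate of head motion is available
-- their *relative* (head-motion-compensated) counterparts.

During vestibulo-ocular-reflex (VOR) gaze stabilization the eye counter-rotates
against the head, so the gaze point co-moves with the scene-camera image
content.  Subtracting the content velocity,

    v_rel = v_gaze - v_content,

yields a signal that is close to zero during functional fixations even under
vigorous head motion; analogously, dispersion of the flow-detrended trajectory
is close to zero.  These relative signals are what the compensated detector
variants threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import savgol_filter

__all__ = [
    "GazeRecording",
    "VelocitySeries",
    "DispersionSeries",
    "window_samples",
    "smooth_gaze",
    "gaze_velocity",
    "speed",
    "relative_velocity",
    "dispersion",
    "relative_dispersion",
    "convert_units",
]

#: degrees of visual angle per scene-camera pixel; fixed by the printed
#: correspondence 42 deg/s = 560 px/s for the reference scene camera.
DEFAULT_DEG_PER_PX = 0.075


@dataclass
class GazeRecording:
    """Timestamped 2-D gaze trace in scene-camera pixel coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    recording_id: str = ""
    condition: str = "unknown"  # {static, dynamic, unknown}
    rate_hz: float = 200.0
    deg_per_px: float = DEFAULT_DEG_PER_PX

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a gaze recording needs at least 2 samples")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x))
                and np.all(np.isfinite(self.y))):
            raise ValueError("t, x, y must be finite")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.condition not in ("static", "dynamic", "unknown"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class VelocitySeries:
    """Per-sample gaze velocity; ``kind='relative'`` means flow-compensated."""

    t: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    units: str = "px_per_s"  # {px_per_s, deg_per_s}
    kind: str = "raw"  # {raw, relative}

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.units not in ("px_per_s", "deg_per_s"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.kind not in ("raw", "relative"):
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass
class DispersionSeries:
    """Windowed gaze dispersion d = (max x - min x) + (max y - min y)."""

    t: np.ndarray
    d: np.ndarray
    window_ms: float = 25.0
    units: str = "px"  # {px, deg}
    kind: str = "raw"  # {raw, relative}

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("dispersion must be nonnegative")


def window_samples(window_ms: float, rate_hz: float, minimum: int = 1) -> int:
    """Window length in samples: round(window_ms * rate / 1000), forced odd.

    Centered windows need an odd sample count; window lengths are specified
    in milliseconds while the data come in samples.
    """
    n = int(round(window_ms * rate_hz / 1000.0))
    n = max(n, minimum)
    if n % 2 == 0:
        n += 1
    return n


def smooth_gaze(rec: GazeRecording, order: int = 3,
                window_ms: float = 55.0) -> GazeRecording:
    """Savitzky--Golay least-squares polynomial smoothing of x and y.

    Defaults: 3rd-order polynomial, 55 ms window.  Preserves polynomial
    traces up to the filter order exactly.
    """
    win = window_samples(window_ms, rec.rate_hz, minimum=order + 2)
    if win <= order:
        win = order + 2 + ((order + 2) % 2 == 0)
    if win > len(rec):
        raise ValueError(
            f"recording has {len(rec)} samples but the smoothing window "
            f"needs at least {win}")
    x = savgol_filter(rec.x, win, order, mode="interp")
    y = savgol_filter(rec.y, win, order, mode="interp")
    return replace(rec, x=x, y=y)


def gaze_velocity(rec: GazeRecording) -> VelocitySeries:
    """Forward-difference velocity of the position signal, px/s.

    The last sample replicates the preceding value so the series stays
    aligned sample-for-sample with the recording.
    """
    dt = np.diff(rec.t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps: zero inter-sample interval")
    vx = np.empty(len(rec))
    vy = np.empty(len(rec))
    vx[:-1] = np.diff(rec.x) / dt
    vy[:-1] = np.diff(rec.y) / dt
    vx[-1] = vx[-2]
    vy[-1] = vy[-2]
    return VelocitySeries(t=rec.t, vx=vx, vy=vy, units="px_per_s", kind="raw")


def speed(v: VelocitySeries) -> np.ndarray:
    """Gaze speed: Euclidean length of the velocity vector per sample."""
    return np.hypot(v.vx, v.vy)


def relative_velocity(v: VelocitySeries, flow) -> VelocitySeries:
    """Head-motion-compensated velocity v_rel = v_gaze - v_content.

    ``flow`` must already be resampled onto the gaze timestamps
    (see :func:`gazefix.opticflow.resample_flow`) and share the units of
    ``v``.
    """
    if getattr(flow, "units", "px_per_s") != v.units:
        raise ValueError(
            f"unit mismatch: velocity is {v.units}, flow is "
            f"{getattr(flow, 'units', 'px_per_s')}")
    if len(flow.t) != len(v.t):
        raise ValueError("flow must be resampled to the gaze timestamps")
    return VelocitySeries(t=v.t, vx=v.vx - flow.u, vy=v.vy - flow.v,
                          units=v.units, kind="relative")


def _minmax_dispersion(x: np.ndarray, y: np.ndarray, win: int) -> np.ndarray:
    # mode='nearest' replicates edge values, which for max/min equals
    # shrinking the window to the available samples.
    dx = (maximum_filter1d(x, win, mode="nearest")
          - minimum_filter1d(x, win, mode="nearest"))
    dy = (maximum_filter1d(y, win, mode="nearest")
          - minimum_filter1d(y, win, mode="nearest"))
    return dx + dy


def dispersion(rec: GazeRecording, window_ms: float = 25.0) -> DispersionSeries:
    """Windowed dispersion: (max x - min x) + (max y - min y), centered.

    The default 25 ms window matches the classical dispersion-threshold
    setup; at the recording edges the window shrinks to the available
    samples so every sample receives a value.
    """
    win = window_samples(window_ms, rec.rate_hz, minimum=2)
    d = _minmax_dispersion(rec.x, rec.y, win)
    return DispersionSeries(t=rec.t, d=d, window_ms=window_ms,
                            units="px", kind="raw")


def relative_dispersion(rec: GazeRecording, flow,
                        window_ms: float = 25.0) -> DispersionSeries:
    """Dispersion of the gaze trajectory relative to an ideally stabilized one.

    For each window center the ideal trajectory carries the center gaze point
    along the integrated global optic flow; the residual between actual and
    ideal trajectory is dispersed over the window.  Because dispersion is
    translation-invariant, this equals the raw dispersion of the
    flow-detrended trajectory q(t) = p(t) - integral(flow), which is how it is
    computed here (single cumulative trapezoidal integral, no per-center
    loop).
    """
    if len(flow.t) != len(rec.t):
        raise ValueError("flow must be resampled to the gaze timestamps")
    win = window_samples(window_ms, rec.rate_hz, minimum=2)
    fx = cumulative_trapezoid(flow.u, rec.t, initial=0.0)
    fy = cumulative_trapezoid(flow.v, rec.t, initial=0.0)
    d = _minmax_dispersion(rec.x - fx, rec.y - fy, win)
    return DispersionSeries(t=rec.t, d=d, window_ms=window_ms,
                            units="px", kind="relative")


def convert_units(series, deg_per_px: float):
    """Convert a pixel-based series to degrees of visual angle (isotropic).

    Accepts a :class:`VelocitySeries` or :class:`DispersionSeries`; returns a
    new series with magnitudes multiplied by ``deg_per_px`` and the units
    field updated.  Passing a degree-based series returns it unchanged.
    """
    if deg_per_px <= 0:
        raise ValueError("deg_per_px must be positive")
    if isinstance(series, VelocitySeries):
        if series.units == "deg_per_s":
            return series
        return replace(series, vx=series.vx * deg_per_px,
                       vy=series.vy * deg_per_px, units="deg_per_s")
    if isinstance(series, DispersionSeries):
        if series.units == "deg":
            return series
        return replace(series, d=series.d * deg_per_px, units="deg")
    raise TypeError(f"cannot convert {type(series).__name__}")
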