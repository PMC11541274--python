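"""Global optic-flow estimation and flow-derived head-motion intensity.

Global optic flow in the scene-camera image is a proxy for head motion: a
pure head rotation shifts the whole image coherently.  The estimator tracks
an 11x11 grid of points between consecutive frames with a pyramidal
Lucas--Kanade method and averages the successfully tracked displacements into
one global flow vector per frame pair.

Downstream consumers need the flow on the (faster) gaze time base, hence
:func:`resample_flow`, and the adaptive-threshold detectors need a windowed
RMS flow magnitude, hence :func:`flow_intensity`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .signal import window_samples

__all__ = [
    "FlowSeries",
    "FlowIntensity",
    "estimate_global_flow",
    "resample_flow",
    "flow_intensity",
    "track_points",
]

log = logging.getLogger(__name__)


@dataclass
class FlowSeries:
    """Per-frame (or per-sample) global optic-flow velocity."""

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    units: str = "px_per_s"  # {px_per_s, deg_per_s}
    source: str = "file"  # {video_lk, file, synthetic}
    grid_n: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.t) == len(self.u) == len(self.v)):
            raise ValueError("t, u, v must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("flow timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow components must be finite")

    def __len__(self) -> int:
        return len(self.t)

    def to_degrees(self, deg_per_px: float) -> "FlowSeries":
        if self.units == "deg_per_s":
            return self
        return replace(self, u=self.u * deg_per_px, v=self.v * deg_per_px,
                       units="deg_per_s")


@dataclass
class FlowIntensity:
    """Windowed RMS flow magnitude o_RMS, the head-motion-intensity proxy."""

    t: np.ndarray
    o_rms: np.ndarray
    window_ms: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.o_rms = np.asarray(self.o_rms, dtype=float)
        if np.any(self.o_rms < 0):
            raise ValueError("o_rms must be nonnegative")


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Image pyramid of cubic-spline coefficient arrays (for fast resampling)."""
    pyr = []
    cur = img
    for lev in range(levels):
        pyr.append(ndimage.spline_filter(cur, order=3, mode="mirror"))
        if lev < levels - 1:
            cur = ndimage.gaussian_filter(cur, 1.0, mode="nearest")[::2, ::2]
    return pyr


def _sample(coeffs: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(coeffs, [ys, xs], order=3,
                                   prefilter=False, mode="mirror")


def _integer_shift_init(img0: np.ndarray, img1: np.ndarray) -> np.ndarray:
    """Integer-pixel global translation by FFT cross-correlation.

    Serves as the coarse stage of the tracker: it brings the residual
    displacement below one pixel so the iterative Lucas--Kanade refinement
    starts inside its convergence basin even for large inter-frame shifts.
    """
    f0 = np.fft.fft2(img0 - img0.mean())
    f1 = np.fft.fft2(img1 - img1.mean())
    corr = np.fft.ifft2(f1 * np.conj(f0)).real
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    dy, dx = peak
    h, w = img0.shape
    if dy > h // 2:
        dy -= h
    if dx > w // 2:
        dx -= w
    return np.array([float(dx), float(dy)])


def track_points(img0: np.ndarray, img1: np.ndarray, pts: np.ndarray,
                 win: int = 21, levels: int = 2, iters: int = 30,
                 tol: float = 1e-4,
                 init: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pyramidal Lucas--Kanade tracking of sparse points.

    Parameters
    ----------
    img0, img1 : 2-D float arrays (grayscale frames).
    pts : (N, 2) array of (x, y) point coordinates in ``img0``.
    win : side length of the square tracking window, pixels.
    levels : number of pyramid levels (coarse-to-fine); levels that would
        make the window larger than the coarse image are skipped.
    iters, tol : per-level iteration cap and convergence tolerance (px).
    init : optional (2,) initial displacement guess applied to all points
        (e.g. from :func:`_integer_shift_init`).

    Returns
    -------
    displacements : (N, 2) array of (dx, dy) per point.
    status : (N,) bool array; False where tracking failed (point left the
        image, the window ran outside it, or the gradient matrix was
        degenerate).
    """
    img0 = np.asarray(img0, dtype=float)
    img1 = np.asarray(img1, dtype=float)
    pts = np.asarray(pts, dtype=float)
    h, w = img0.shape
    half = win // 2
    # drop pyramid levels whose coarse image cannot hold the window
    while levels > 1 and min(h, w) / 2 ** (levels - 1) < 2 * win:
        levels -= 1
    off = np.arange(-half, half + 1, dtype=float)
    oy, ox = np.meshgrid(off, off, indexing="ij")
    oy = oy.ravel()
    ox = ox.ravel()

    pyr0 = _pyramid(img0, levels)
    pyr1 = _pyramid(img1, levels)

    n = len(pts)
    disp = np.zeros((n, 2))
    status = np.ones(n, dtype=bool)

    for i in range(n):
        d = np.zeros(2) if init is None else np.asarray(init, dtype=float).copy()
        ok = True
        for lev in range(levels - 1, -1, -1):
            scale = 2.0 ** lev
            a, b = pyr0[lev], pyr1[lev]
            ys = pts[i, 1] / scale + oy
            xs = pts[i, 0] / scale + ox
            if (ys.min() < 0 or xs.min() < 0 or ys.max() > (h - 1) / scale
                    or xs.max() > (w - 1) / scale):
                ok = False
                break
            # spatial gradients of the template window (frame 0)
            gx = 0.5 * (_sample(a, ys, xs + 1) - _sample(a, ys, xs - 1))
            gy = 0.5 * (_sample(a, ys + 1, xs) - _sample(a, ys - 1, xs))
            t0 = _sample(a, ys, xs)
            g = np.array([[np.sum(gx * gx), np.sum(gx * gy)],
                          [np.sum(gx * gy), np.sum(gy * gy)]])
            if np.linalg.det(g) < 1e-6:
                ok = False
                break
            ginv = np.linalg.inv(g)
            for _ in range(iters):
                t1 = _sample(b, ys + d[1] / scale, xs + d[0] / scale)
                err = t0 - t1
                step = ginv @ np.array([np.sum(gx * err), np.sum(gy * err)])
                d += step * scale
                if np.hypot(*step) < tol:
                    break
        tx, ty = pts[i, 0] + d[0], pts[i, 1] + d[1]
        # the window around the tracked point must stay inside the frame,
        # otherwise the estimate leaned on extrapolated image content
        inside = (half + 1 <= tx <= w - 2 - half
                  and half + 1 <= ty <= h - 2 - half)
        if not ok or not inside:
            status[i] = False
        disp[i] = d
    return disp, status


def _grid_points(shape: tuple[int, int], grid_n: int,
                 inset: float = 0.05) -> np.ndarray:
    """Centers of a uniform grid_n x grid_n lattice, inset from the borders."""
    h, w = shape
    xs = np.linspace(inset * w, (1 - inset) * w, grid_n)
    ys = np.linspace(inset * h, (1 - inset) * h, grid_n)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def estimate_global_flow(video_frames, frame_times, grid_n: int = 11,
                         win: int = 21, levels: int = 3) -> FlowSeries:
    """Global optic flow from a frame sequence, px/s.

    For each consecutive frame pair, a ``grid_n`` x ``grid_n`` grid of points
    is tracked with pyramidal Lucas--Kanade; the global flow is the mean
    displacement of the successfully tracked points divided by the
    inter-frame interval.  The flow sample is stamped at the midtime of the
    frame pair.  A pair where every point fails yields (0, 0) with a logged
    warning.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    frames = [np.asarray(f, dtype=float) for f in video_frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to estimate flow")
    if len(frames) != len(frame_times):
        raise ValueError("one timestamp per frame required")
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")

    pts = _grid_points(frames[0].shape, grid_n)
    t_mid = 0.5 * (frame_times[1:] + frame_times[:-1])
    u = np.zeros(len(frames) - 1)
    v = np.zeros(len(frames) - 1)
    for k in range(len(frames) - 1):
        dt = frame_times[k + 1] - frame_times[k]
        init = _integer_shift_init(frames[k], frames[k + 1])
        disp, status = track_points(frames[k], frames[k + 1], pts,
                                    win=win, levels=levels, init=init)
        if not np.any(status):
            log.warning("frame pair %d: no points tracked; flow set to 0", k)
            continue
        mean_disp = disp[status].mean(axis=0)
        u[k] = mean_disp[0] / dt
        v[k] = mean_disp[1] / dt
    return FlowSeries(t=t_mid, u=u, v=v, source="video_lk", grid_n=grid_n)


def resample_flow(flow: FlowSeries, target_t: np.ndarray) -> FlowSeries:
    """Linear interpolation of the flow onto arbitrary timestamps.

    Outside the covered span the nearest endpoint value is held.
    """
    if len(flow) == 0:
        raise ValueError("cannot resample an empty flow series")
    target_t = np.asarray(target_t, dtype=float)
    u = np.interp(target_t, flow.t, flow.u)
    v = np.interp(target_t, flow.t, flow.v)
    return FlowSeries(t=target_t, u=u, v=v, units=flow.units,
                      source=flow.source, grid_n=flow.grid_n)


def _windowed_mean(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges."""
    n = len(x)
    half = win // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def flow_intensity(flow_on_gaze: FlowSeries, window_ms: float = 205.0,
                   rate_hz: float | None = None) -> FlowIntensity:
    """Windowed RMS flow magnitude o_RMS around each sample.

    o_rms = sqrt(RMS(u)^2 + RMS(v)^2) over a centered window; the default
    205 ms window is the mean optimal window length found for the adaptive
    detectors.  ``rate_hz`` defaults to the median sampling rate of the
    series.
    """
    t = flow_on_gaze.t
    if rate_hz is None:
        if len(t) > 1:
            rate_hz = 1.0 / float(np.median(np.diff(t)))
        else:
            rate_hz = 1.0
    win = window_samples(window_ms, rate_hz, minimum=1)
    mean_u2 = _windowed_mean(flow_on_gaze.u ** 2, win)
    mean_v2 = _windowed_mean(flow_on_gaze.v ** 2, win)
    return FlowIntensity(t=t, o_rms=np.sqrt(mean_u2 + mean_v2),
                         window_ms=window_ms)
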