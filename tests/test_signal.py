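"""Unit tests for gaze-signal preprocessing (smoothing, velocity, dispersion)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazefix.signal import (DispersionSeries, GazeRecording, VelocitySeries,
                            convert_units, dispersion, gaze_velocity,
                            relative_dispersion, relative_velocity,
                            smooth_gaze, speed, window_samples)
from gazefix.opticflow import FlowSeries

from helpers import random_recording


# ---------------------------------------------------------------- recording

def test_recording_validation():
    t = np.arange(4) / 200.0
    with pytest.raises(ValueError):
        GazeRecording(t=t, x=np.zeros(3), y=np.zeros(4))
    with pytest.raises(ValueError):
        GazeRecording(t=[0.0], x=[0.0], y=[0.0])
    with pytest.raises(ValueError):
        GazeRecording(t=[0.0, 0.0, 0.01], x=np.zeros(3), y=np.zeros(3))
    with pytest.raises(ValueError):
        GazeRecording(t=t, x=[0, np.nan, 0, 0], y=np.zeros(4))
    with pytest.raises(ValueError):
        GazeRecording(t=t, x=np.zeros(4), y=np.zeros(4), condition="walking")
    with pytest.raises(ValueError):
        GazeRecording(t=t, x=np.zeros(4), y=np.zeros(4), deg_per_px=0.0)


# ----------------------------------------------------------- window_samples

def test_window_samples():
    assert window_samples(25.0, 200.0) == 5
    assert window_samples(55.0, 200.0) == 11
    assert window_samples(205.0, 200.0) == 41
    assert window_samples(20.0, 100.0) == 3      # rounds to even 2 -> odd 3
    assert window_samples(1.0, 100.0, minimum=1) == 1
    assert window_samples(1.0, 100.0, minimum=4) == 5  # minimum forced odd


# ---------------------------------------------------------------- smoothing

def test_smooth_preserves_cubic():
    t = np.arange(300) / 200.0
    x = 3.0 - 2.0 * t + 5.0 * t**2 - 4.0 * t**3
    y = 1.0 + t - t**3
    rec = GazeRecording(t=t, x=x, y=y)
    sm = smooth_gaze(rec, order=3, window_ms=55.0)
    np.testing.assert_allclose(sm.x, x, atol=1e-8)
    np.testing.assert_allclose(sm.y, y, atol=1e-8)


def _savgol_oracle(x: np.ndarray, win: int, order: int) -> np.ndarray:
    """Per-window least-squares polynomial fit evaluated at the sample.

    Interior samples: centered window.  Edge samples: the polynomial fitted
    to the first/last full window, evaluated at the sample's offset.
    """
    n = len(x)
    h = win // 2
    out = np.empty(n)
    for i in range(n):
        if i < h:
            idx0, pos = 0, i
        elif i >= n - h:
            idx0, pos = n - win, i - (n - win)
        else:
            idx0, pos = i - h, h
        seg = x[idx0:idx0 + win]
        coef = np.polyfit(np.arange(win), seg, order)
        out[i] = np.polyval(coef, pos)
    return out


def test_smooth_step_trace_matches_regression_oracle():
    # a 200 Hz step trace 0 -> 10 px
    t = np.arange(120) / 200.0
    x = np.where(t >= 0.3, 10.0, 0.0)
    rec = GazeRecording(t=t, x=x, y=x.copy())
    sm = smooth_gaze(rec, order=3, window_ms=55.0)
    oracle = _savgol_oracle(x, win=11, order=3)
    np.testing.assert_allclose(sm.x, oracle, atol=1e-9)
    np.testing.assert_allclose(sm.y, oracle, atol=1e-9)


def test_smooth_random_traces_match_regression_oracle():
    rng = np.random.default_rng(42)
    for _ in range(5):
        rec = random_recording(rng, n=80)
        sm = smooth_gaze(rec, order=3, window_ms=55.0)
        np.testing.assert_allclose(sm.x, _savgol_oracle(rec.x, 11, 3),
                                   atol=1e-8)


def test_smooth_too_short_recording_raises():
    t = np.arange(5) / 200.0
    rec = GazeRecording(t=t, x=np.zeros(5), y=np.zeros(5))
    with pytest.raises(ValueError, match="window"):
        smooth_gaze(rec, order=3, window_ms=55.0)


# ----------------------------------------------------------------- velocity

def test_velocity_trivial():
    rec = GazeRecording(t=[0.0, 0.1, 0.2], x=[0.0, 1.0, 3.0],
                        y=[0.0, 0.0, 1.0])
    v = gaze_velocity(rec)
    np.testing.assert_allclose(v.vx, [10.0, 20.0, 20.0])
    np.testing.assert_allclose(v.vy, [0.0, 10.0, 10.0])
    assert v.kind == "raw"


def test_velocity_loop_oracle_random():
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = 50
        t = np.cumsum(rng.uniform(0.004, 0.006, n))
        rec = GazeRecording(t=t, x=rng.normal(0, 10, n),
                            y=rng.normal(0, 10, n))
        v = gaze_velocity(rec)
        for i in range(n - 1):
            assert v.vx[i] == (rec.x[i + 1] - rec.x[i]) / (t[i + 1] - t[i])
            assert v.vy[i] == (rec.y[i + 1] - rec.y[i]) / (t[i + 1] - t[i])
        assert v.vx[-1] == v.vx[-2] and v.vy[-1] == v.vy[-2]


def test_speed_trivial():
    v = VelocitySeries(t=[0.0], vx=[3.0], vy=[4.0])
    assert speed(v)[0] == 5.0
    v = VelocitySeries(t=[0.0], vx=[-200.0], vy=[0.0])
    assert speed(v)[0] == 200.0


@settings(derandomize=True, max_examples=40)
@given(st.floats(-10, 10), st.floats(-500, 500), st.floats(-500, 500))
def test_speed_rotation_invariant(theta, vx, vy):
    c, s = np.cos(theta), np.sin(theta)
    v1 = VelocitySeries(t=[0.0], vx=[vx], vy=[vy])
    v2 = VelocitySeries(t=[0.0], vx=[c * vx - s * vy], vy=[s * vx + c * vy])
    assert speed(v1)[0] == pytest.approx(speed(v2)[0], abs=1e-9, rel=1e-12)


def test_relative_velocity_subtracts_flow():
    v = VelocitySeries(t=[0.0, 0.005], vx=[100.0, 50.0], vy=[0.0, -20.0])
    flow = FlowSeries(t=[0.0, 0.005], u=[100.0, 40.0], v=[0.0, -20.0])
    rel = relative_velocity(v, flow)
    np.testing.assert_allclose(rel.vx, [0.0, 10.0])
    np.testing.assert_allclose(rel.vy, [0.0, 0.0])
    assert rel.kind == "relative"


def test_relative_velocity_unit_and_length_checks():
    v = VelocitySeries(t=[0.0, 0.005], vx=[1.0, 1.0], vy=[0.0, 0.0])
    flow_deg = FlowSeries(t=[0.0, 0.005], u=[1.0, 1.0], v=[0.0, 0.0],
                          units="deg_per_s")
    with pytest.raises(ValueError, match="unit"):
        relative_velocity(v, flow_deg)
    short = FlowSeries(t=[0.0], u=[1.0], v=[0.0])
    with pytest.raises(ValueError, match="resampled"):
        relative_velocity(v, short)


# --------------------------------------------------------------- dispersion

def _dispersion_oracle(x, y, win):
    n = len(x)
    h = win // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = ((x[lo:hi].max() - x[lo:hi].min())
                  + (y[lo:hi].max() - y[lo:hi].min()))
    return out


def test_dispersion_loop_oracle_random():
    rng = np.random.default_rng(3)
    for _ in range(10):
        rec = random_recording(rng, n=30)
        d = dispersion(rec, window_ms=25.0)
        np.testing.assert_array_equal(
            d.d, _dispersion_oracle(rec.x, rec.y, 5))


def test_dispersion_constant_trace_is_zero():
    t = np.arange(20) / 200.0
    rec = GazeRecording(t=t, x=np.full(20, 7.0), y=np.full(20, -3.0))
    assert np.all(dispersion(rec).d == 0.0)


def test_dispersion_translation_invariant():
    rng = np.random.default_rng(5)
    rec = random_recording(rng, n=60)
    shifted = GazeRecording(t=rec.t, x=rec.x + 123.0, y=rec.y - 77.0)
    np.testing.assert_allclose(dispersion(rec).d, dispersion(shifted).d,
                               atol=1e-9)


def test_relative_dispersion_zero_flow_equals_raw():
    rng = np.random.default_rng(6)
    rec = random_recording(rng, n=60)
    zero = FlowSeries(t=rec.t, u=np.zeros(len(rec)), v=np.zeros(len(rec)))
    np.testing.assert_array_equal(relative_dispersion(rec, zero).d,
                                  dispersion(rec).d)


def test_relative_dispersion_comoving_gaze_is_zero():
    # piecewise-constant flow, gaze riding exactly on the integrated flow
    from scipy.integrate import cumulative_trapezoid
    t = np.arange(100) / 200.0
    u = np.where(t < 0.25, 400.0, -200.0)
    v = np.where(t < 0.25, 0.0, 300.0)
    x = 500.0 + cumulative_trapezoid(u, t, initial=0.0)
    y = 500.0 + cumulative_trapezoid(v, t, initial=0.0)
    rec = GazeRecording(t=t, x=x, y=y)
    flow = FlowSeries(t=t, u=u, v=v)
    d = relative_dispersion(rec, flow)
    np.testing.assert_allclose(d.d, 0.0, atol=1e-9)
    assert d.kind == "relative"


def _relative_dispersion_oracle(rec, flow, win):
    """Literal per-center construction: carry the center gaze point along the
    integrated flow and disperse the residual over the window."""
    from scipy.integrate import cumulative_trapezoid
    n = len(rec)
    h = win // 2
    fx = cumulative_trapezoid(flow.u, rec.t, initial=0.0)
    fy = cumulative_trapezoid(flow.v, rec.t, initial=0.0)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        # ideal trajectory: gaze at center i carried along the flow
        ix = rec.x[i] + (fx[lo:hi] - fx[i])
        iy = rec.y[i] + (fy[lo:hi] - fy[i])
        rx = rec.x[lo:hi] - ix
        ry = rec.y[lo:hi] - iy
        out[i] = rx.max() - rx.min() + ry.max() - ry.min()
    return out


def test_relative_dispersion_matches_per_center_oracle():
    rng = np.random.default_rng(8)
    for _ in range(5):
        rec = random_recording(rng, n=60)
        flow = FlowSeries(t=rec.t, u=rng.normal(0, 200, 60),
                          v=rng.normal(0, 200, 60))
        d = relative_dispersion(rec, flow, window_ms=25.0)
        np.testing.assert_allclose(
            d.d, _relative_dispersion_oracle(rec, flow, 5), atol=1e-9)


def test_relative_dispersion_length_check():
    rng = np.random.default_rng(9)
    rec = random_recording(rng, n=20)
    flow = FlowSeries(t=rec.t[:10], u=np.zeros(10), v=np.zeros(10))
    with pytest.raises(ValueError, match="resampled"):
        relative_dispersion(rec, flow)


# ------------------------------------------------------------ unit handling

def test_convert_units_velocity():
    # 560 px/s corresponds to 42 deg/s at 0.075 deg/px
    v = VelocitySeries(t=[0.0], vx=[560.0], vy=[0.0])
    vd = convert_units(v, 0.075)
    assert vd.vx[0] == pytest.approx(42.0)
    assert vd.units == "deg_per_s"
    assert convert_units(vd, 0.075) is vd  # already degrees: unchanged


def test_convert_units_dispersion_and_errors():
    d = DispersionSeries(t=[0.0], d=[40.0])
    dd = convert_units(d, 0.075)
    assert dd.d[0] == pytest.approx(3.0)
    assert dd.units == "deg"
    with pytest.raises(ValueError):
        convert_units(d, 0.0)
    with pytest.raises(TypeError):
        convert_units(np.zeros(3), 0.075)
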