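"""Ussing-chamber ΔIsc and YFP-quenching rate computations.

Short-circuit current (Isc) traces are sampled every ~10 s while chemicals
are added; the response to an addition is the difference between the mean of
the 5 samples after and the 5 samples before the addition (the sample at the
addition instant itself is excluded), divided by the mounted membrane area so
results are in µA/cm².

Halide-sensitive YFP traces report anion influx: after iodide injection the
fluorescence decays, each trace is normalized to its own initial (injection
time) fluorescence, a linear slope is fitted in every sliding window of
``window`` samples over the post-injection span, and the quenching rate (QR)
is the magnitude of the steepest (most negative) slope, in fraction of
initial fluorescence per second. QRs are usually reported relative to the
mean QR of control wells.
"""

from __future__ import annotations

import numpy as np

from .errors import TraceError


def delta_isc(
    times: np.ndarray,
    current: np.ndarray,
    event_time: float,
    membrane_area: float = 1.0,
    n_points: int = 5,
    gap: int = 0,
) -> float:
    """Current step across a chemical addition, in µA/cm².

    ``mean(n_points after) - mean(n_points before)``, both windows adjacent
    to the event (after skipping ``gap`` samples on each side), divided by
    ``membrane_area``. The sample exactly at ``event_time`` belongs to
    neither window.
    """
    times = np.asarray(times, float)
    current = np.asarray(current, float)
    if membrane_area <= 0:
        raise TraceError(f"membrane_area must be > 0, got {membrane_area}")
    if not times[0] < event_time < times[-1]:
        raise TraceError(
            f"event at t={event_time}s outside trace [{times[0]}, {times[-1]}]"
        )
    before = current[times < event_time]
    after = current[times > event_time]
    if len(before) < gap + n_points:
        raise TraceError(
            f"only {len(before)} samples before event, need {gap + n_points}"
        )
    if len(after) < gap + n_points:
        raise TraceError(
            f"only {len(after)} samples after event, need {gap + n_points}"
        )
    pre = before[len(before) - gap - n_points: len(before) - gap]
    post = after[gap: gap + n_points]
    return float((post.mean() - pre.mean()) / membrane_area)


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope in every contiguous window of ``window`` samples."""
    n = len(t)
    slopes = np.empty(n - window + 1)
    for i in range(n - window + 1):
        ti = t[i:i + window]
        yi = y[i:i + window]
        tc = ti - ti.mean()
        slopes[i] = tc @ (yi - yi.mean()) / (tc @ tc)
    return slopes


def quench_rate(
    times: np.ndarray,
    fluorescence: np.ndarray,
    injection_time: float,
    window: int = 5,
    background: float | None = None,
) -> float:
    """Steepest decay slope of the normalized post-injection trace (≥ 0).

    Background (if given) is subtracted first; the trace is restricted to
    ``t >= injection_time`` and divided by its value at the first
    post-injection sample, so the normalized trace starts at 1. Slopes are
    fitted in every sliding ``window``-sample span and the QR is the
    magnitude of the most negative one; a trace that never decays scores 0.
    """
    times = np.asarray(times, float)
    y = np.asarray(fluorescence, float)
    if window < 2:
        raise TraceError(f"window must be >= 2 samples, got {window}")
    if background is not None:
        y = y - background
    mask = times >= injection_time
    t_post = times[mask]
    y_post = y[mask]
    if len(t_post) < window:
        raise TraceError(
            f"{len(t_post)} post-injection samples, need >= window ({window})"
        )
    if y_post[0] <= 0:
        raise TraceError(
            f"initial (post-injection) fluorescence must be > 0, got {y_post[0]}"
        )
    norm = y_post / y_post[0]
    slopes = _window_slopes(t_post, norm, window)
    return float(max(0.0, -slopes.min()))


def normalize_to_control(
    qrs: np.ndarray, control_qrs: np.ndarray
) -> np.ndarray:
    """Each QR divided by the mean control QR."""
    control_qrs = np.asarray(control_qrs, float)
    if control_qrs.size == 0:
        raise TraceError("need at least one control QR")
    mean_control = control_qrs.mean()
    if mean_control == 0:
        raise TraceError("mean control QR is zero, cannot normalize")
    return np.asarray(qrs, float) / mean_control
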