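"""Transient kinetics estimators.

Half-rise/half-decay times are read off sampled ΔF/F0 traces by linear
interpolation between the bracketing frames, matching how indicator
kinetics are routinely reported. A single-exponential fit and a
stimulus-tracking Fourier amplitude (spectrum normalized to its 0 Hz
magnitude) complete the set.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .traceproc import Trace


class HalfTime(NamedTuple):
    """Interpolated half time in seconds; ``censored`` if no crossing."""

    time_s: float
    censored: bool


class ExpFit(NamedTuple):
    amplitude: float
    tau_s: float
    goodness: float  # RMS residual / fitted amplitude
    ok: bool


class TrackingResult(NamedTuple):
    freqs: np.ndarray
    spectrum: np.ndarray  # |DFT| / |DFT at 0 Hz|
    amplitude: float  # spectrum value at the bin nearest f_stim
    defined: bool


def decay_eligibility(
    trace: Trace,
    baseline_window: tuple[float, float],
    stimulus_window: tuple[float, float],
    n_sd: float = 4.0,
    last_s: float = 1.0,
) -> bool:
    """Peak-amplitude gate for decay analysis.

    True iff the maximum during the last ``last_s`` seconds of the
    stimulus exceeds ``n_sd`` times the baseline standard deviation.
    A zero-variance baseline with a nonzero peak counts as eligible.
    """
    base = trace.samples[trace.window_slice(*baseline_window)]
    if base.size == 0:
        raise ValueError("empty baseline window")
    tail = trace.samples[trace.window_slice(stimulus_window[1] - last_s, stimulus_window[1])]
    if tail.size == 0:
        raise ValueError("empty stimulus tail window")
    sd = float(base.std())
    peak = float(tail.max() - base.mean())
    if sd == 0.0:
        return peak > 0.0
    return peak > n_sd * sd


def _cross_time(times, values, target, rising):
    """First linear-interpolated crossing of ``target`` in sample order."""
    v = values - target
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        hit = (a >= 0 > b) if not rising else (a <= 0 < b)
        if hit:
            frac = a / (a - b)
            return times[i] + frac * (times[i + 1] - times[i])
    return None


def half_decay_time(
    trace: Trace, peak_time: float | None = None, baseline: float = 0.0
) -> HalfTime:
    """Time from the peak to the half-amplitude crossing on the decay.

    The peak is the global maximum (or the sample at ``peak_time`` if
    given); the crossing of ``baseline + (peak - baseline)/2`` is
    located by linear interpolation between the bracketing samples.
    Returns a censored result if the trace never falls to half peak.
    """
    t = trace.times
    y = trace.samples
    if peak_time is None:
        i_peak = int(np.argmax(y))
    else:
        i_peak = int(np.argmin(np.abs(t - peak_time)))
    peak = y[i_peak]
    if peak <= baseline:
        return HalfTime(np.nan, True)
    target = baseline + 0.5 * (peak - baseline)
    tc = _cross_time(t[i_peak:], y[i_peak:], target, rising=False)
    if tc is None:
        return HalfTime(np.nan, True)
    return HalfTime(float(tc - t[i_peak]), False)


def half_rise_time(
    trace: Trace, event_time: float = 0.0, baseline: float = 0.0
) -> HalfTime:
    """Time from ``event_time`` to the first upward half-peak crossing."""
    sl = trace.window_slice(event_time, trace.t0 + trace.duration)
    t = trace.times[sl]
    y = trace.samples[sl]
    if len(y) == 0:
        return HalfTime(np.nan, True)
    peak = float(y.max())
    if peak <= baseline:
        return HalfTime(np.nan, True)
    target = baseline + 0.5 * (peak - baseline)
    if y[0] > target:
        return HalfTime(0.0, False)
    tc = _cross_time(t, y, target, rising=True)
    if tc is None:
        return HalfTime(np.nan, True)
    return HalfTime(float(tc - event_time), False)


def fit_exp_decay(trace: Trace) -> ExpFit:
    """Least-squares single-exponential fit A*exp(-t/tau) to a decay segment.

    ``goodness`` is the RMS residual normalized by the fitted amplitude;
    callers filter on a threshold (0.1 by default elsewhere). Requires
    at least 5 samples and a positive initial value.
    """
    y = trace.samples
    if len(y) < 5:
        raise ValueError("need at least 5 samples")
    if y[0] <= 0:
        raise ValueError("initial value must be positive")
    t = trace.times - trace.t0

    # log-linear initialization on the positive part
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else trace.duration
    a0 = float(np.exp(intercept))

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[a0, max(tau0, 1e-3)], maxfev=10000,
            bounds=([0, 1e-6], [np.inf, np.inf]),
        )
    except RuntimeError:
        return ExpFit(np.nan, np.nan, np.inf, False)
    resid = y - model(t, *popt)
    goodness = float(np.sqrt(np.mean(resid**2)) / popt[0]) if popt[0] > 0 else np.inf
    return ExpFit(float(popt[0]), float(popt[1]), goodness, True)


def fourier_tracking(trace: Trace, f_stim: float) -> TrackingResult:
    """Stimulus-tracking amplitude of a ΔF/F0 trace.

    Magnitude spectrum of the stimulus-period trace divided by its 0 Hz
    magnitude (rectangular window, no padding); the reported amplitude
    is the value at the bin nearest ``f_stim``. Undefined (flagged) if
    the 0 Hz magnitude vanishes.
    """
    if trace.duration < 2.0 / f_stim:
        raise ValueError("trace must span at least two stimulus cycles")
    if trace.fs <= 2.0 * f_stim:
        raise ValueError("sampling rate must exceed twice the stimulus frequency")
    y = trace.samples
    mag = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(len(y), d=1.0 / trace.fs)
    if mag[0] <= 1e-12 * max(mag.max(), 1e-300):
        return TrackingResult(freqs, np.full_like(mag, np.nan), np.nan, False)
    spectrum = mag / mag[0]
    idx = int(np.argmin(np.abs(freqs - f_stim)))
    return TrackingResult(freqs, spectrum, float(spectrum[idx]), True)
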