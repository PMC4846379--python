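"""Fluorescence transient kernel.

A calcium-bound indicator transient is modelled as a difference of
exponentials,

    k(t) = (1 - exp(-t / tau_r)) * exp(-t / tau_d),   t >= 0,

which rises with time constant ``tau_r`` and decays with ``tau_d``.
Indicator data sheets quote half-rise and half-decay times rather than
exponential time constants, so ``solve_time_constants`` inverts the
half-time equations numerically: it finds the (tau_r, tau_d) pair whose
kernel reaches half of its peak ``half_rise_s`` after onset and falls
back to half of its peak ``half_decay_s`` after the peak.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, root


def kernel_peak_time(tau_r: float, tau_d: float) -> float:
    """Time of the kernel maximum, tau_r * log(1 + tau_d/tau_r)."""
    return tau_r * np.log1p(tau_d / tau_r)


def _kernel(t, tau_r, tau_d):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = -np.expm1(-tp / tau_r) * np.exp(-tp / tau_d)
    return out


def kernel_half_times(tau_r: float, tau_d: float) -> tuple[float, float]:
    """Half-rise (onset -> half peak) and half-decay (peak -> half peak)."""
    tp = kernel_peak_time(tau_r, tau_d)
    vp = float(_kernel(tp, tau_r, tau_d))
    half = 0.5 * vp

    def f(t):
        return float(_kernel(t, tau_r, tau_d)) - half

    t_half_rise = brentq(f, 1e-15, tp)
    # decay side: bracket generously; the tail is a clean exponential
    hi = tp + 50.0 * tau_d
    t_half_decay = brentq(f, tp, hi)
    return t_half_rise, t_half_decay - tp


# Largest attainable half-rise/half-decay ratio in this kernel family:
# as tau_r/tau_d -> inf the kernel tends to t*exp(-t/tau_d), whose
# half-rise/half-decay ratio is ~0.1384; slower relative rises require
# a sigmoidal onset the two-exponential model cannot produce.
_MAX_RATIO = 0.1380


@lru_cache(maxsize=256)
def solve_time_constants(half_rise_s: float, half_decay_s: float) -> tuple[float, float]:
    """Invert (half_rise, half_decay) -> (tau_r, tau_d).

    The kernel's shape depends only on rho = tau_r/tau_d, and the
    half-rise/half-decay ratio is monotone increasing in rho, so the
    inversion is a bracketed 1-D solve on log(rho) followed by a time
    rescaling. The requested ratio must stay below the family limit
    (~0.138).
    """
    if not (half_rise_s > 0 and half_decay_s > 0):
        raise ValueError("half times must be positive")
    target = half_rise_s / half_decay_s
    if target >= _MAX_RATIO:
        raise ValueError(
            f"half_rise/half_decay ratio {target:.3f} exceeds the "
            f"difference-of-exponentials limit {_MAX_RATIO}"
        )

    def ratio(log_rho):
        hr, hd = kernel_half_times(float(np.exp(log_rho)), 1.0)
        return hr / hd - target

    log_rho = brentq(ratio, np.log(1e-6), np.log(1e4), xtol=1e-13)
    rho = float(np.exp(log_rho))
    hr_unit, hd_unit = kernel_half_times(rho, 1.0)
    tau_d = half_decay_s / hd_unit
    return rho * tau_d, float(tau_d)


def unit_transient(t, half_rise_s: float, half_decay_s: float):
    """Kernel evaluated at times ``t`` (s from burst onset), peak scaled to 1."""
    tau_r, tau_d = solve_time_constants(half_rise_s, half_decay_s)
    vp = float(_kernel(kernel_peak_time(tau_r, tau_d), tau_r, tau_d))
    return _kernel(t, tau_r, tau_d) / vp
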