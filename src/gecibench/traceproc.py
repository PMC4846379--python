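"""Raw two-channel ROI fluorescence -> neuropil-corrected ΔF/F0.

The somatic signal measured in an ROI is contaminated by out-of-focus
neuropil fluorescence. The corrected cell signal is

    F_cell(t) = F_measured(t) - r * F_neuropil(t),    r = 0.7 by default,

and the correction is applied only to cells whose baseline fluorescence
exceeds the surrounding neuropil baseline by more than a margin
(3% by default) — otherwise F0 cannot be estimated reliably and the
cell is excluded upstream. ΔF/F0 is (F - F0)/F0 with F0 averaged over a
1 s window immediately before stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class Trace:
    """A uniformly sampled fluorescence series.

    ``samples`` are in arbitrary fluorescence units (or ΔF/F0 after
    normalization), ``fs`` is the frame rate in frames/s and ``t0`` the
    time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self):
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def window_slice(self, t_start: float, t_stop: float) -> slice:
        """Index slice covering samples with t_start <= t < t_stop."""
        i0 = int(np.ceil((t_start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self.samples))
        return slice(i0, i1)


@dataclass(frozen=True)
class CorrectionParams:
    """Neuropil correction coefficient and baseline-eligibility margin."""

    r: float = 0.7
    eligibility_margin: float = 0.03

    def __post_init__(self):
        if not 0 <= self.r < 1:
            raise ValueError("r must lie in [0, 1)")
        if self.eligibility_margin < 0:
            raise ValueError("eligibility_margin must be >= 0")


def _check_aligned(a: Trace, b: Trace):
    if len(a) != len(b) or not np.isclose(a.fs, b.fs):
        raise ValueError("traces must share length and frame rate")


def neuropil_correct(f_meas: Trace, f_np: Trace, params: CorrectionParams) -> Trace:
    """Subtract the scaled neuropil signal: F_meas - r * F_np, elementwise."""
    _check_aligned(f_meas, f_np)
    return replace(f_meas, samples=f_meas.samples - params.r * f_np.samples)


def check_eligibility(
    f_meas: Trace,
    f_np: Trace,
    params: CorrectionParams,
    baseline_windows: list[tuple[float, float]],
) -> tuple[bool, float]:
    """Baseline test gating the neuropil correction.

    Returns ``(eligible, ratio)`` where ratio is baseline(F_meas) /
    baseline(F_np) over the pre-stimulus windows and the cell is
    eligible iff the ratio exceeds ``1 + eligibility_margin``.
    """
    _check_aligned(f_meas, f_np)
    idx = np.zeros(len(f_meas), dtype=bool)
    for t0, t1 in baseline_windows:
        idx[f_meas.window_slice(t0, t1)] = True
    if not idx.any():
        raise ValueError("baseline windows select no samples")
    b_cell = float(f_meas.samples[idx].mean())
    b_np = float(f_np.samples[idx].mean())
    ratio = b_cell / b_np
    return ratio > 1.0 + params.eligibility_margin, ratio


def compute_f0(trace: Trace, window: tuple[float, float]) -> float:
    """Mean fluorescence over ``window`` = (t_start, t_stop) seconds."""
    sl = trace.window_slice(*window)
    if sl.start >= sl.stop:
        raise ValueError("F0 window selects no samples")
    return float(trace.samples[sl].mean())


def compute_dff(trace: Trace, f0: float) -> Trace:
    """(F - F0) / F0 elementwise; requires F0 > 0."""
    if not f0 > 0:
        raise ValueError("F0 must be > 0; exclude the cell upstream")
    return replace(trace, samples=(trace.samples - f0) / f0)


def moving_average(trace: Trace, k: int) -> Trace:
    """Centered k-point moving average (k odd); edges use truncated windows.

    Display smoothing only — quantitative estimators operate on raw
    traces.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be odd and >= 1")
    if k == 1:
        return replace(trace, samples=trace.samples.copy())
    kern = np.ones(k)
    summed = np.convolve(trace.samples, kern, mode="same")
    counts = np.convolve(np.ones(len(trace.samples)), kern, mode="same")
    return replace(trace, samples=summed / counts)


def unmix_channels(
    red: Trace, green: Trace, mixing: np.ndarray
) -> tuple[Trace, Trace]:
    """Undo linear spectral bleedthrough between two detection channels.

    ``mixing`` is the 2x2 forward matrix mapping true (red, green) to
    measured (red, green) at each time point; the inverse is applied.
    """
    _check_aligned(red, green)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape != (2, 2):
        raise ValueError("mixing must be 2x2")
    if abs(np.linalg.det(mixing)) < 1e-12:
        raise ValueError("mixing matrix is singular")
    inv = np.linalg.inv(mixing)
    stacked = np.vstack([red.samples, green.samples])
    unmixed = inv @ stacked
    return (
        replace(red, samples=unmixed[0]),
        replace(green, samples=unmixed[1]),
    )
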