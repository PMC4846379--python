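"""Template-projection spike detection on fluorescence snippets.

The analysis links fluorescence to ground-truth spikes: n-AP burst
events (n spikes inside an indicator-specific time bin, isolated from
other spikes by more than 1 s) and no-AP noise segments are cut from
the recording, converted to ΔF/F0 with a 10-frame pre-event baseline,
averaged into per-class templates, mean-subtracted and normalized into
unit vectors, and every snippet is scored by its inner product with the
unit vector. The score distributions yield d', empirical ROC curves and
detection accuracy at a fixed false-positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .traceproc import Trace

# Event time-bin schedules (seconds) by burst size. Bins widen with the
# number of APs to capture accumulating calcium, and are longer for the
# slower jRCaMP1a than for jRGECO1a.
_BIN_RULES = {
    "jRGECO1a": (0.100, 0.025, 0.250),  # 2 APs: 100 ms, +25 ms/AP, cap 250 ms
    "jRCaMP1a": (0.150, 0.050, 0.350),  # 2 APs: 150 ms, +50 ms/AP, cap 350 ms
}

# Default post-event snippet windows; longer for slow indicators.
_POST_WINDOW_S = {"jRGECO1a": 1.0, "jRCaMP1a": 2.0}


def ap_bin_width(indicator: str, n_ap: int) -> float:
    """Time-bin width for an ``n_ap``-burst under the indicator's schedule."""
    if n_ap < 2:
        raise ValueError("bins are defined for bursts of 2 or more APs")
    base, step, cap = _BIN_RULES[indicator]
    return min(base + step * (n_ap - 2), cap)


@dataclass
class APEventSet:
    """Labeled ΔF/F0 snippets: n-AP events plus no-AP noise segments."""

    snippets: np.ndarray  # (n_events, n_frames)
    labels: np.ndarray  # n_APs per snippet; 0 = noise
    fs: float
    indicator: str
    pre_frames: int = 10
    n_dropped: int = 0

    def of_class(self, n_ap: int) -> np.ndarray:
        return self.snippets[self.labels == n_ap]


@dataclass
class DetectionResult:
    templates: dict[int, np.ndarray]
    unit_vectors: dict[int, np.ndarray]
    signal_scores: dict[int, np.ndarray]
    noise_scores: dict[int, np.ndarray]
    dprimes: dict[int, float]
    roc: dict[int, np.ndarray] = field(default_factory=dict)
    accuracy_at_fpr: dict[int, float] = field(default_factory=dict)


def _cluster_spikes(times: np.ndarray, isolation_s: float) -> list[np.ndarray]:
    """Split sorted spike times into clusters separated by > isolation_s."""
    if len(times) == 0:
        return []
    breaks = np.where(np.diff(times) > isolation_s)[0]
    return np.split(times, breaks + 1)


def extract_events(
    spikes,
    trace: Trace,
    indicator: str,
    isolation_s: float = 1.0,
    pre_frames: int = 10,
    post_s: float | None = None,
    noise_bin_s: float = 4.0,
    max_ap: int = 8,
) -> APEventSet:
    """Cut labeled event and noise snippets from a recording.

    A cluster of n spikes (isolated from all other spikes by more than
    ``isolation_s``) is an n-AP event when n == 1, or when n in [2,
    ``max_ap``] and the cluster span fits the indicator's n-AP bin;
    clusters violating their bin are discarded. Snippets cover
    ``pre_frames`` frames before the first spike plus ``post_s``
    seconds, and are normalized to ΔF/F0 with F0 = the mean of the 10
    pre-event frames. Noise snippets are drawn from ``noise_bin_s``-long
    spike-free spans. Snippets that would run off the trace are dropped
    and counted in ``n_dropped``.
    """
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    if len(times) and (times.min() < trace.t0 or times.max() > trace.t0 + trace.duration):
        raise ValueError("spike times outside trace extent")
    if post_s is None:
        post_s = _POST_WINDOW_S.get(indicator, 1.0)
    n_post = int(round(post_s * trace.fs))
    length = pre_frames + n_post
    y = trace.samples

    snippets, labels = [], []
    dropped = 0

    def cut(t_first):
        i0 = int(np.floor((t_first - trace.t0) * trace.fs)) - pre_frames
        i1 = i0 + length
        if i0 < 0 or i1 > len(y):
            return None
        seg = y[i0:i1]
        f0 = seg[:pre_frames].mean()
        if f0 <= 0:
            return None
        return (seg - f0) / f0

    for cluster in _cluster_spikes(times, isolation_s):
        n = len(cluster)
        if n > 1:
            if n > max_ap or (cluster[-1] - cluster[0]) > ap_bin_width(indicator, n) + 1e-9:
                continue  # not a clean n-AP event under the schedule
        snip = cut(cluster[0])
        if snip is None:
            dropped += 1
            continue
        snippets.append(snip)
        labels.append(n)

    # spike-free spans, padded by the isolation window on both sides
    edges = np.concatenate([[trace.t0], times, [trace.t0 + trace.duration]])
    for lo, hi in zip(edges[:-1], edges[1:]):
        span_lo = lo + (isolation_s if lo != trace.t0 else 0.0)
        span_hi = hi - (isolation_s if hi != trace.t0 + trace.duration else 0.0)
        n_bins = int((span_hi - span_lo) // noise_bin_s)
        for b in range(n_bins):
            start = span_lo + b * noise_bin_s + pre_frames / trace.fs
            snip = cut(start)
            if snip is None:
                dropped += 1
                continue
            snippets.append(snip)
            labels.append(0)

    return APEventSet(
        snippets=np.array(snippets) if snippets else np.empty((0, length)),
        labels=np.array(labels, dtype=int),
        fs=trace.fs,
        indicator=indicator,
        pre_frames=pre_frames,
        n_dropped=dropped,
    )


def build_unit_template(events: np.ndarray) -> np.ndarray:
    """Mean snippet, mean-subtracted, scaled to unit Euclidean norm."""
    events = np.atleast_2d(np.asarray(events, dtype=float))
    if events.shape[0] < 1:
        raise ValueError("need at least one event")
    template = events.mean(axis=0)
    centered = template - template.mean()
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("template is constant; unit vector undefined")
    return centered / norm


def project(snippets: np.ndarray, unit_vector: np.ndarray) -> np.ndarray:
    """Inner product of each raw (un-normalized) snippet with the unit vector."""
    snippets = np.atleast_2d(np.asarray(snippets, dtype=float))
    unit_vector = np.asarray(unit_vector, dtype=float)
    if snippets.shape[1] != unit_vector.shape[0]:
        raise ValueError("snippet and template lengths differ")
    return snippets @ unit_vector


def dprime(signal_scores, noise_scores) -> float:
    """Sensitivity index with pooled equal-weight sample variances."""
    s = np.asarray(signal_scores, dtype=float)
    n = np.asarray(noise_scores, dtype=float)
    if len(s) < 2 or len(n) < 2:
        raise ValueError("need at least 2 scores per group")
    pooled = 0.5 * (s.var(ddof=1) + n.var(ddof=1))
    if pooled == 0:
        warnings.warn("zero pooled variance; d' is infinite")
        diff = s.mean() - n.mean()
        return np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0)
    return float((s.mean() - n.mean()) / np.sqrt(pooled))


def roc_curve(signal_scores, noise_scores) -> np.ndarray:
    """Empirical ROC over all threshold placements; ties grouped.

    Returns an (m, 2) array of (FPR, TPR) anchored at (0, 0) and
    (1, 1), nondecreasing in both coordinates.
    """
    s = np.sort(np.asarray(signal_scores, dtype=float))
    n = np.sort(np.asarray(noise_scores, dtype=float))
    if len(s) == 0 or len(n) == 0:
        raise ValueError("need nonempty score groups")
    thresholds = np.unique(np.concatenate([s, n]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for th in thresholds:
        tpr.append(1.0 - np.searchsorted(s, th, side="left") / len(s))
        fpr.append(1.0 - np.searchsorted(n, th, side="left") / len(n))
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def roc_auc(signal_scores, noise_scores) -> float:
    """Trapezoidal area under the empirical ROC."""
    pts = roc_curve(signal_scores, noise_scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def accuracy_at_fpr(signal_scores, noise_scores, fpr_target: float = 0.05) -> float:
    """Detection rate at a fixed empirical false-positive rate.

    The threshold is the (1 - fpr_target) quantile of the noise scores
    using the 'higher' interpolation convention (conservative: the
    realized FPR never exceeds the target); the return value is the
    fraction of signal scores strictly above the threshold.
    """
    if not 0 < fpr_target < 1:
        raise ValueError("fpr_target must lie in (0, 1)")
    s = np.asarray(signal_scores, dtype=float)
    n = np.asarray(noise_scores, dtype=float)
    if len(n) < 1.0 / fpr_target:
        warnings.warn(
            f"only {len(n)} noise scores for an FPR of {fpr_target}; "
            "quantile is conservative"
        )
    threshold = np.quantile(n, 1.0 - fpr_target, method="higher")
    return float(np.mean(s > threshold))


def analyze_events(
    events: APEventSet, fpr_target: float = 0.05, common_template: bool = False
) -> DetectionResult:
    """Full detection analysis of a labeled event set.

    Per burst size n, builds the template/unit vector (or, with
    ``common_template``, uses the 1-AP unit vector for all classes),
    projects the class's events and the noise snippets, and computes
    d', ROC and accuracy at the target FPR.
    """
    noise = events.of_class(0)
    classes = sorted(set(events.labels) - {0})
    result = DetectionResult({}, {}, {}, {}, {})
    shared = build_unit_template(events.of_class(classes[0])) if common_template else None
    for n in classes:
        evts = events.of_class(n)
        unit = shared if common_template else build_unit_template(evts)
        result.templates[n] = evts.mean(axis=0)
        result.unit_vectors[n] = unit
        s_scores = project(evts, unit)
        n_scores = project(noise, unit)
        result.signal_scores[n] = s_scores
        result.noise_scores[n] = n_scores
        result.dprimes[n] = dprime(s_scores, n_scores)
        result.roc[n] = roc_curve(s_scores, n_scores)
        result.accuracy_at_fpr[n] = accuracy_at_fpr(s_scores, n_scores, fpr_target)
    return result
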