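"""Culture-screen analytics.

In the neuronal culture screen, field electrodes evoke trains of 1 to
160 APs at 83 Hz in every neuron of a well while fluorescence is imaged
at 35 Hz. Per cell and train, the observables are the peak ΔF/F0, the
SNR (peak above baseline divided by the pre-stimulus standard
deviation) and the half-decay time after the train. Variants are
compared to their parent construct with a two-sided Wilcoxon rank-sum
test on per-cell peaks and ranked by significant improvements at 1/3/10
APs, excluding variants with a significant loss of the 160-AP maximal
response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import half_decay_time
from .traceproc import Trace


@dataclass
class WellRecord:
    """Per-cell fluorescence traces for every stimulus train in one well.

    ``traces[n_ap]`` is an (n_cells, n_frames) array of raw
    fluorescence; stimulation starts at ``stim_time_s`` into each
    trace.
    """

    variant: str
    traces: dict[int, np.ndarray]
    fs: float
    stim_time_s: float
    plate: str = "P1"
    well: str = "A1"
    train_hz: float = 83.0

    def n_cells(self) -> int:
        return next(iter(self.traces.values())).shape[0]


@dataclass
class VariantSummary:
    """Screen summary of one variant: per-AP-count medians and parent tests."""

    name: str
    median_peak: dict[int, float]
    median_snr: dict[int, float]
    half_decay_10ap_s: float
    fold_vs_parent: dict[int, float] = field(default_factory=dict)
    p_vs_parent: dict[int, float] = field(default_factory=dict)


class Comparison(NamedTuple):
    fold_change: float  # variant median peak / parent median peak
    pvalue: float
    n_variant: int
    n_parent: int
    defined: bool  # False when the parent median is not positive


def well_metrics(
    record: WellRecord,
    pre_s: float = 1.0,
    event_times_s: Sequence[float] | None = None,
    event_window_s: float = 1.0,
) -> pd.DataFrame:
    """Per-cell, per-train response metrics.

    F0 is the mean over the ``pre_s`` window before stimulation (>= 10
    frames required); peak ΔF/F0 is the post-stimulus maximum; SNR is
    peak divided by the pre-stimulus ΔF/F0 standard deviation (infinite,
    with a warning, for noiseless traces); the half decay is measured
    from the post-stimulus peak (NaN when censored).

    With ``event_times_s`` (slow trains whose individual responses are
    resolved, e.g. 1 Hz NMJ stimulation) the peak becomes the per-event
    amplitude: for each event, the maximum within ``event_window_s``
    minus the local baseline (mean of the 10 frames before the event),
    averaged over events. Subtracting the local baseline removes the
    summation tail of the preceding response.
    """
    n_pre = int(round(pre_s * record.fs))
    if n_pre < 10:
        raise ValueError("pre-stimulus window must cover at least 10 frames")
    i_stim = int(round(record.stim_time_s * record.fs))
    rows = []
    for n_ap, block in sorted(record.traces.items()):
        train_s = max(n_ap - 1, 0) / record.train_hz
        for cell in range(block.shape[0]):
            f = block[cell]
            f0 = f[i_stim - n_pre:i_stim].mean()
            dff = (f - f0) / f0
            sd_pre = float(dff[i_stim - n_pre:i_stim].std())
            if event_times_s is not None:
                amps = []
                for t_ev in event_times_s:
                    i_ev = int(round(t_ev * record.fs))
                    i_hi = min(i_ev + int(round(event_window_s * record.fs)), len(dff))
                    local = dff[i_ev - 10:i_ev].mean()
                    amps.append(float(dff[i_ev:i_hi].max() - local))
                peak = float(np.mean(amps))
            else:
                peak = float(dff[i_stim:].max())
            if sd_pre == 0.0:
                warnings.warn("zero pre-stimulus sd; SNR flagged infinite")
                snr = np.inf
            else:
                snr = peak / sd_pre
            tr = Trace(dff, fs=record.fs)
            hd = half_decay_time(
                tr, peak_time=None, baseline=0.0
            )
            rows.append(
                {
                    "plate": record.plate,
                    "well": record.well,
                    "variant": record.variant,
                    "cell_id": cell,
                    "train_aps": n_ap,
                    "train_s": train_s,
                    "peak_dff": peak,
                    "snr": snr,
                    "half_decay_s": hd.time_s,
                    "censored": hd.censored,
                }
            )
    return pd.DataFrame(rows)


def compare_variant_to_parent(
    variant_metrics: pd.DataFrame, parent_metrics: pd.DataFrame, ap_count: int
) -> Comparison:
    """Median fold-change and rank-sum p on per-cell peaks at one AP count."""
    v = variant_metrics.loc[variant_metrics.train_aps == ap_count, "peak_dff"].to_numpy()
    p = parent_metrics.loc[parent_metrics.train_aps == ap_count, "peak_dff"].to_numpy()
    if len(v) < 3 or len(p) < 3:
        raise ValueError("need at least 3 cells per side")
    med_p = float(np.median(p))
    defined = med_p > 0
    fold = float(np.median(v)) / med_p if defined else np.nan
    pval = float(stats.mannwhitneyu(v, p, alternative="two-sided").pvalue)
    return Comparison(fold, pval, len(v), len(p), defined)


def summarize_variant(
    metrics: pd.DataFrame,
    parent_metrics: pd.DataFrame | None = None,
    name: str | None = None,
) -> VariantSummary:
    """Collapse a per-cell metrics table into a VariantSummary."""
    name = name or str(metrics.variant.iloc[0])
    by_ap = metrics.groupby("train_aps")
    median_peak = by_ap.peak_dff.median().to_dict()
    median_snr = by_ap.snr.median().to_dict()
    hd10 = float(
        metrics.loc[(metrics.train_aps == 10) & ~metrics.censored, "half_decay_s"].median()
    ) if (metrics.train_aps == 10).any() else np.nan
    summary = VariantSummary(name, median_peak, median_snr, hd10)
    if parent_metrics is not None:
        for n_ap in sorted(median_peak):
            cmp = compare_variant_to_parent(metrics, parent_metrics, n_ap)
            summary.fold_vs_parent[n_ap] = cmp.fold_change
            summary.p_vs_parent[n_ap] = cmp.pvalue
    return summary


def rank_variants(
    summaries: Sequence[VariantSummary],
    improvement_aps: tuple[int, ...] = (1, 3, 10),
    max_ap: int = 160,
    alpha: float = 0.01,
) -> list[VariantSummary]:
    """Order variants by screen merit.

    A variant is excluded when its ``max_ap`` response is significantly
    reduced versus the parent (p < alpha and fold < 1). The remainder
    are sorted lexicographically: number of significant improvements
    (p < alpha and fold > 1) across ``improvement_aps``, then the mean
    fold-change across those counts. Ranking is insensitive to input
    order (stable sort on a deterministic key).
    """
    kept = []
    for s in summaries:
        p160 = s.p_vs_parent.get(max_ap, 1.0)
        f160 = s.fold_vs_parent.get(max_ap, 1.0)
        if p160 < alpha and f160 < 1.0:
            continue
        n_sig = sum(
            1
            for n in improvement_aps
            if s.p_vs_parent.get(n, 1.0) < alpha and s.fold_vs_parent.get(n, 0.0) > 1.0
        )
        mean_fold = float(
            np.mean([s.fold_vs_parent.get(n, np.nan) for n in improvement_aps])
        )
        kept.append((n_sig, mean_fold, s))
    kept.sort(key=lambda t: (-t[0], -(t[1] if np.isfinite(t[1]) else -np.inf), t[2].name))
    return [s for _, _, s in kept]
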