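"""Spike-to-fluorescence forward model with known ground truth.

Every analysis stage in this package is exercised on data from this
generator, so each estimator can be validated by parameter recovery:

1. spikes -> ΔF/F0: spikes are grouped into bursts (maximal runs with
   inter-spike gaps below 250 ms); each burst contributes one
   difference-of-exponentials kernel scaled so its peak equals the
   indicator's saturating burst-amplitude curve A(n); bursts superpose
   additively. A long high-frequency train is therefore a single burst
   whose peak is A(n_total) — the model does not resolve intra-train
   accumulation dynamics.
2. ΔF/F0 -> measured fluorescence: F_np is the shared neuropil channel
   (baseline plus a slow Gaussian-process fluctuation, 1 s correlation
   length); F_cell_true = F0*(1 + ΔF/F) plus additive white noise; the
   ROI reads F_meas = F_cell_true + r_true * F_np.
3. Trial structure for visual cortex emulation: 8 grating directions x
   5 trials, 4 s blank + 4 s stimulus per trial; responsive cells fire
   inhomogeneous-Poisson spikes whose stimulus rate follows a
   double-Gaussian direction-tuning profile; non-responsive cells fire
   homogeneous background spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._kernel import kernel_peak_time, solve_time_constants
from .depth import DepthProfile
from .detection import ap_bin_width
from .presets import IndicatorKinetics
from .screen import WellRecord
from .traceproc import Trace
from .tuning import DIRECTIONS, _double_gaussian

BURST_WINDOW_S = 0.25  # widest event bin; amplitudes are per burst, not per spike


@dataclass
class SpikeTrain:
    """Sorted spike times (s) on [0, duration]; duplicates removed."""

    times: np.ndarray
    duration: float

    def __post_init__(self):
        t = np.unique(np.asarray(self.times, dtype=float))
        if len(t) and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")
        self.times = t

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition and noise parameters of the simulated microscope."""

    fs: float = 15.0  # frames/s
    f0: float = 100.0  # baseline fluorescence, arbitrary units
    noise_sd: float = 0.02  # white-noise sd as a fraction of f0
    r_true: float = 0.7  # neuropil contamination coefficient
    neuropil_amp: float = 0.05  # sd of the slow shared fluctuation, fraction of f0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.f0 <= 0:
            raise ValueError("fs and f0 must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.r_true < 1:
            raise ValueError("r_true must lie in [0, 1)")


@dataclass
class GroundTruthCell:
    cell_id: int
    responsive: bool
    theta_pref: float  # degrees in [0, 360)
    sigma: float  # degrees
    a1_rate: float  # Hz above baseline at the preferred direction
    a2_rate: float
    base_rate: float  # untuned stimulus-driven rate, Hz
    blank_rate: float  # spontaneous rate, Hz
    true_osi: float
    spikes: SpikeTrain | None = None


@dataclass
class CellRecording:
    cell_id: int
    f_meas: Trace
    f_np: Trace
    spikes: SpikeTrain


@dataclass
class Population:
    cells: list[CellRecording]
    truth: list[GroundTruthCell]
    schedule: pd.DataFrame
    kinetics: IndicatorKinetics
    config: ImagingConfig


def group_bursts(times: np.ndarray, window_s: float = BURST_WINDOW_S):
    """Maximal runs of spikes whose inter-spike gaps are <= window_s.

    Returns a list of (first_time, last_time, n_spikes).
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return []
    breaks = np.where(np.diff(times) > window_s)[0]
    return [(grp[0], grp[-1], len(grp)) for grp in np.split(times, breaks + 1)]


def spikes_to_dff(
    spikes: SpikeTrain,
    kin: IndicatorKinetics,
    fs: float,
    duration: float | None = None,
    burst_window_s: float = BURST_WINDOW_S,
) -> np.ndarray:
    """Render a spike train as a noiseless ΔF/F0 series.

    Output has ceil(duration * fs) samples at times k/fs. Each burst of
    n spikes adds ``kin.amplitude(n)`` times the unit-peak kernel
    anchored at the burst's *last* spike — calcium accumulates over a
    burst, so the fluorescence peak follows the final action potential.
    For single spikes the anchor is the spike time. An empty train
    yields zeros.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if duration is None:
        duration = spikes.duration
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    dff = np.zeros(n)
    for _, last, count in group_bursts(spikes.times, burst_window_s):
        dff += kin.amplitude(count) * kin.transient(t - last)
    return dff


def _neuropil_fluctuation(n: int, fs: float, amp: float, rng) -> np.ndarray:
    """Slow zero-mean fluctuation: Gaussian process, 1 s correlation length."""
    if amp == 0.0 or n < 2:
        return np.zeros(n)
    white = rng.standard_normal(n)
    slow = gaussian_filter1d(white, sigma=1.0 * fs, mode="reflect")
    sd = slow.std()
    if sd == 0:
        return np.zeros(n)
    return amp * slow / sd


def render_fov(
    dff: np.ndarray, cfg: ImagingConfig, rng: np.random.Generator | None = None
) -> tuple[Trace, Trace]:
    """Turn a ΔF/F0 series into the measured ROI and neuropil channels.

    F_np = F0 * (1 + slow shared fluctuation); F_cell_true =
    F0 * (1 + ΔF/F) + white noise; F_meas = F_cell_true + r_true * F_np.
    Reproducible from cfg.seed when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dff = np.asarray(dff, dtype=float)
    n = len(dff)
    f_np = cfg.f0 * (1.0 + _neuropil_fluctuation(n, cfg.fs, cfg.neuropil_amp, rng))
    noise = cfg.noise_sd * cfg.f0 * rng.standard_normal(n) if cfg.noise_sd else 0.0
    f_true = cfg.f0 * (1.0 + dff) + noise
    f_meas = f_true + cfg.r_true * f_np
    return Trace(f_meas, fs=cfg.fs), Trace(f_np, fs=cfg.fs)


def make_schedule(
    n_trials_per_dir: int = 5, blank_s: float = 4.0, stim_s: float = 4.0
) -> pd.DataFrame:
    """Trial schedule: cycles through the 8 directions, 5 cycles, 8 s trials."""
    rows = []
    trial = 0
    for cycle in range(n_trials_per_dir):
        for d in DIRECTIONS:
            t0 = trial * (blank_s + stim_s)
            rows.append(
                {
                    "trial": trial,
                    "cycle": cycle,
                    "direction": d,
                    "blank_start": t0,
                    "stim_start": t0 + blank_s,
                    "stim_end": t0 + blank_s + stim_s,
                }
            )
            trial += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TuningSpec:
    """Ranges for the per-cell ground-truth tuning parameters (rates in Hz).

    Defaults emulate mouse V1 L2/3 under drifting gratings: sparse
    spontaneous firing (~0.2 Hz), evoked rates of a few Hz at the
    preferred direction, and tuning widths of 25-40 degrees. Keeping
    evoked rates in this range also keeps the spike-to-fluorescence
    mapping near its linear regime (few large saturating bursts), which
    is the regime in which tuning parameters are identifiable from
    ΔF/F0 at all.
    """

    blank_rate: float = 0.2
    base_rate: float = 0.5
    pref_rate: tuple[float, float] = (3.0, 5.0)  # A1 range
    a2_frac: tuple[float, float] = (0.0, 0.5)  # A2 as a fraction of A1
    sigma_deg: tuple[float, float] = (25.0, 40.0)


def _poisson_times(rate_hz, t0, t1, rng):
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_tuned_population(
    n_cells: int,
    frac_responsive: float,
    kin: IndicatorKinetics,
    cfg: ImagingConfig,
    tuning: TuningSpec | None = None,
    n_trials_per_dir: int = 5,
) -> Population:
    """Simulate a trial-structured V1-style population recording.

    Responsive cells fire stimulus-locked Poisson spikes at the
    double-Gaussian tuned rate; non-responsive cells fire homogeneous
    background spikes. Ground truth (tuning parameters and OSI on the
    rate scale) is recorded per cell.
    """
    if not 0 <= frac_responsive <= 1:
        raise ValueError("frac_responsive must lie in [0, 1]")
    tuning = tuning or TuningSpec()
    schedule = make_schedule(n_trials_per_dir)
    duration = float(schedule.stim_end.iloc[-1])
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_cells)
    n_resp = int(round(frac_responsive * n_cells))

    cells, truth = [], []
    for cid in range(n_cells):
        rng = np.random.default_rng(seeds[cid])
        responsive = cid < n_resp
        theta_pref = float(rng.uniform(0.0, 360.0))
        sigma = float(rng.uniform(*tuning.sigma_deg))
        a1 = float(rng.uniform(*tuning.pref_rate))
        a2 = a1 * float(rng.uniform(*tuning.a2_frac))

        def rate(d):
            return _double_gaussian(d, tuning.base_rate, a1, a2, theta_pref, sigma, 180.0)

        times = []
        for rec in schedule.itertuples():
            times.append(_poisson_times(tuning.blank_rate, rec.blank_start, rec.stim_start, rng))
            stim_rate = float(rate(rec.direction)) if responsive else tuning.blank_rate
            times.append(_poisson_times(stim_rate, rec.stim_start, rec.stim_end, rng))
        spikes = SpikeTrain(np.concatenate(times), duration)
        dff = spikes_to_dff(spikes, kin, cfg.fs, duration)
        f_meas, f_np = render_fov(dff, cfg, rng=rng)
        cells.append(CellRecording(cid, f_meas, f_np, spikes))

        r_pref = float(rate(theta_pref))
        r_ortho = float(rate(theta_pref + 90.0))
        truth.append(
            GroundTruthCell(
                cell_id=cid,
                responsive=responsive,
                theta_pref=theta_pref,
                sigma=sigma,
                a1_rate=a1,
                a2_rate=a2,
                base_rate=tuning.base_rate,
                blank_rate=tuning.blank_rate,
                true_osi=(r_pref - r_ortho) / (r_pref + r_ortho),
                spikes=spikes,
            )
        )
    return Population(cells, truth, schedule, kin, cfg)


@dataclass
class EventDatasetTruth:
    labels: np.ndarray
    amplitudes: np.ndarray  # noiseless peak ΔF/F0 per snippet (0 for noise)


def generate_ap_event_dataset(
    counts_per_class: dict[int, int],
    n_noise: int,
    kin: IndicatorKinetics,
    cfg: ImagingConfig,
    indicator: str | None = None,
    pre_frames: int = 10,
    post_s: float = 1.0,
):
    """Labeled isolated burst snippets plus no-AP noise segments.

    Each n-AP event is rendered as its own snippet (10 baseline frames
    + ``post_s`` seconds) with the event's n spikes spread over the
    indicator's n-AP time bin; the burst onset is placed so the kernel
    peak falls exactly on a sample. Noise snippets contain baseline and
    noise only. Returns (APEventSet, EventDatasetTruth); snippets are
    ΔF/F0 with F0 = the mean of the 10 pre-event frames, mirroring the
    event-extraction convention.
    """
    from .detection import APEventSet  # local import to avoid cycle at module load

    if any(c < 0 for c in counts_per_class.values()) or n_noise < 0:
        raise ValueError("counts must be nonnegative")
    indicator = indicator or kin.name
    rng = np.random.default_rng(cfg.seed)
    n_post = int(round(post_s * cfg.fs))
    length = pre_frames + n_post
    t = np.arange(length) / cfg.fs

    tau_r, tau_d = solve_time_constants(kin.half_rise_s, kin.half_decay_s)
    t_peak = kernel_peak_time(tau_r, tau_d)

    snippets, labels, amps = [], [], []
    for n_ap in sorted(counts_per_class):
        width = 0.0 if n_ap == 1 else ap_bin_width(indicator, n_ap)
        # kernel is anchored at the burst's last spike; place that anchor
        # so the kernel peak falls exactly on a sample, with the whole
        # burst after the 10-frame baseline window
        k_peak = pre_frames + 1 + int(np.ceil((t_peak + width) * cfg.fs))
        anchor = k_peak / cfg.fs - t_peak
        spike_times = anchor - width + (
            np.linspace(0.0, width, n_ap) if n_ap > 1 else np.zeros(1)
        )
        dff = spikes_to_dff(SpikeTrain(spike_times, length / cfg.fs), kin, cfg.fs, length / cfg.fs)
        for _ in range(counts_per_class[n_ap]):
            f = cfg.f0 * (1.0 + dff)
            if cfg.noise_sd:
                f = f + cfg.noise_sd * cfg.f0 * rng.standard_normal(length)
            f0 = f[:pre_frames].mean()
            snippets.append((f - f0) / f0)
            labels.append(n_ap)
            amps.append(kin.amplitude(n_ap))
    for _ in range(n_noise):
        f = np.full(length, cfg.f0)
        if cfg.noise_sd:
            f = f + cfg.noise_sd * cfg.f0 * rng.standard_normal(length)
        f0 = f[:pre_frames].mean()
        snippets.append((f - f0) / f0)
        labels.append(0)
        amps.append(0.0)

    events = APEventSet(
        snippets=np.array(snippets),
        labels=np.array(labels, dtype=int),
        fs=cfg.fs,
        indicator=indicator,
        pre_frames=pre_frames,
    )
    return events, EventDatasetTruth(events.labels.copy(), np.array(amps))


def generate_ap_session(
    event_plan: list[int],
    kin: IndicatorKinetics,
    cfg: ImagingConfig,
    indicator: str | None = None,
    spacing_s: float = 6.0,
) -> tuple[SpikeTrain, Trace]:
    """One continuous recording with well-separated planned burst events.

    ``event_plan`` lists the burst sizes in temporal order; events are
    ``spacing_s`` apart (well beyond the 1 s isolation window). Used to
    exercise event extraction end to end.
    """
    indicator = indicator or kin.name
    times = []
    for i, n_ap in enumerate(event_plan):
        onset = 3.0 + i * spacing_s
        width = 0.0 if n_ap == 1 else ap_bin_width(indicator, n_ap)
        times.append(onset + (np.linspace(0.0, width, n_ap) if n_ap > 1 else np.zeros(1)))
    duration = 3.0 + len(event_plan) * spacing_s + 3.0
    spikes = SpikeTrain(np.concatenate(times) if times else np.empty(0), duration)
    dff = spikes_to_dff(spikes, kin, cfg.fs, duration)
    rng = np.random.default_rng(cfg.seed)
    noise = cfg.noise_sd * cfg.f0 * rng.standard_normal(len(dff)) if cfg.noise_sd else 0.0
    f = Trace(cfg.f0 * (1.0 + dff) + noise, fs=cfg.fs)
    return spikes, f


def generate_depth_profiles(
    n_dendrites: int,
    lambda_true_um: float,
    depth_grid_um,
    noise_cv: float,
    seed: int = 0,
) -> tuple[list[DepthProfile], float]:
    """Exponentially attenuating dendrite brightness profiles.

    Per dendrite, F(z) = F(z0) * exp(-(z - z0)/lambda) with
    multiplicative lognormal-free Gaussian noise of coefficient of
    variation ``noise_cv`` (negative draws truncated just above zero).
    Returns the profiles and the generating length constant.
    """
    if not np.isfinite(lambda_true_um) or lambda_true_um <= 0:
        raise ValueError("lambda_true_um must be finite and positive")
    depths = np.asarray(depth_grid_um, dtype=float)
    if np.any(depths < 0) or np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be nonnegative and increasing")
    rng = np.random.default_rng(seed)
    profiles = []
    for d in range(n_dendrites):
        f_surface = float(rng.lognormal(mean=np.log(1000.0), sigma=0.3))
        clean = f_surface * np.exp(-(depths - depths[0]) / lambda_true_um)
        noisy = clean * (1.0 + noise_cv * rng.standard_normal(len(depths)))
        noisy = np.maximum(noisy, 1e-6 * f_surface)
        profiles.append(
            DepthProfile(depths, noisy, dendrite_id=d, indicator="synthetic")
        )
    return profiles, lambda_true_um


def generate_screen_plate(
    variants: list[IndicatorKinetics],
    n_cells_per_well: int,
    cfg: ImagingConfig,
    protocol: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 40, 80, 160),
    train_hz: float = 83.0,
    jitter_cv: float = 0.15,
    pre_s: float = 1.0,
    post_s: float = 4.0,
) -> list[WellRecord]:
    """One well per variant, with per-cell jittered kinetics.

    Each well holds ``n_cells_per_well`` traces per AP-count in
    ``protocol``. Per-cell kinetics are multiplicatively jittered
    (lognormal, sd ``jitter_cv`` in log space) around the variant's
    amplitude and decay; ``jitter_cv=0`` reproduces the variant
    exactly.
    """
    if any(n <= 0 for n in protocol):
        raise ValueError("protocol AP counts must be positive")
    wells = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(variants))
    max_train_s = (max(protocol) - 1) / train_hz
    n_frames = int(np.ceil((pre_s + max_train_s + post_s) * cfg.fs))
    duration = n_frames / cfg.fs
    for vi, kin in enumerate(variants):
        rng = np.random.default_rng(seeds[vi])
        traces: dict[int, np.ndarray] = {}
        cell_kins = []
        for c in range(n_cells_per_well):
            if jitter_cv > 0:
                amp = kin.one_ap_amplitude * rng.lognormal(0.0, jitter_cv)
                # one shared speed factor so the rise/decay shape is preserved
                speed = rng.lognormal(0.0, jitter_cv)
                hd = kin.half_decay_s * speed
                hr = kin.half_rise_s * speed
            else:
                amp, hd, hr = kin.one_ap_amplitude, kin.half_decay_s, kin.half_rise_s
            cell_kins.append(
                IndicatorKinetics(
                    name=kin.name,
                    one_ap_amplitude=amp,
                    half_rise_s=hr,
                    half_decay_s=hd,
                    max_amplitude=max(kin.max_amplitude, amp),
                    amplitude_anchored=False,
                )
            )
        for n_ap in protocol:
            block = np.empty((n_cells_per_well, n_frames))
            spike_times = pre_s + np.arange(n_ap) / train_hz
            for c in range(n_cells_per_well):
                dff = spikes_to_dff(
                    SpikeTrain(spike_times, duration), cell_kins[c], cfg.fs, duration
                )
                noise = (
                    cfg.noise_sd * cfg.f0 * rng.standard_normal(n_frames)
                    if cfg.noise_sd
                    else 0.0
                )
                block[c] = cfg.f0 * (1.0 + dff) + noise
            traces[n_ap] = block
        wells.append(
            WellRecord(
                variant=kin.name,
                traces=traces,
                fs=cfg.fs,
                stim_time_s=pre_s,
                well=f"A{vi + 1}",
            )
        )
    return wells
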