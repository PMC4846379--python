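"""Generator-truth recovery experiments at study scale.

Each function simulates one published-condition experiment with this
package's forward model (using the published value as the generator
truth where one exists) and recovers the quantity with the package's
own estimator. They are used both by the test suite and by the
acceptance script; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np

from .depth import summarize_attenuation
from .kinetics import half_decay_time
from .presets import kinetics_preset
from .screen import WellRecord, well_metrics
from .synth import SpikeTrain, generate_depth_profiles, spikes_to_dff
from .traceproc import Trace

DEPTH_GRID_UM = np.arange(100.0, 501.0, 10.0)

# published medians of the depth length constant: 130 um over 19 red-GECI
# dendrites vs 75 um over 14 green-GECI (GCaMP6) dendrites
RED_LAMBDA_UM, N_RED_DENDRITES = 130.0, 19
GREEN_LAMBDA_UM, N_GREEN_DENDRITES = 75.0, 14


def depth_attenuation_recovery(seed: int = 0, noise_cv: float = 0.1):
    """Median fitted length constants for the red vs green dendrite groups.

    Returns (median_red_um, median_green_um, ranksum_p, n_red, n_green).
    """
    red, _ = generate_depth_profiles(
        N_RED_DENDRITES, RED_LAMBDA_UM, DEPTH_GRID_UM, noise_cv, seed=seed
    )
    green, _ = generate_depth_profiles(
        N_GREEN_DENDRITES, GREEN_LAMBDA_UM, DEPTH_GRID_UM, noise_cv, seed=seed + 1
    )
    summary, p = summarize_attenuation({"red": red, "green": green})
    med = summary.set_index("group").median_lambda_um
    return float(med["red"]), float(med["green"]), p, N_RED_DENDRITES, N_GREEN_DENDRITES


def v1_half_decay_s(indicator: str, fs: float = 15.0) -> float:
    """Half decay of a noiseless single-burst transient at the V1 frame rate.

    Renders one isolated burst with the indicator's in vivo preset and
    reads the half-decay from the transient peak by linear
    interpolation — the estimator applied to post-stimulus transients.
    Deterministic (noiseless).
    """
    kin = kinetics_preset(indicator, "v1")
    dff = spikes_to_dff(SpikeTrain([2.0], 2.0 + 12.0 * kin.half_decay_s), kin, fs)
    res = half_decay_time(Trace(dff, fs=fs))
    if res.censored:
        raise RuntimeError("transient never reached half peak")
    return res.time_s


def nmj_single_ap_amplitude_pct(
    seed: int = 0,
    n_fov: int = 12,
    boutons_per_fov: int = 4,
    noise_sd: float = 0.02,
    fs: float = 30.0,
):
    """Grand-mean single-AP peak ΔF/F0 (%) across NMJ fields of view.

    Emulates the fly NMJ assay: 1 Hz stimulation for 2 s (two evoked
    APs), ``boutons_per_fov`` bouton traces per field of view with
    additive ΔF/F0 noise. The four bouton traces of each FOV are
    averaged (the assay's unit of analysis is the FOV-mean transient)
    and the per-AP amplitude is the event peak above the local 10-frame
    pre-event baseline, via ``well_metrics``. Returns (grand_mean_pct,
    sem_pct).
    """
    kin = kinetics_preset("jRGECO1a", "nmj")
    rng = np.random.default_rng(seed)
    stim_times = [1.0, 2.0]
    duration = 5.0
    base = spikes_to_dff(SpikeTrain(stim_times, duration), kin, fs)
    f0 = 100.0
    fov_means = []
    for _ in range(n_fov):
        boutons = base + noise_sd * rng.standard_normal((boutons_per_fov, len(base)))
        avg = boutons.mean(axis=0)
        rec = WellRecord("jRGECO1a", {1: f0 * (1.0 + avg)[None, :]}, fs=fs, stim_time_s=1.0)
        m = well_metrics(rec, event_times_s=stim_times, event_window_s=1.0)
        fov_means.append(float(m.peak_dff.iloc[0]))
    fov_means = 100.0 * np.asarray(fov_means)
    return float(fov_means.mean()), float(fov_means.std(ddof=1) / np.sqrt(n_fov))


def nmj_tetanus_half_decay_s(fs: float = 30.0) -> float:
    """Half decay after a 160 Hz, 2 s tetanus, noiseless, from stimulus offset."""
    kin = kinetics_preset("jRGECO1a", "nmj")
    t_on, t_off = 1.0, 3.0
    times = t_on + np.arange(320) / 160.0
    dff = spikes_to_dff(SpikeTrain(times, 10.0), kin, fs)
    tr = Trace(dff, fs=fs)
    sl = tr.window_slice(t_off, tr.duration)
    post = Trace(tr.samples[sl], fs=fs)
    res = half_decay_time(post)
    if res.censored:
        raise RuntimeError("tetanus response never reached half peak")
    return res.time_s
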