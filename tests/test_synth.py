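"""Forward-model generator: oracles, invariants and reproducibility."""

import numpy as np
import pytest

from gecibench import (
    ImagingConfig,
    SpikeTrain,
    generate_ap_event_dataset,
    generate_depth_profiles,
    generate_screen_plate,
    generate_tuned_population,
    kinetics_preset,
    render_fov,
    spikes_to_dff,
)
from gecibench.synth import group_bursts
from gecibench.traceproc import CorrectionParams, Trace, compute_dff, compute_f0, neuropil_correct


class TestSpikesToDff:
    def test_empty_train_is_zero(self, jrgeco_v1):
        dff = spikes_to_dff(SpikeTrain([], 4.0), jrgeco_v1, 15.0)
        assert dff.shape == (60,)
        assert np.all(dff == 0.0)

    def test_single_spike_peak_near_one_ap_amplitude(self, jrgeco_v1):
        dff = spikes_to_dff(SpikeTrain([1.0], 8.0), jrgeco_v1, 200.0)
        assert dff.max() == pytest.approx(jrgeco_v1.one_ap_amplitude, rel=1e-3)

    def test_superposition_of_distant_spikes(self, jrgeco_v1):
        """Two spikes 5 s apart equal the sum of the single-spike traces."""
        a = spikes_to_dff(SpikeTrain([1.0], 12.0), jrgeco_v1, 30.0, duration=12.0)
        b = spikes_to_dff(SpikeTrain([6.0], 12.0), jrgeco_v1, 30.0, duration=12.0)
        both = spikes_to_dff(SpikeTrain([1.0, 6.0], 12.0), jrgeco_v1, 30.0)
        np.testing.assert_allclose(both, a + b, atol=1e-12)

    def test_burst_grouping_oracle(self):
        """Gap-based grouping matches a hand enumeration."""
        times = np.array([0.0, 0.1, 0.2, 1.0, 2.0, 2.2, 2.4, 2.7])
        got = group_bursts(times, window_s=0.25)
        assert got == [(0.0, 0.2, 3), (1.0, 1.0, 1), (2.0, 2.4, 3), (2.7, 2.7, 1)]

    def test_burst_peak_follows_amplitude_curve(self, jrgeco_v1):
        """Measured noiseless peaks preserve amplitude-curve monotonicity."""
        peaks = []
        for n in [1, 2, 5, 20, 160]:
            spikes = SpikeTrain(1.0 + np.arange(n) / 83.0, 10.0)
            dff = spikes_to_dff(spikes, jrgeco_v1, 500.0)
            peaks.append(dff.max())
            assert dff.max() == pytest.approx(jrgeco_v1.amplitude(n), rel=1e-3)
        assert np.all(np.diff(peaks) > 0)


class TestRenderFov:
    def test_noiseless_identity(self, jrgeco_v1):
        dff = spikes_to_dff(SpikeTrain([1.0], 6.0), jrgeco_v1, 15.0)
        cfg = ImagingConfig(fs=15.0, noise_sd=0.0, neuropil_amp=0.0, r_true=0.0, seed=0)
        f_meas, f_np = render_fov(dff, cfg)
        np.testing.assert_allclose(f_meas.samples, cfg.f0 * (1.0 + dff), atol=1e-12)
        np.testing.assert_allclose(f_np.samples, cfg.f0, atol=1e-12)

    def test_correction_cancels_neuropil_exactly(self, jrgeco_v1):
        dff = spikes_to_dff(SpikeTrain([1.0], 6.0), jrgeco_v1, 15.0)
        cfg = ImagingConfig(fs=15.0, noise_sd=0.0, neuropil_amp=0.1, r_true=0.7, seed=3)
        f_meas, f_np = render_fov(dff, cfg)
        corr = neuropil_correct(f_meas, f_np, CorrectionParams(r=cfg.r_true))
        np.testing.assert_allclose(corr.samples, cfg.f0 * (1.0 + dff), atol=1e-9)

    def test_noise_moment(self):
        """Residual noise sd matches the configured fraction of F0."""
        cfg = ImagingConfig(fs=100.0, noise_sd=0.02, neuropil_amp=0.05, r_true=0.7, seed=5)
        dff = np.zeros(10_000)
        f_meas, f_np = render_fov(dff, cfg)
        resid = (f_meas.samples - cfg.r_true * f_np.samples - cfg.f0 * (1.0 + dff)) / cfg.f0
        mc_err = 0.02 / np.sqrt(2 * (len(dff) - 1))
        assert resid.std() == pytest.approx(0.02, abs=3 * mc_err)

    def test_seed_determinism(self):
        cfg = ImagingConfig(fs=30.0, noise_sd=0.03, neuropil_amp=0.05, seed=9)
        dff = np.zeros(500)
        a = render_fov(dff, cfg)
        b = render_fov(dff, cfg)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        np.testing.assert_array_equal(a[1].samples, b[1].samples)

    def test_roundtrip_recovers_dff(self, jrgeco_v1, quiet_cfg):
        """Noiseless render -> correct -> ΔF/F reproduces the input exactly."""
        spikes = SpikeTrain([5.0], 10.0)
        dff = spikes_to_dff(spikes, jrgeco_v1, quiet_cfg.fs)
        f_meas, f_np = render_fov(dff, quiet_cfg)
        corr = neuropil_correct(f_meas, f_np, CorrectionParams(r=quiet_cfg.r_true))
        f0 = compute_f0(corr, (0.0, 4.0))
        got = compute_dff(corr, f0)
        np.testing.assert_allclose(got.samples, dff, atol=1e-9)


class TestTunedPopulation:
    def test_structure(self, small_population):
        pop = small_population
        assert len(pop.schedule) == 40
        n_frames = int(np.ceil(320.0 * pop.config.fs))
        for cell in pop.cells:
            assert len(cell.f_meas) == n_frames
        assert len(pop.truth) == len(pop.cells)
        for gt in pop.truth:
            assert 0.0 <= gt.theta_pref < 360.0

    def test_frac_responsive_bounds(self, jrgeco_v1, quiet_cfg):
        with pytest.raises(ValueError):
            generate_tuned_population(2, 1.5, jrgeco_v1, quiet_cfg)

    def test_determinism(self, jrgeco_v1):
        cfg = ImagingConfig(fs=15.0, noise_sd=0.02, seed=21)
        a = generate_tuned_population(2, 1.0, jrgeco_v1, cfg)
        b = generate_tuned_population(2, 1.0, jrgeco_v1, cfg)
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.f_meas.samples, cb.f_meas.samples)
            np.testing.assert_array_equal(ca.spikes.times, cb.spikes.times)


class TestEventDataset:
    def test_counts_match_request(self, jrgeco_v1):
        cfg = ImagingConfig(fs=30.0, noise_sd=0.01, seed=2)
        events, truth = generate_ap_event_dataset({1: 199}, 320, jrgeco_v1, cfg)
        assert int((events.labels == 1).sum()) == 199
        assert int((events.labels == 0).sum()) == 320
        np.testing.assert_array_equal(events.labels, truth.labels)

    def test_noiseless_peaks_exact(self, jrgeco_v1):
        cfg = ImagingConfig(fs=30.0, noise_sd=0.0, seed=2)
        events, truth = generate_ap_event_dataset({1: 3, 4: 3}, 2, jrgeco_v1, cfg)
        for snip, n in zip(events.snippets, events.labels):
            if n > 0:
                assert snip.max() == pytest.approx(jrgeco_v1.amplitude(n), abs=1e-12)

    def test_reproducibility(self, jrgeco_v1):
        cfg = ImagingConfig(fs=30.0, noise_sd=0.02, seed=17)
        a, _ = generate_ap_event_dataset({1: 5, 2: 5}, 10, jrgeco_v1, cfg)
        b, _ = generate_ap_event_dataset({1: 5, 2: 5}, 10, jrgeco_v1, cfg)
        np.testing.assert_array_equal(a.snippets, b.snippets)


class TestDepthProfiles:
    def test_noiseless_recovery_to_machine_precision(self):
        from gecibench import fit_depth_profile

        profiles, lam = generate_depth_profiles(3, 100.0, np.arange(100, 501, 10), 0.0, 1)
        for p in profiles:
            assert fit_depth_profile(p).lambda_um == pytest.approx(100.0, rel=1e-9)

    def test_nonfinite_lambda_rejected(self):
        with pytest.raises(ValueError):
            generate_depth_profiles(3, np.inf, np.arange(100, 501, 10), 0.1, 1)


class TestScreenPlate:
    def test_structure_and_saturating_peak(self):
        kin = kinetics_preset("jRGECO1a", "culture")
        cfg = ImagingConfig(fs=35.0, noise_sd=0.0, seed=4)
        wells = generate_screen_plate([kin], 3, cfg, jitter_cv=0.0)
        assert len(wells) == 1
        w = wells[0]
        assert set(w.traces) == {1, 2, 3, 5, 10, 20, 40, 80, 160}
        block = w.traces[160]
        assert block.shape[0] == 3
        peak_dff = block[0].max() / cfg.f0 - 1.0
        assert peak_dff == pytest.approx(kin.amplitude(160), rel=1e-2)
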