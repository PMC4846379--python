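"""Event extraction, template projection, d', ROC and accuracy."""

import numpy as np
import pytest
from scipy import stats

from gecibench import (
    ImagingConfig,
    SpikeTrain,
    accuracy_at_fpr,
    analyze_events,
    build_unit_template,
    dprime,
    extract_events,
    generate_ap_event_dataset,
    project,
    roc_auc,
    roc_curve,
)
from gecibench.detection import ap_bin_width
from gecibench.synth import generate_ap_session
from gecibench.traceproc import Trace


def brute_force_census(times, indicator, isolation_s=1.0, max_ap=8):
    """Enumeration oracle for event grouping."""
    times = np.sort(np.asarray(times, float))
    census = {}
    # clusters by isolation gaps
    clusters, current = [], [times[0]]
    for t in times[1:]:
        if t - current[-1] > isolation_s:
            clusters.append(current)
            current = [t]
        else:
            current.append(t)
    clusters.append(current)
    for c in clusters:
        n = len(c)
        if n == 1:
            census[1] = census.get(1, 0) + 1
        elif n <= max_ap and (c[-1] - c[0]) <= ap_bin_width(indicator, n):
            census[n] = census.get(n, 0) + 1
    return census


class TestExtractEvents:
    def _flat_trace(self, duration, fs=30.0):
        return Trace(np.full(int(duration * fs), 100.0), fs=fs)

    def test_two_isolated_singles(self):
        spikes = SpikeTrain([1.0, 10.0], 20.0)
        evset = extract_events(spikes, self._flat_trace(20.0), "jRGECO1a")
        assert int((evset.labels == 1).sum()) == 2

    def test_two_spikes_within_bin_is_one_2ap_event(self):
        spikes = SpikeTrain([1.00, 1.05], 20.0)
        evset = extract_events(spikes, self._flat_trace(20.0), "jRGECO1a")
        assert int((evset.labels == 2).sum()) == 1
        assert int((evset.labels == 1).sum()) == 0

    def test_pair_wider_than_bin_discarded(self):
        spikes = SpikeTrain([1.0, 1.2], 20.0)  # 200 ms > the 100 ms 2-AP bin
        evset = extract_events(spikes, self._flat_trace(20.0), "jRGECO1a")
        assert not np.any(evset.labels >= 1)

    def test_census_matches_bruteforce_oracle(self):
        times = [2.0, 2.05, 5.0, 8.0, 8.04, 8.08, 12.0, 12.5, 16.0, 20.0, 20.3, 24.0]
        spikes = SpikeTrain(times, 30.0)
        evset = extract_events(spikes, self._flat_trace(30.0), "jRGECO1a")
        got = {n: int((evset.labels == n).sum()) for n in set(evset.labels) if n > 0}
        assert got == brute_force_census(times, "jRGECO1a")

    def test_noise_segment_count(self):
        """A spike-free recording yields floor(duration/4 s) noise bins."""
        spikes = SpikeTrain([], 41.0)
        evset = extract_events(spikes, self._flat_trace(41.0), "jRGECO1a")
        assert int((evset.labels == 0).sum()) == 10

    def test_event_near_edge_dropped(self):
        spikes = SpikeTrain([0.1], 20.0)  # 10 pre-frames do not fit
        evset = extract_events(spikes, self._flat_trace(20.0), "jRGECO1a")
        assert evset.n_dropped >= 1
        assert not np.any(evset.labels == 1)

    def test_end_to_end_on_generated_session(self, jrgeco_v1):
        plan = [1, 2, 1, 3, 1, 2]
        cfg = ImagingConfig(fs=30.0, noise_sd=0.005, seed=3)
        spikes, trace = generate_ap_session(plan, jrgeco_v1, cfg)
        evset = extract_events(spikes, trace, "jRGECO1a")
        for n in set(plan):
            assert int((evset.labels == n).sum()) == plan.count(n)


class TestTemplatesAndProjection:
    def test_single_event_template(self):
        unit = build_unit_template(np.array([[0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(unit, np.array([-1.0, 0.0, 1.0]) / np.sqrt(2))

    def test_duplicate_events_same_template(self, rng):
        e = rng.normal(size=12)
        np.testing.assert_allclose(
            build_unit_template(np.array([e])), build_unit_template(np.array([e, e]))
        )

    def test_constant_template_rejected(self):
        with pytest.raises(ValueError):
            build_unit_template(np.full((3, 8), 2.0))

    def test_loop_oracle(self, rng):
        events = rng.normal(size=(7, 20))
        unit = build_unit_template(events)
        mean = sum(events) / 7
        centered = mean - sum(mean) / 20
        expected = centered / np.sqrt(sum(centered**2))
        np.testing.assert_allclose(unit, expected, atol=1e-12)
        # projection equals the loop dot product of raw snippets
        scores = project(events, unit)
        for i in range(7):
            assert scores[i] == pytest.approx(
                sum(events[i][j] * unit[j] for j in range(20))
            )

    def test_projection_geometry(self):
        unit = build_unit_template(np.array([[0.0, 1.0, 2.0]]))
        # the mean-subtracted template projects onto its own norm
        assert project(np.array([[-1.0, 0.0, 1.0]]), unit)[0] == pytest.approx(np.sqrt(2))
        assert project(np.array([[1.0, 0.0, 1.0]]), unit)[0] == pytest.approx(0.0)


class TestDprime:
    def test_identical_distributions_near_zero(self, rng):
        s = rng.normal(size=10_000)
        n = rng.normal(size=10_000)
        se = np.sqrt(2.0 / 10_000)
        assert abs(dprime(s, n)) < 3 * se + 0.01

    def test_unit_gaussians_analytic(self, rng):
        s = rng.normal(1.0, 1.0, 100_000)
        n = rng.normal(0.0, 1.0, 100_000)
        assert dprime(s, n) == pytest.approx(1.0, abs=0.02)

    def test_affine_invariance(self, rng):
        s = rng.normal(2.0, 1.5, 500)
        n = rng.normal(0.0, 0.5, 500)
        d0 = dprime(s, n)
        assert dprime(10 * s, 10 * n) == pytest.approx(d0, rel=1e-12)
        assert dprime(3 * s + 7, 3 * n + 7) == pytest.approx(d0, rel=1e-12)

    def test_zero_variance_flagged_infinite(self):
        with pytest.warns(UserWarning):
            assert dprime([1.0, 1.0], [0.0, 0.0]) == np.inf


class TestRoc:
    def test_hand_enumerated_five_points(self):
        pts = roc_curve([3.0, 4.0], [1.0, 2.0])
        expected = np.array([[0, 0], [0, 0.5], [0, 1], [0.5, 1], [1, 1]], dtype=float)
        np.testing.assert_allclose(pts, expected)

    def test_perfect_separation_hits_corner(self, rng):
        pts = roc_curve(rng.normal(10, 0.1, 50), rng.normal(0, 0.1, 50))
        assert any(np.allclose(p, [0.0, 1.0]) for p in pts)

    def test_null_auc_near_half(self, rng):
        s = rng.normal(size=2000)
        n = rng.normal(size=2000)
        se = np.sqrt((2000 + 2000 + 1) / (12 * 2000 * 2000))
        assert roc_auc(s, n) == pytest.approx(0.5, abs=3 * se)

    def test_auc_equals_mannwhitney_u(self, rng):
        """Oracle identity: trapezoidal AUC == U / (n_s * n_n), with ties."""
        s = np.round(rng.normal(0.5, 1.0, 150), 1)  # rounding forces ties
        n = np.round(rng.normal(0.0, 1.0, 120), 1)
        u = stats.mannwhitneyu(s, n, alternative="two-sided").statistic
        assert roc_auc(s, n) == pytest.approx(u / (150 * 120), abs=1e-12)

    def test_monotone(self, rng):
        pts = roc_curve(rng.normal(1, 1, 200), rng.normal(0, 1, 200))
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)


class TestAccuracyAtFpr:
    def test_fully_separated(self, rng):
        assert accuracy_at_fpr(rng.normal(100, 1, 200), rng.normal(0, 1, 200), 0.05) == 1.0

    def test_chance_level(self, rng):
        s = rng.normal(size=50_000)
        n = rng.normal(size=50_000)
        assert accuracy_at_fpr(s, n, 0.05) == pytest.approx(0.05, abs=0.01)

    def test_gaussian_closed_form(self, rng):
        """d'=1 Gaussians at 5% FPR -> TPR = Phi(1 - z_0.95) ~ 0.26."""
        s = rng.normal(1.0, 1.0, 100_000)
        n = rng.normal(0.0, 1.0, 100_000)
        expected = stats.norm.cdf(1.0 - stats.norm.ppf(0.95))
        assert accuracy_at_fpr(s, n, 0.05) == pytest.approx(expected, abs=0.01)

    def test_few_noise_scores_warns(self, rng):
        with pytest.warns(UserWarning):
            accuracy_at_fpr(rng.normal(size=10), rng.normal(size=5), 0.05)


class TestEndToEnd:
    def test_dprime_increases_with_burst_size(self, jrgeco_v1):
        cfg = ImagingConfig(fs=30.0, noise_sd=0.02, seed=8)
        events, _ = generate_ap_event_dataset(
            {1: 60, 2: 60, 3: 60, 5: 60}, 120, jrgeco_v1, cfg
        )
        result = analyze_events(events)
        d = [result.dprimes[n] for n in [1, 2, 3, 5]]
        assert np.all(np.diff(d) > 0)

    def test_accuracy_increases_with_amplitude_over_noise(self, jrgeco_v1):
        accs = []
        for noise in [0.5, 0.2, 0.05]:
            cfg = ImagingConfig(fs=30.0, noise_sd=noise, seed=8)
            events, _ = generate_ap_event_dataset({1: 100}, 200, jrgeco_v1, cfg)
            accs.append(analyze_events(events).accuracy_at_fpr[1])
        assert accs[0] < accs[-1]
        assert np.all(np.diff(accs) >= 0)
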