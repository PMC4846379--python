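"""Trace correction and normalization against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gecibench import (
    CorrectionParams,
    Trace,
    check_eligibility,
    compute_dff,
    compute_f0,
    moving_average,
    neuropil_correct,
    unmix_channels,
)

finite = st.floats(-100.0, 100.0, allow_nan=False)


def _trace(values, fs=10.0):
    return Trace(np.asarray(values, dtype=float), fs=fs)


class TestNeuropilCorrect:
    def test_zero_neuropil(self):
        out = neuropil_correct(_trace(np.ones(5)), _trace(np.zeros(5)), CorrectionParams(0.7))
        np.testing.assert_array_equal(out.samples, np.ones(5))

    def test_exact_cancellation(self, rng):
        g = rng.normal(size=50)
        h = rng.normal(size=50)
        out = neuropil_correct(_trace(g + 0.7 * h), _trace(h), CorrectionParams(0.7))
        np.testing.assert_allclose(out.samples, g, atol=1e-12)

    def test_loop_oracle(self, rng):
        f = rng.normal(size=100)
        n = rng.normal(size=100)
        out = neuropil_correct(_trace(f), _trace(n), CorrectionParams(0.7))
        expected = np.array([f[i] - 0.7 * n[i] for i in range(100)])
        np.testing.assert_allclose(out.samples, expected, atol=0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            neuropil_correct(_trace(np.ones(5)), _trace(np.ones(6)), CorrectionParams())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        f=arrays(float, 20, elements=finite),
        g=arrays(float, 20, elements=finite),
        n=arrays(float, 20, elements=finite),
        m=arrays(float, 20, elements=finite),
        a=st.floats(-3, 3),
        b=st.floats(-3, 3),
    )
    def test_linearity(self, f, g, n, m, a, b):
        p = CorrectionParams(0.7)
        lhs = neuropil_correct(_trace(a * f + b * g), _trace(a * n + b * m), p).samples
        rhs = (
            a * neuropil_correct(_trace(f), _trace(n), p).samples
            + b * neuropil_correct(_trace(g), _trace(m), p).samples
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestEligibility:
    def test_margin_rule(self):
        base_np = np.full(20, 100.0)
        p = CorrectionParams(0.7, 0.03)
        ok, ratio = check_eligibility(_trace(base_np * 1.04), _trace(base_np), p, [(0, 2)])
        assert ok and ratio == pytest.approx(1.04)
        ok, _ = check_eligibility(_trace(base_np * 1.02), _trace(base_np), p, [(0, 2)])
        assert not ok

    def test_exclusion_fraction_matches_construction(self, rng):
        """Counting oracle: eligibility reproduces the planted baseline ratios."""
        p = CorrectionParams(0.7, 0.03)
        ratios = rng.uniform(0.95, 1.15, size=100)
        flags = []
        for r in ratios:
            f_np = np.full(30, 50.0)
            flags.append(
                check_eligibility(_trace(f_np * r), _trace(f_np), p, [(0, 3)])[0]
            )
        assert np.array_equal(np.array(flags), ratios > 1.03)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            check_eligibility(
                _trace(np.ones(5)), _trace(np.ones(5)), CorrectionParams(), [(10, 12)]
            )


class TestF0AndDff:
    def test_constant_trace(self):
        assert compute_f0(_trace(np.full(10, 2.0)), (0.0, 1.0)) == 2.0

    def test_window_mean(self):
        tr = _trace(np.arange(1.0, 11.0), fs=1.0)
        assert compute_f0(tr, (5.0, 10.0)) == pytest.approx(8.0)

    def test_loop_mean_oracle(self, rng):
        vals = rng.normal(size=40)
        tr = _trace(vals, fs=4.0)
        sl = slice(8, 24)
        assert compute_f0(tr, (2.0, 6.0)) == pytest.approx(
            sum(vals[sl]) / len(vals[sl])
        )

    def test_dff_arithmetic(self):
        tr = _trace([2.0, 3.0, 2.0])
        out = compute_dff(tr, 2.0)
        np.testing.assert_allclose(out.samples, [0.0, 0.5, 0.0])

    def test_dff_requires_positive_f0(self):
        with pytest.raises(ValueError):
            compute_dff(_trace(np.ones(3)), 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        vals=arrays(float, 15, elements=st.floats(0.5, 10.0)),
        c=st.floats(0.1, 50.0),
    )
    def test_dff_scale_invariance(self, vals, c):
        """ΔF/F0 is unchanged by a global rescaling of raw fluorescence."""
        f0 = float(vals[:5].mean())
        a = compute_dff(_trace(vals), f0).samples
        b = compute_dff(_trace(c * vals), c * f0).samples
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestMovingAverage:
    def test_identity_and_center(self):
        tr = _trace([0.0, 3.0, 0.0])
        np.testing.assert_array_equal(moving_average(tr, 1).samples, tr.samples)
        assert moving_average(tr, 3).samples[1] == pytest.approx(1.0)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            moving_average(_trace(np.ones(5)), 2)

    def test_loop_oracle_with_truncated_edges(self, rng):
        vals = rng.normal(size=30)
        got = moving_average(_trace(vals), 5).samples
        expected = np.array(
            [vals[max(0, i - 2):i + 3].mean() for i in range(30)]
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestUnmix:
    def test_identity_mixing(self, rng):
        r, g = rng.normal(size=20), rng.normal(size=20)
        out_r, out_g = unmix_channels(_trace(r), _trace(g), np.eye(2))
        np.testing.assert_allclose(out_r.samples, r)
        np.testing.assert_allclose(out_g.samples, g)

    def test_known_bleedthrough_recovered(self, rng):
        true_r, true_g = rng.normal(size=50), rng.normal(size=50)
        mix = np.array([[1.0, 0.0], [0.1, 1.0]])  # red bleeds into green
        meas = mix @ np.vstack([true_r, true_g])
        out_r, out_g = unmix_channels(_trace(meas[0]), _trace(meas[1]), mix)
        np.testing.assert_allclose(out_g.samples, true_g, atol=1e-12)

    def test_forward_inverse_roundtrip(self, rng):
        mix = np.array([[0.9, 0.2], [0.3, 1.1]])
        r, g = rng.normal(size=30), rng.normal(size=30)
        meas = mix @ np.vstack([r, g])
        out_r, out_g = unmix_channels(_trace(meas[0]), _trace(meas[1]), mix)
        np.testing.assert_allclose(out_r.samples, r, atol=1e-12)
        np.testing.assert_allclose(out_g.samples, g, atol=1e-12)

    def test_singular_matrix(self):
        with pytest.raises(ValueError):
            unmix_channels(
                _trace(np.ones(3)), _trace(np.ones(3)), np.ones((2, 2))
            )
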