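"""Reconvolution model, residual diagnostics and global lifetime analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcspcmcr as tm
from tcspcmcr.axes import ExponentialModel, InstrumentResponse
from tcspcmcr.fitting import (
    autocorrelation_outlier_fraction,
    reconvolution_basis,
    residual_autocorrelation,
    weighted_residuals,
)

from conftest import simulate_group, single_species


def brute_force_reconvolve(irf_counts, model, bin_width):
    """O(n^2) direct discrete convolution, the independent oracle."""
    n = irf_counts.size
    h = irf_counts / irf_counts.sum()
    t = np.arange(n) * bin_width
    decay = model.evaluate(t)
    out = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for j in range(k + 1):
            acc += h[j] * decay[k - j]
        out[k] = acc
    return out


class TestReconvolve:
    def test_delta_irf_identity(self, delta_irf, axis):
        model = ExponentialModel(np.array([1000.0]), np.array([1.0]))
        out = tm.reconvolve(delta_irf, model)
        t = np.arange(axis.n_bins) * axis.bin_width
        np.testing.assert_allclose(out, 1000.0 * np.exp(-t), rtol=1e-12)

    def test_linearity_in_terms(self, irf):
        m1 = ExponentialModel(np.array([300.0]), np.array([0.4]))
        m2 = ExponentialModel(np.array([700.0]), np.array([2.2]))
        combined = m1.combine(m2)
        lhs = tm.reconvolve(irf, m1) + tm.reconvolve(irf, m2)
        np.testing.assert_allclose(lhs, tm.reconvolve(irf, combined), rtol=1e-10,
                                   atol=1e-12)

    def test_matches_brute_force_oracle_short_lifetime(self, irf, axis):
        model = ExponentialModel(np.array([1.0]), np.array([0.03]))
        fast = tm.reconvolve(irf, model)
        slow = brute_force_reconvolve(irf.counts, model, axis.bin_width)
        np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-300)

    def test_too_short_lifetime_rejected(self, irf, axis):
        model = ExponentialModel(np.array([1.0]), np.array([axis.bin_width / 200]))
        with pytest.raises(ValueError, match="ill-conditioned"):
            tm.reconvolve(irf, model)

    @settings(deadline=None, max_examples=25)
    @given(
        tau=st.lists(st.floats(0.05, 4.0), min_size=1, max_size=3),
        shift=st.floats(-0.04, 0.04),
    )
    def test_output_nonnegative_and_right_length(self, irf, tau, shift):
        model = ExponentialModel(np.ones(len(tau)), np.array(tau))
        out = tm.reconvolve(irf, model, shift=shift)
        assert out.shape == (irf.axis.n_bins,)
        assert np.all(out >= 0)


class TestWeightedResiduals:
    def test_exact_fit_gives_zeros(self):
        c = np.array([10.0, 50.0, 100.0])
        np.testing.assert_array_equal(weighted_residuals(c, c), np.zeros(3))

    def test_direct_substitution(self):
        r = weighted_residuals(np.array([100.0]), np.array([90.0]))
        assert r[0] == pytest.approx(1.0)

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            weighted_residuals(np.zeros(5), np.zeros(5))

    def test_poisson_residual_variance_near_unity(self, irf, control_species):
        from tcspcmcr.synthetic import expected_curve

        mu = expected_curve([(control_species, 1.0)], irf, 30_000)
        rng = np.random.default_rng(11)
        keep = mu >= 100  # window where the Neyman weight is nearly unbiased
        assert keep.sum() >= 300
        variances = []
        for _ in range(5):
            counts = rng.poisson(mu)
            r = weighted_residuals(counts[keep].astype(float), mu[keep])
            variances.append(r.var())
        assert 0.9 <= np.mean(variances) <= 1.1


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        acf, _ = residual_autocorrelation(rng.normal(size=200))
        assert acf[0] == pytest.approx(1.0)

    def test_alternating_signs_give_minus_one_at_lag_one(self):
        r = np.tile([1.0, -1.0], 50)
        acf, _ = residual_autocorrelation(r)
        # finite-sample value is -(N-1)/N
        assert acf[1] == pytest.approx(-1.0, abs=2.0 / r.size)

    def test_white_noise_mostly_inside_band(self):
        rng = np.random.default_rng(42)
        fractions = []
        for _ in range(100):
            fractions.append(
                autocorrelation_outlier_fraction(rng.normal(size=500))
            )
        assert np.mean(fractions) <= 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            residual_autocorrelation(np.ones(100))
        with pytest.raises(ValueError):
            residual_autocorrelation(np.arange(10.0))


class TestAverageLifetime:
    def test_published_parameter_sets(self):
        # open form of a short beacon at neutral pH
        assert tm.average_lifetime(
            [2.34, 1.11, 0.35], [38.17, 44.09, 17.75]
        ) == pytest.approx(1.45, abs=0.02)
        # folded i-motif regime at pH 4: dominant 30 ps quenched term
        assert tm.average_lifetime(
            [3.01, 0.88, 0.18, 0.03], [1.75, 2.59, 7.93, 87.73]
        ) == pytest.approx(0.11, abs=0.02)

    def test_single_term_identity(self):
        assert tm.average_lifetime([0.72], [100.0]) == pytest.approx(0.72)

    @settings(deadline=None, max_examples=25)
    @given(st.permutations(range(4)))
    def test_permutation_invariance(self, perm):
        tau = np.array([3.01, 0.88, 0.18, 0.03])
        amp = np.array([1.75, 2.59, 7.93, 87.73])
        idx = np.array(perm)
        assert tm.average_lifetime(tau[idx], amp[idx]) == pytest.approx(
            tm.average_lifetime(tau, amp)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.average_lifetime([1.0, 2.0], [100.0])
        with pytest.raises(ValueError):
            tm.average_lifetime([1.0], [90.0])


class TestGlobalFit:
    def test_noiseless_two_term_exact_recovery(self, delta_irf):
        model = ExponentialModel(np.array([500.0, 500.0]), np.array([3.0, 0.5]))
        mu = tm.reconvolve(delta_irf, model)
        trace = tm.DecayTrace(axis=delta_irf.axis, counts=mu)
        res = tm.global_fit([trace], delta_irf, 2)
        np.testing.assert_allclose(res.lifetimes, [3.0, 0.5], rtol=1e-6)
        np.testing.assert_allclose(res.amplitudes[0], [500.0, 500.0], rtol=1e-5)
        assert res.chi2_reduced < 1e-12

    def test_noiseless_recovery_through_gaussian_irf(self, irf):
        model = ExponentialModel(np.array([200.0, 800.0]), np.array([2.4, 0.3]))
        mu = tm.reconvolve(irf, model)
        trace = tm.DecayTrace(axis=irf.axis, counts=mu)
        res = tm.global_fit([trace], irf, 2)
        np.testing.assert_allclose(res.lifetimes, [2.4, 0.3], rtol=1e-6)
        assert abs(res.shift) < 1e-6

    def test_fractional_amplitudes_sum_to_100(self, irf, acidic_species):
        traces = simulate_group(acidic_species, irf, n_traces=3, seed=2)
        res = tm.global_fit(traces, irf, 4)
        np.testing.assert_allclose(
            res.fractional_amplitudes.sum(axis=1), 100.0, atol=1e-9
        )

    def test_mismatched_axes_rejected(self, irf, acidic_species):
        other_axis = tm.make_axis(n_bins=400)
        bad = tm.DecayTrace(axis=other_axis, counts=np.ones(400, dtype=int))
        good = simulate_group(acidic_species, irf, n_traces=1)[0]
        with pytest.raises(ValueError, match="share one time axis"):
            tm.GlobalDecayModel([good, bad], irf, 2)

    def test_summary_mentions_key_diagnostics(self, irf, control_species):
        traces = simulate_group(control_species, irf, n_traces=2, seed=1, ph=7.0)
        res = tm.global_fit(traces, irf, 3)
        text = res.summary()
        assert "chi2_reduced" in text and "tau_bar" in text


class TestModelOrderSelection:
    def test_noiseless_single_exponential_selects_one(self, irf):
        model = ExponentialModel(np.array([1000.0]), np.array([1.5]))
        mu = tm.reconvolve(irf, model)
        trace = tm.DecayTrace(axis=irf.axis, counts=mu)
        sel = tm.select_model_order([trace], irf, max_terms=3)
        assert sel.order == 1 and sel.satisfied

    def test_diagnostics_are_auditable(self, irf, control_species):
        traces = simulate_group(control_species, irf, n_traces=3, seed=0, ph=7.0)
        sel = tm.select_model_order(traces, irf, max_terms=3)
        assert set(sel.chi2_by_order) == set(sel.outlier_fraction_by_order)
        assert sel.order in sel.results_by_order
        assert "selected order" in sel.summary()
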