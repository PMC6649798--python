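"""Rank estimation, EFA initialization and MCR-ALS resolution."""

import numpy as np
import pytest

import tcspcmcr as tm
from tcspcmcr.matrix import DecayMatrix, RowMeta


def matrix_from(values, ph):
    values = np.asarray(values, dtype=float)
    axis = tm.make_axis(n_bins=values.shape[1])
    meta = tuple(RowMeta("s", p, 560.0) for p in ph)
    return DecayMatrix(values=values, row_meta=meta, axis=axis)


@pytest.fixture(scope="module")
def short_noisy(irf):
    scenario = tm.preset_scenario("short_sequence", seed=1)
    return tm.build_matrix(tm.simulate_ph_series(scenario, irf))


class TestDiagnostics:
    def test_lack_of_fit_trivial_cases(self):
        D = np.array([[3.0, 4.0]])
        assert tm.lack_of_fit(D, D) == 0.0
        assert tm.lack_of_fit(D, np.zeros((1, 2))) == pytest.approx(100.0)

    def test_lof_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(0)
        D = rng.random((5, 5))
        Dh = rng.random((5, 5))
        manual = 0.0
        denom = 0.0
        for i in range(5):
            for j in range(5):
                manual += (D[i, j] - Dh[i, j]) ** 2
                denom += D[i, j] ** 2
        assert tm.lack_of_fit(D, Dh) == pytest.approx(100 * np.sqrt(manual / denom))

    def test_r2_trivial_cases(self):
        D = np.array([[3.0, 4.0]])
        assert tm.explained_r2(D, D) == 1.0
        assert tm.explained_r2(D, np.zeros((1, 2))) == 0.0

    def test_pythagoras_for_least_squares_reconstruction(self):
        rng = np.random.default_rng(1)
        D = rng.random((10, 8))
        U, sv, Vt = np.linalg.svd(D, full_matrices=False)
        Dh = (U[:, :3] * sv[:3]) @ Vt[:3]
        lof = tm.lack_of_fit(D, Dh)
        r2 = tm.explained_r2(D, Dh)
        assert r2 + (lof / 100.0) ** 2 == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            tm.lack_of_fit(np.zeros((2, 2)), np.zeros((2, 2)))


class TestSvdRank:
    def test_rank_one_outer_product(self):
        D = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        rank, sv, _ = tm.svd_rank(D)
        assert rank == 1

    def test_noiseless_three_species(self, irf):
        scenario = tm.preset_scenario("short_sequence", seed=0)
        D = tm.build_matrix(tm.simulate_ph_series(scenario, irf, noise=False))
        rank, sv, details = tm.svd_rank(D)
        assert rank == 3 and details["noiseless"]

    def test_noisy_two_species_across_seeds(self, irf):
        hits = 0
        for seed in range(10):
            scenario = tm.preset_scenario("long_sequence", seed=seed)
            D = tm.build_matrix(tm.simulate_ph_series(scenario, irf))
            rank, _, _ = tm.svd_rank(D)
            hits += rank == 2
        assert hits >= 9


class TestEFA:
    def test_one_species_window_spans_all_rows(self, irf):
        scenario = tm.preset_scenario("control", seed=0)
        D = tm.build_matrix(tm.simulate_ph_series(scenario, irf))
        result = tm.efa(D, 1)
        assert np.all(result.c_init[:, 0] > 0)

    def test_two_species_windows_cross_at_transition(self, irf):
        """Sequential two-species design: the acidic window fades toward
        neutral pH while the open-form window grows, crossing where the
        logistic transition sits (between pH 6 and 7)."""
        scenario = tm.preset_scenario("long_sequence", seed=0)
        D = tm.build_matrix(tm.simulate_ph_series(scenario, irf, noise=False))
        result = tm.efa(D, 2)
        ph = np.array([m.ph for m in D.row_meta])
        folded, open_ = result.c_init[:, 0], result.c_init[:, 1]
        assert np.all(folded[ph == 4] > 0) and np.all(open_[ph == 7] > 0)
        assert folded[ph == 7].max() <= folded[ph == 4].min()
        crossings = np.sign(folded - open_)
        assert crossings[ph == 4][0] > 0 and crossings[ph == 7][0] < 0

    def test_c_init_nonnegative(self, short_noisy):
        assert np.all(tm.efa(short_noisy, 3).c_init >= 0)

    def test_p_exceeding_rows_rejected(self, short_noisy):
        with pytest.raises(ValueError):
            tm.efa(short_noisy, short_noisy.shape[0] + 1)


class TestMCRALS:
    def test_exact_bilinear_recovery(self):
        """Noiseless bilinear data with clean concentration windows."""
        t = np.linspace(0, 12.5, 200)
        S_true = np.vstack([np.exp(-t / 0.2), np.exp(-t / 2.0)])
        C_true = np.array(
            [[1.0, 0.0], [1.0, 0.0], [0.7, 0.3], [0.3, 0.7], [0.0, 1.0], [0.0, 1.0]]
        ) * 1000
        D = matrix_from(C_true @ S_true, ph=[4, 4, 5, 6, 7, 7])
        res = tm.mcr_als(D, n_components=2)
        assert res.lof < 0.1
        for j, true in enumerate(S_true):
            corr = max(np.corrcoef(res.S[k], true)[0, 1] for k in range(2))
            assert corr > 0.999

    def test_lof_non_increasing(self, short_noisy):
        res = tm.mcr_als(short_noisy, n_components=3)
        diffs = np.diff(res.lof_history)
        assert np.all(diffs <= 1e-9)

    def test_scale_of_c_init_is_irrelevant(self, short_noisy):
        a = tm.mcr_als(short_noisy, c_init=tm.efa(short_noisy, 2).c_init)
        b = tm.mcr_als(short_noisy, c_init=tm.efa(short_noisy, 2).c_init * 37.0)
        np.testing.assert_allclose(a.S, b.S, atol=1e-6)
        np.testing.assert_allclose(a.C, b.C, rtol=1e-4, atol=1e-6)

    def test_factors_nonnegative_and_unit_max(self, short_noisy):
        res = tm.mcr_als(short_noisy, n_components=3)
        assert np.all(res.C >= 0) and np.all(res.S >= 0)
        np.testing.assert_allclose(res.S.max(axis=1), 1.0, atol=1e-12)

    def test_components_ordered_most_acidic_first(self, short_noisy):
        res = tm.mcr_als(short_noisy, n_components=3)
        dom = res.dominant_ph()
        assert list(dom) == sorted(dom)

    def test_empty_component_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        base = np.outer(rng.random(6) + 0.5, rng.random(40) + 0.5)
        D = matrix_from(base, ph=[4, 4, 5, 6, 7, 7])
        c_init = np.column_stack([np.ones(6), np.zeros(6)])
        with pytest.warns(RuntimeWarning, match="empty MCR component"):
            res = tm.mcr_als(D, c_init=c_init)
        assert res.n_components == 1

    def test_autoscaled_input_rejected(self, short_noisy):
        with pytest.raises(ValueError, match="raw counts"):
            tm.MCRALS(tm.autoscale(short_noisy), n_components=2)

    def test_summary_reports_fit_quality(self, short_noisy):
        res = tm.mcr_als(short_noisy, n_components=3)
        text = res.summary()
        assert "LOF" in text and "components" in text
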