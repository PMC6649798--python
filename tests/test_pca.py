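"""PCA of autoscaled decay matrices: oracle equivalence and clustering."""

import numpy as np
import pytest
from scipy import linalg

import tcspcmcr as tm
from tcspcmcr.matrix import DecayMatrix, RowMeta


def matrix_from(values, ph=None, seq=None):
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    axis = tm.make_axis(n_bins=values.shape[1])
    meta = tuple(
        RowMeta((seq or ["s"] * m)[i], (ph or list(range(m)))[i], 560.0)
        for i in range(m)
    )
    return DecayMatrix(values=values, row_meta=meta, axis=axis)


@pytest.fixture(scope="module")
def noisy_matrix():
    rng = np.random.default_rng(7)
    base = rng.random((12, 30))
    return tm.autoscale(matrix_from(base))


class TestFitPCA:
    def test_requires_autoscaled_input(self):
        D = matrix_from(np.random.default_rng(0).random((4, 6)))
        with pytest.raises(ValueError, match="autoscale"):
            tm.fit_pca(D, 2)

    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.linspace(1, 2, 8)
        D = matrix_from(np.outer(u, v))
        Z = tm.autoscale(D, ddof=0)
        model = tm.fit_pca(Z, 2)
        assert model.explained_variance[0] == pytest.approx(100.0, abs=1e-8)
        assert model.singular_values[1] < 1e-8 * model.singular_values[0]

    def test_matches_svd_oracle(self, noisy_matrix):
        model = tm.fit_pca(noisy_matrix, 4)
        U, sv, Vt = linalg.svd(noisy_matrix.values, full_matrices=False)
        # align oracle signs to the model's convention before comparing
        for k in range(4):
            j = np.argmax(np.abs(Vt[k]))
            if Vt[k, j] < 0:
                Vt[k] = -Vt[k]
                U[:, k] = -U[:, k]
        np.testing.assert_allclose(model.loadings, Vt[:4], atol=1e-8)
        np.testing.assert_allclose(model.scores, U[:, :4] * sv[:4], atol=1e-8)
        # scores are the projection of the data on the loadings
        np.testing.assert_allclose(
            model.scores, noisy_matrix.values @ model.loadings.T, atol=1e-8
        )

    def test_matches_sklearn_explained_variance(self, noisy_matrix):
        sklearn_decomposition = pytest.importorskip("sklearn.decomposition")
        model = tm.fit_pca(noisy_matrix, 3)
        # sklearn re-centres internally; the autoscaled matrix is already
        # centred so the ratios agree
        skl = sklearn_decomposition.PCA(n_components=3).fit(noisy_matrix.values)
        np.testing.assert_allclose(
            model.explained_variance / 100.0,
            skl.explained_variance_ratio_,
            rtol=1e-8,
        )

    def test_loadings_orthonormal_and_variance_ordered(self, noisy_matrix):
        model = tm.fit_pca(noisy_matrix, 5)
        np.testing.assert_allclose(
            model.loadings @ model.loadings.T, np.eye(5), atol=1e-8
        )
        assert np.all(np.diff(model.explained_variance) <= 1e-12)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-6)

    def test_full_rank_variance_sums_to_100(self, noisy_matrix):
        s = min(noisy_matrix.shape)
        model = tm.fit_pca(noisy_matrix, s)
        assert model.cumulative_variance()[-1] == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction_improves_with_components(self, noisy_matrix):
        errs = []
        for s in (1, 3, 5):
            model = tm.fit_pca(noisy_matrix, s)
            errs.append(np.linalg.norm(noisy_matrix.values - model.reconstruct()))
        assert errs[0] > errs[1] > errs[2]

    def test_noiseless_two_species_needs_two_components(self, irf):
        scenario = tm.preset_scenario("long_sequence", seed=0)
        traces = tm.simulate_ph_series(scenario, irf, noise=False)
        Z = tm.autoscale(tm.build_matrix(traces))
        model = tm.fit_pca(Z, 2)
        assert model.cumulative_variance()[-1] >= 99.9

    def test_component_count_out_of_range(self, noisy_matrix):
        with pytest.raises(ValueError):
            tm.fit_pca(noisy_matrix, 0)
        with pytest.raises(ValueError):
            tm.fit_pca(noisy_matrix, 100)


class TestLocalPCA:
    def test_filter_cardinality(self, irf):
        scenario = tm.preset_scenario("short_sequence", seed=1)
        D = tm.build_matrix(tm.simulate_ph_series(scenario, irf))
        sub = D.select_rows(lambda m: m.ph <= 6)
        assert sub.shape[0] == 21

    def test_all_rows_filter_equals_global_fit(self, irf):
        scenario = tm.preset_scenario("long_sequence", seed=2)
        D = tm.build_matrix(tm.simulate_ph_series(scenario, irf))
        local = tm.local_pca(D, lambda m: True, 2)
        global_ = tm.fit_pca(tm.autoscale(D), 2)
        np.testing.assert_allclose(local.scores, global_.scores, atol=1e-8)

    def test_too_few_rows_rejected(self, irf):
        scenario = tm.preset_scenario("control", seed=0)
        D = tm.build_matrix(tm.simulate_ph_series(scenario, irf))
        with pytest.raises(ValueError):
            tm.local_pca(D, lambda m: m.wavelength < 0, 1)

    def test_acidic_scores_separate_presets(self, irf):
        """Short (3-species) and long (2-species) series cluster apart at
        acidic pH, as expected when the folded-state heterogeneity differs."""
        from sklearn.metrics import silhouette_score

        short = tm.simulate_ph_series(tm.preset_scenario("short_sequence", seed=4), irf)
        long_ = tm.simulate_ph_series(tm.preset_scenario("long_sequence", seed=4), irf)
        D = tm.build_matrix(short + long_)
        model = tm.local_pca(D, lambda m: m.ph <= 6, 2)
        labels = [m.sequence_id for m in model.row_meta]
        assert silhouette_score(model.scores[:, :2], labels) > 0
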