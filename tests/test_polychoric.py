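"""Threshold, polychoric and polyserial estimation against simulation and
brute-force likelihood oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr, ndtri

import phenofactor as pf
from phenofactor._bvn import cell_probabilities
from phenofactor.exceptions import DataError, DegeneratePredictorError
from phenofactor.polychoric import smooth_correlation_matrix


class TestThresholds:
    def test_median_split(self):
        x = np.array([0] * 50 + [1] * 50, dtype=float)
        tau = pf.estimate_thresholds(x)
        assert tau == pytest.approx([0.0], abs=1e-12)

    def test_phi_unit_gaps(self):
        # proportions Phi(-1), Phi(1)-Phi(-1), 1-Phi(1)
        n = 100_000
        counts = np.round(n * np.array([ndtr(-1), ndtr(1) - ndtr(-1),
                                        1 - ndtr(1)])).astype(int)
        x = np.repeat([0.0, 1.0, 2.0], counts)
        tau = pf.estimate_thresholds(x)
        assert tau == pytest.approx([-1.0, 1.0], abs=2e-3)

    def test_recovery_from_discretised_normal(self):
        cut = np.array([-0.5, 0.4, 1.2])
        n = 100_000
        z = np.random.default_rng(31).standard_normal(n)
        x = np.digitize(z, cut).astype(float)
        tau = pf.estimate_thresholds(x)
        # 3 SE of an inverse-CDF-transformed proportion
        for t, c in zip(tau, cut):
            p = ndtr(c)
            se = np.sqrt(p * (1 - p) / n) / np.exp(-c * c / 2) * np.sqrt(2 * np.pi)
            assert abs(t - c) < 3 * se

    @given(st.lists(st.integers(0, 3), min_size=30, max_size=200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_inverse_cdf_reconstruction(self, values):
        """Phi gaps of the estimated thresholds reproduce the observed
        marginal proportions to machine precision."""
        x = np.asarray(values, dtype=float)
        if np.unique(x).size < 2:
            return
        tau = pf.estimate_thresholds(x)
        rec = np.diff(np.concatenate(([0.0], ndtr(tau), [1.0])))
        _, counts = np.unique(x, return_counts=True)
        np.testing.assert_allclose(rec, counts / x.size, atol=1e-10)

    def test_empty_category_collapses_with_warning(self, caplog):
        x = np.array([0.0] * 20 + [3.0] * 30)  # declared 4 categories, 2 seen
        with caplog.at_level("WARNING"):
            tau = pf.estimate_thresholds(x, n_categories=4)
        assert tau.size == 1
        assert "collapsed" in caplog.text

    def test_single_category_rejected(self):
        with pytest.raises(DataError):
            pf.estimate_thresholds(np.zeros(50))


def _discretise_bivariate(rho, tau_x, tau_y, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    return (np.digitize(z[:, 0], tau_x).astype(float),
            np.digitize(z[:, 1], tau_y).astype(float))


class TestPolychoric:
    def test_identical_vectors_hit_clip_boundary(self):
        x = np.array([0, 1, 2, 3] * 10, dtype=float)
        rho, _ = pf.polychoric_corr(x, x.copy())
        assert rho > 0.998

    def test_independent_variables(self):
        x, y = _discretise_bivariate(0.0, [-0.5, 0.5], [0.0], 100_000, 32)
        rho, avar = pf.polychoric_corr(x, y)
        assert abs(rho) < 3 * np.sqrt(avar)

    def test_recovers_known_correlation(self):
        x, y = _discretise_bivariate(0.5, [-0.8, 0.0, 0.9],
                                     [-0.5, 0.4, 1.2], 100_000, 33)
        rho, avar = pf.polychoric_corr(x, y)
        assert abs(rho - 0.5) < 3 * np.sqrt(avar)

    def test_symmetric_in_arguments(self):
        x, y = _discretise_bivariate(0.35, [-0.3, 0.6], [0.1], 2000, 34)
        r1, _ = pf.polychoric_corr(x, y)
        r2, _ = pf.polychoric_corr(y, x)
        assert r1 == pytest.approx(r2, abs=1e-7)

    def test_matches_tetrachoric_grid_search(self):
        """On a 2x2 table the two-step estimate equals the brute-force
        maximiser of the bivariate-normal cell likelihood over a fine
        rho grid with thresholds fixed at the margins."""
        x, y = _discretise_bivariate(0.4, [0.2], [-0.3], 3000, 35)
        rho, _ = pf.polychoric_corr(x, y)
        tau_x = pf.estimate_thresholds(x)
        tau_y = pf.estimate_thresholds(y)
        table = np.histogram2d(x, y, bins=[[-.5, .5, 1.5]] * 2)[0]
        grid = np.linspace(-0.99, 0.99, 3961)
        ll = [np.sum(table * np.log(np.maximum(
            cell_probabilities(tau_x, tau_y, r), 1e-300))) for r in grid]
        brute = grid[int(np.argmax(ll))]
        assert rho == pytest.approx(brute, abs=2 * (grid[1] - grid[0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            pf.polychoric_corr(np.array([0.0, 1.0] * 3), np.array([1.0, 0.0] * 3))


class TestPolyserial:
    def test_recovers_latent_correlation(self):
        n = 100_000
        rng = np.random.default_rng(36)
        g = rng.binomial(2, 0.3, n).astype(float)
        z = (g - g.mean()) / g.std()
        latent = 0.3 * z + np.sqrt(1 - 0.09) * rng.standard_normal(n)
        x = np.digitize(latent, [-0.5, 0.6, 1.4]).astype(float)
        rho, avar = pf.polyserial_corr(x, g)
        assert abs(rho - 0.3) < 3 * np.sqrt(avar) + 0.005

    def test_independent_pair(self):
        rng = np.random.default_rng(37)
        g = rng.binomial(2, 0.3, 50_000).astype(float)
        x = np.digitize(rng.standard_normal(50_000), [-0.5, 0.8]).astype(float)
        rho, avar = pf.polyserial_corr(x, g)
        assert abs(rho) < 3 * np.sqrt(avar)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            pf.polyserial_corr(np.array([0.0, 1.0] * 10), np.ones(20))


class TestCorrelationStructure:
    def test_assemble_is_psd_and_unsmoothed_on_clean_data(self, default_pop):
        import dataclasses
        pop = dataclasses.replace(default_pop, n=500)
        g = pf.simulate_genotypes(500, 0.3, seed=38)
        items = pf.simulate_item_responses(pop, g, seed=39)
        stats = pf.assemble_correlation_structure(items, g)
        M = stats.full_matrix()
        assert not stats.smoothed
        assert np.linalg.eigvalsh(M)[0] > -1e-8
        np.testing.assert_allclose(M, M.T)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert np.all(np.abs(M) <= 1 + 1e-12)

    def test_smoothing_clips_indefinite_matrix(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R)[0] < 0
        S, did = smooth_correlation_matrix(R)
        assert did
        assert np.linalg.eigvalsh(S)[0] >= 0
        np.testing.assert_allclose(np.diag(S), 1.0)
        # a PSD matrix passes through untouched
        R2 = np.array([[1.0, 0.3], [0.3, 1.0]])
        S2, did2 = smooth_correlation_matrix(R2)
        assert not did2
        assert np.array_equal(R2, S2)

    def test_matrix_tsv_roundtrip_bit_exact(self, tmp_path, default_pop):
        import dataclasses
        pop = dataclasses.replace(default_pop, n=300)
        g = pf.simulate_genotypes(300, 0.3, seed=40)
        items = pf.simulate_item_responses(pop, g, seed=41)
        stats = pf.assemble_correlation_structure(items)
        path = tmp_path / "rho.tsv"
        stats.to_tsv(path)
        labels, M = pf.CorrelationStructure.matrix_from_tsv(path)
        assert labels == stats.labels
        assert np.array_equal(M, stats.full_matrix())
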