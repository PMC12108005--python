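"""Moment propagation for the projection error and variance factors."""

import numpy as np
import pytest

import paleopca as pp
from paleopca.errors import ValidationError
from paleopca.projection import ProjectionScores, gram_solve

from conftest import make_toy_model


class TestDiscrepancyMap:
    def test_fully_observed_mask_gives_exact_zero(self, model):
        dmap = pp.discrepancy_map(np.ones(model.n_loci, dtype=bool), model, p=2)
        assert np.all(dmap.a == 0.0)

    def test_matches_dense_algebra_oracle(self):
        toy = make_toy_model(d=4, q=3, seed=1)
        mask = np.array([True, True, False, False])
        dmap = pp.discrepancy_map(mask, toy, p=1)
        v_p = toy.eigenvectors[mask, :1]
        v_q = toy.eigenvectors[mask, 1:]
        expected = -np.linalg.inv(v_p.T @ v_p) @ v_p.T @ v_q
        np.testing.assert_allclose(dmap.a, expected, atol=1e-12)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_shape_contract(self, p):
        toy = make_toy_model(d=10, q=5, seed=7)
        rng = np.random.default_rng(0)
        mask = rng.random(10) < 0.6
        dmap = pp.discrepancy_map(mask, toy, p=p)
        assert dmap.shape == (p, 5 - p)

    def test_error_is_linear_in_trailing_scores(self):
        # a sample lying exactly in the model plane: tau_hat - tau = A tau_Q
        toy = make_toy_model(d=12, q=6, seed=9)
        rng = np.random.default_rng(10)
        tau = rng.standard_normal(6)
        x = toy.eigenvectors @ tau
        mask = np.ones(12, dtype=bool)
        mask[rng.permutation(12)[:5]] = False
        p = 2
        v_p = toy.eigenvectors[mask, :p]
        tau_hat = gram_solve(v_p, v_p.T @ x[mask])
        dmap = pp.discrepancy_map(mask, toy, p=p)
        np.testing.assert_allclose(tau_hat - tau[:p], -dmap.a @ tau[p:], atol=1e-10)


class TestPredictCovariance:
    def test_fully_observed_is_zero_matrix(self, model):
        sigma = pp.predict_covariance(np.ones(model.n_loci, dtype=bool), model)
        assert np.all(sigma == 0.0)

    def test_monte_carlo_propagation_oracle(self):
        # empirical covariance of A tau_Q over draws tau_Q ~ N(0, Lambda_Q)
        toy = make_toy_model(d=30, q=10, seed=3)
        rng = np.random.default_rng(12)
        mask = rng.random(30) < 0.5
        p = 2
        sigma = pp.predict_covariance(mask, toy, p=p)
        lam_q = toy.eigenvalues[p:]
        n = 100_000
        draws = rng.standard_normal((n, len(lam_q))) * np.sqrt(lam_q)
        disc = draws @ pp.discrepancy_map(mask, toy, p=p).a.T
        emp_mean = disc.mean(axis=0)
        emp_cov = np.cov(disc.T, ddof=1)
        se_mean = np.sqrt(np.diag(sigma) / n)
        assert np.all(np.abs(emp_mean) <= 3 * se_mean)
        se_cov = np.sqrt(
            (np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n
        )
        assert np.all(np.abs(emp_cov - sigma) <= 3 * se_cov)

    def test_constant_factor_scales_linearly(self, model):
        rng = np.random.default_rng(2)
        mask = rng.random(model.n_loci) < 0.3
        base = pp.predict_covariance(mask, model)
        doubled = pp.VarianceFactors(
            f_in=np.full(model.n_loci, 2.0),
            f_out=np.full(model.n_components, 2.0),
        )
        sigma2 = pp.predict_covariance(mask, model, factors=doubled)
        np.testing.assert_allclose(sigma2, 2.0 * base, rtol=1e-12)

    def test_unit_factors_change_nothing(self, model):
        rng = np.random.default_rng(2)
        mask = rng.random(model.n_loci) < 0.3
        ones = pp.VarianceFactors(
            f_in=np.ones(model.n_loci), f_out=np.ones(model.n_components)
        )
        np.testing.assert_array_equal(
            pp.predict_covariance(mask, model, factors=ones),
            pp.predict_covariance(mask, model),
        )

    def test_trace_grows_with_missingness(self, model):
        rng = np.random.default_rng(42)
        rates = (0.25, 0.5, 0.75, 0.9)
        traces = []
        for r in rates:
            t = [
                np.trace(
                    pp.predict_covariance(rng.random(model.n_loci) > r, model)
                )
                for _ in range(50)
            ]
            traces.append(np.mean(t))
        assert np.all(np.diff(traces) > 0)


class TestPredictEmbedding:
    def test_mean_is_the_estimate_itself(self):
        scores = ProjectionScores(
            scores=np.array([1.5, -2.0]), mask=np.ones(4, dtype=bool)
        )
        g = pp.predict_embedding(scores, np.eye(2))
        np.testing.assert_array_equal(g.mean, [1.5, -2.0])

    def test_zero_covariance_flags_point_mass(self):
        scores = ProjectionScores(scores=np.zeros(2), mask=np.ones(4, dtype=bool))
        g = pp.predict_embedding(scores, np.zeros((2, 2)))
        assert g.is_degenerate

    def test_non_psd_rejected(self):
        scores = ProjectionScores(scores=np.zeros(2), mask=np.ones(4, dtype=bool))
        with pytest.raises(ValidationError):
            pp.predict_embedding(scores, np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_density_peaks_at_mean(self):
        from scipy.stats import multivariate_normal

        g = pp.GaussianEmbedding(
            mean=np.array([0.3, -1.0]), cov=np.array([[2.0, 0.5], [0.5, 1.0]])
        )
        mvn = multivariate_normal(g.mean, g.cov)
        rng = np.random.default_rng(1)
        elsewhere = mvn.pdf(rng.normal(size=(100, 2)))
        assert np.all(mvn.pdf(g.mean) >= elsewhere)


class TestVarianceFactors:
    def test_reference_against_itself_is_unity(self, ref_panel, model):
        fac = pp.variance_factors(ref_panel, ref_panel, model)
        np.testing.assert_allclose(fac.f_in, 1.0, atol=1e-12)
        np.testing.assert_allclose(fac.f_out, 1.0, atol=1e-12)

    def test_projection_matches_dense_quadratic_form(self, model, pop_freqs, ref_panel):
        anc = pp.generate_ancient_like(pop_freqs, 40, seed=77)
        fac = pp.variance_factors(anc, ref_panel, model)
        v = model.eigenvectors
        dense = np.diag(v.T @ np.diag(fac.f_in) @ v)
        np.testing.assert_allclose(fac.f_out, dense, atol=1e-10)
        # convex combination of f_in: bounded by its extremes
        assert fac.f_out.min() >= fac.f_in.min() - 1e-12
        assert fac.f_out.max() <= fac.f_in.max() + 1e-12

    def test_pseudo_haploid_doubles_variance(self):
        # analytic ratio 4p(1-p) / 2p(1-p) = 2 under matching frequencies
        spec = pp.PanelSpec(
            n_loci=400, n_samples_per_population=50, fst=0.02, seed=21
        )
        panel = pp.generate_reference(spec)
        model = pp.fit_pca(panel)
        freqs = pp.reference_frequencies(spec)
        anc = pp.generate_ancient_like(freqs, 2000, seed=22)
        fac = pp.variance_factors(anc, panel, model)
        assert 1.9 <= fac.f_in.mean() <= 2.1

    def test_empty_panel_rejected(self, ref_panel, model):
        empty = pp.GenotypePanel(
            genotypes=np.empty((ref_panel.n_loci, 0), dtype=np.int8),
            locus_ids=ref_panel.locus_ids,
            sample_ids=[],
        )
        with pytest.raises(ValidationError):
            pp.variance_factors(empty, ref_panel, model)
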