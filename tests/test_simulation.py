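"""Downsampling experiments and the Gaussian KL divergence."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import paleopca as pp
from paleopca.errors import ValidationError


@pytest.fixture(scope="module")
def held_out_column(model, pop_freqs):
    held = pp.generate_diploid(pop_freqs, 1, seed=51)
    aligned, _ = pp.align_to_model(held, model)
    return aligned[:, 0]


class TestDownsample:
    def test_rate_zero_is_identity(self):
        sample = np.array([0, 1, 2, pp.MISSING, 2], dtype=np.int8)
        np.testing.assert_array_equal(pp.downsample(sample, 0.0, seed=1), sample)

    def test_exact_omission_count(self):
        rng = np.random.default_rng(0)
        sample = rng.integers(0, 3, size=100).astype(np.int8)
        out = pp.downsample(sample, 0.75, seed=3)
        assert (out != pp.MISSING).sum() == 25

    def test_previously_missing_entries_untouched(self):
        sample = np.array([pp.MISSING] * 10 + [2] * 10, dtype=np.int8)
        out = pp.downsample(sample, 0.5, seed=4)
        assert (out[:10] == pp.MISSING).all()
        assert (out[10:] != pp.MISSING).sum() == 5

    def test_deterministic_given_seed(self):
        sample = np.tile([0, 1, 2], 40).astype(np.int8)
        a = pp.downsample(sample, 0.5, seed=9)
        b = pp.downsample(sample, 0.5, seed=9)
        c = pp.downsample(sample, 0.5, seed=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("rate", [-0.1, 1.0, 1.5])
    def test_rate_out_of_range(self, rate):
        with pytest.raises(ValueError):
            pp.downsample(np.array([0, 1, 2]), rate, seed=0)


class TestKLGaussian:
    def g(self, mean, var):
        return pp.GaussianEmbedding(mean=np.atleast_1d(mean), cov=np.atleast_2d(var))

    def test_self_divergence_is_zero(self):
        g = pp.GaussianEmbedding(
            mean=np.array([1.0, 2.0]), cov=np.array([[2.0, 0.3], [0.3, 1.0]])
        )
        assert pp.kl_gaussian(g, g) == 0.0

    def test_against_numeric_integration(self):
        # KL(N(0,1) || N(0,2)) = 0.5 (ln 2 - 1/2) ~ 0.09657
        g1, g2 = self.g(0.0, 1.0), self.g(0.0, 2.0)
        val, _ = quad(
            lambda x: norm.pdf(x) * (norm.logpdf(x) - norm.logpdf(x, scale=np.sqrt(2))),
            -10,
            10,
        )
        assert pp.kl_gaussian(g1, g2) == pytest.approx(val, abs=1e-9)
        assert pp.kl_gaussian(g1, g2) == pytest.approx(0.096574, abs=1e-5)

    def test_asymmetry(self):
        g1, g2 = self.g(0.0, 1.0), self.g(0.0, 2.0)
        assert pp.kl_gaussian(g1, g2) != pp.kl_gaussian(g2, g1)

    def test_singular_covariance_rejected(self):
        g1 = self.g(0.0, 1.0)
        g0 = pp.GaussianEmbedding(mean=np.zeros(1), cov=np.zeros((1, 1)))
        with pytest.raises(ValidationError):
            pp.kl_gaussian(g1, g0)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.standard_normal((2, 2))
            b = rng.standard_normal((2, 2))
            g1 = pp.GaussianEmbedding(mean=rng.normal(size=2), cov=a @ a.T + 0.1 * np.eye(2))
            g2 = pp.GaussianEmbedding(mean=rng.normal(size=2), cov=b @ b.T + 0.1 * np.eye(2))
            assert pp.kl_gaussian(g1, g2) >= 0.0


class TestRunDownsampling:
    def test_rate_zero_discrepancies_exactly_zero(self, model, held_out_column):
        res = pp.run_downsampling(
            held_out_column, model, rates=(0.0,), n_reps=50, seed=1
        )[0]
        assert np.all(res.discrepancies == 0.0)
        assert res.n_reps == 50

    def test_bit_identical_for_identical_seed(self, model, held_out_column):
        kwargs = dict(rates=(0.5,), n_reps=200, seed=33)
        r1 = pp.run_downsampling(held_out_column, model, **kwargs)[0]
        r2 = pp.run_downsampling(held_out_column, model, **kwargs)[0]
        np.testing.assert_array_equal(r1.discrepancies, r2.discrepancies)
        assert r1.kl == r2.kl
        np.testing.assert_array_equal(r1.predicted.cov, r2.predicted.cov)

    def test_empirical_moments_use_sample_mean_and_nm1(self, model, held_out_column):
        res = pp.run_downsampling(
            held_out_column, model, rates=(0.5,), n_reps=300, seed=2
        )[0]
        d = res.discrepancies
        np.testing.assert_allclose(res.empirical.mean, d.mean(axis=0))
        np.testing.assert_allclose(res.empirical.cov, np.cov(d.T, ddof=1))
        assert res.kl >= 0.0

    def test_predicted_matches_single_mask_prediction(self, model, held_out_column):
        # averaged predicted covariance stays close to any one mask's
        res = pp.run_downsampling(
            held_out_column, model, rates=(0.75,), n_reps=100, seed=5
        )[0]
        rng = np.random.default_rng(0)
        obs = held_out_column != pp.MISSING
        k = int(np.rint(0.75 * obs.sum()))
        mask = obs.copy()
        mask[rng.permutation(np.flatnonzero(obs))[:k]] = False
        single = pp.predict_covariance(mask, model, p=2)
        assert np.linalg.norm(res.predicted.cov - single) < 0.25 * np.linalg.norm(single)

    def test_mismatched_length_rejected(self, model):
        with pytest.raises(IndexError):
            pp.run_downsampling(np.array([0, 1, 2]), model)


class TestSpreadSummary:
    def test_sd_increases_with_rate(self, model, held_out_column):
        results = pp.run_downsampling(
            held_out_column, model, rates=(0.25, 0.9), n_reps=1000, seed=8,
            sample_id="s",
        )
        table = pp.spread_summary(results)
        assert table["sd_monotone"].all()
        by_rate = table.pivot(index="rate", columns="component", values="sd")
        assert (by_rate.loc[0.9] > by_rate.loc[0.25]).all()
        # medians hover near zero relative to the spread
        norm_med = (table["median"].abs() / table["sd"]).max()
        assert norm_med < 0.1

    def test_zero_rate_yields_zero_spread(self, model, held_out_column):
        results = pp.run_downsampling(
            held_out_column, model, rates=(0.0, 0.5), n_reps=100, seed=9
        )
        table = pp.spread_summary(results)
        zero = table[table["rate"] == 0.0]
        assert (zero["sd"] == 0.0).all()
        assert (zero["median"] == 0.0).all()

    def test_single_rate_rejected(self, model, held_out_column):
        results = pp.run_downsampling(
            held_out_column, model, rates=(0.5,), n_reps=20, seed=10
        )
        with pytest.raises(ValidationError):
            pp.spread_summary(results)


class TestHarmonize:
    def test_common_observed_set(self):
        m = pp.MISSING
        panel = pp.GenotypePanel(
            genotypes=np.array([[0, 2], [m, 2], [2, m], [1, 2]]),
            locus_ids=[f"rs{i}" for i in range(4)],
            sample_ids=["a", "b"],
        )
        out = pp.harmonize_observed(panel)
        np.testing.assert_array_equal(out.observed.all(axis=1), [True, False, False, True])
        assert (out.genotypes[[1, 2]] == m).all()
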