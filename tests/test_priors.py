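"""Latent-trait prior structure: transforms, presets, prior draws."""

import numpy as np
import pytest
from scipy import stats

import ordtree as ot
from ordtree.priors import sample_lkj_cholesky


class TestProbit:
    def test_symmetry_point(self):
        assert ot.probit_inverse(0.0) == pytest.approx(0.5)

    def test_quantile_table_value(self):
        assert ot.probit_inverse(1.6449) == pytest.approx(0.95, abs=1e-4)

    def test_roundtrip(self):
        z = np.arange(-3.0, 3.5, 0.5)
        np.testing.assert_allclose(ot.probit(ot.probit_inverse(z)), z, atol=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ot.probit(1.0)


class TestPresets:
    def test_informative_assigns_by_parameter_type(self, htsm):
        prior = ot.informative_preset(htsm)
        assert prior.group_mean["g"].sd == pytest.approx(0.28)
        assert prior.group_mean["b"].sd == pytest.approx(0.28)
        assert prior.group_mean["D"].sd == pytest.approx(1.0)
        assert prior.group_mean["d"].sd == pytest.approx(1.0)
        assert isinstance(prior.deviation, ot.GammaSpec)
        assert prior.deviation.mean == pytest.approx(2.0 / 3.0)

    def test_untagged_parameter_rejected(self):
        model = ot.parse_eqn("T x q\nT y (1-q)")
        with pytest.raises(ValueError, match="overrides"):
            ot.informative_preset(model)
        prior = ot.informative_preset(model, overrides={"q": "guessing"})
        assert prior.group_mean["q"].sd == pytest.approx(0.28)

    def test_matzke_klauer_implies_uniform_group_theta(self, htsm):
        prior = ot.matzke_klauer_preset(htsm)
        draws = ot.draw_prior(prior, htsm, n_participants=1, n_draws=100_000, seed=0)
        ks = stats.kstest(draws.group_prob[:, draws.index("g")], "uniform")
        assert ks.pvalue > 0.01

    def test_informative_guessing_median_at_chance(self, htsm):
        prior = ot.informative_preset(htsm)
        draws = ot.draw_prior(prior, htsm, n_participants=1, n_draws=50_000, seed=1)
        summary = ot.group_prob_summary(draws, "g")
        assert summary["median"] == pytest.approx(0.5, abs=0.01)


class TestLkjSampler:
    def test_marginal_correlation_distribution(self):
        """Off-diagonal of LKJ(eta) in dim d is 2*Beta(a, a)-1 with a = eta+(d-2)/2."""
        rng = np.random.default_rng(5)
        for dim, eta in ((4, 1.0), (3, 2.0)):
            chol = sample_lkj_cholesky(40_000, dim, eta, rng)
            corr = chol @ np.swapaxes(chol, -1, -2)
            r = corr[:, 1, 0]
            a = eta + (dim - 2) / 2.0
            ks = stats.kstest((r + 1.0) / 2.0, stats.beta(a, a).cdf)
            assert ks.pvalue > 0.001

    def test_unit_diagonal_and_psd(self):
        rng = np.random.default_rng(0)
        chol = sample_lkj_cholesky(200, 6, 1.0, rng)
        corr = chol @ np.swapaxes(chol, -1, -2)
        np.testing.assert_allclose(np.einsum("npp->np", corr), 1.0, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(corr) > -1e-10)


class TestDrawPrior:
    def test_invariants(self, htsm):
        prior = ot.informative_preset(htsm)
        draws = ot.draw_prior(prior, htsm, n_participants=5, n_draws=500, seed=3)
        assert draws.group_mu.shape == (500, 4)
        assert draws.individual_probit.shape == (500, 5, 4)
        prob = draws.individual_prob
        assert np.all((prob > 0) & (prob < 1))
        np.testing.assert_allclose(
            prob, ot.probit_inverse(draws.individual_probit), atol=1e-12
        )
        np.testing.assert_allclose(np.einsum("npp->np", draws.corr), 1.0, atol=1e-9)

    def test_zero_deviation_collapses_hierarchy(self, htsm):
        prior = ot.PriorSpec(
            group_mean={p: ot.NormalSpec(0, 1) for p in htsm.parameters},
            deviation=ot.FixedSpec(0.0),
            correlation=ot.LKJSpec(1.0),
        )
        draws = ot.draw_prior(prior, htsm, n_participants=4, n_draws=100, seed=0)
        expected = ot.probit_inverse(draws.group_mu)[:, None, :]
        np.testing.assert_allclose(draws.individual_prob, np.broadcast_to(expected, (100, 4, 4)))

    def test_seed_determinism(self, htsm):
        prior = ot.informative_preset(htsm)
        a = ot.draw_prior(prior, htsm, 3, 200, seed=11)
        b = ot.draw_prior(prior, htsm, 3, 200, seed=11)
        np.testing.assert_array_equal(a.individual_probit, b.individual_probit)

    def test_hierarchy_variance_shrinks_with_deviation(self, htsm):
        base = ot.informative_preset(htsm)
        small = ot.priors.replace_deviation(base, ot.FixedSpec(0.01))
        large = ot.priors.replace_deviation(base, ot.FixedSpec(1.0))
        ds = ot.draw_prior(small, htsm, 50, 200, seed=2)
        dl = ot.draw_prior(large, htsm, 50, 200, seed=2)
        var_s = ds.individual_prob.var(axis=1).mean()
        var_l = dl.individual_prob.var(axis=1).mean()
        assert var_s < var_l / 100


class TestExtremeness:
    def test_uniform_band_mass(self):
        """Exact uniform individual draws put band mass 2*band near the extremes."""
        rng = np.random.default_rng(0)
        prob = rng.uniform(size=(2000, 50))
        probit = ot.probit(np.clip(prob, 1e-12, 1 - 1e-12))
        draws = ot.ParameterDraws(
            parameters=("q",),
            group_mu=np.zeros((2000, 1)),
            sigma=np.ones((2000, 1)),
            corr=np.ones((2000, 1, 1)),
            individual_probit=probit[:, :, None],
            provenance="prior",
        )
        idx = ot.extremeness_index(draws, "q", band=0.1)
        assert idx.value == pytest.approx(0.2, abs=3 * idx.se + 0.005)

    def test_point_mass_at_half_is_zero(self):
        draws = ot.ParameterDraws(
            parameters=("q",),
            group_mu=np.zeros((100, 1)),
            sigma=np.zeros((100, 1)),
            corr=np.ones((100, 1, 1)),
            individual_probit=np.zeros((100, 3, 1)),
            provenance="prior",
        )
        assert ot.extremeness_index(draws, "q").value == 0.0

    def test_preset_contrast_on_guessing_and_source_memory(self, htsm):
        """The default latent-trait priors pile individual-level mass near 0/1."""
        informative = ot.informative_preset(htsm)
        mk = ot.matzke_klauer_preset(htsm)
        di = ot.draw_prior(informative, htsm, 2, 30_000, seed=4)
        dm = ot.draw_prior(mk, htsm, 2, 30_000, seed=4)
        for p in ("g", "d"):
            a = ot.extremeness_index(di, p)
            b = ot.extremeness_index(dm, p)
            pooled = np.hypot(a.se, b.se)
            assert b.value - a.value > 3 * pooled


class TestGroupSummary:
    def test_degenerate_median(self):
        draws = ot.ParameterDraws(
            parameters=("q",),
            group_mu=np.zeros((50, 1)),
            sigma=np.zeros((50, 1)),
            corr=np.ones((50, 1, 1)),
            individual_probit=np.zeros((50, 1, 1)),
            provenance="prior",
        )
        s = ot.group_prob_summary(draws, "q")
        assert s["median"] == pytest.approx(0.5)
        assert s["mean"] == pytest.approx(0.5)

    def test_normal_cdf_median(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(0.5, 0.1, size=(20_000, 1))
        draws = ot.ParameterDraws(
            parameters=("q",),
            group_mu=mu,
            sigma=np.zeros((20_000, 1)),
            corr=np.ones((20_000, 1, 1)),
            individual_probit=mu[:, None, :],
            provenance="prior",
        )
        s = ot.group_prob_summary(draws, "q")
        assert s["median"] == pytest.approx(ot.probit_inverse(0.5), abs=0.01)
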