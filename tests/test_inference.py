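"""Likelihood oracles, posterior sampling correctness, diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats

import ordtree as ot
from tests.conftest import make_binomial_table


class TestLogLikelihood:
    def test_two_category_closed_form(self):
        model = ot.parse_eqn("T x p\nT y (1-p)")
        table = ot.FrequencyTable(
            participants=("a",), categories={"T": ("x", "y")}, counts={"T": np.array([[1, 1]])}
        )
        ll = ot.log_likelihood(model, {"p": 0.5}, table)
        assert ll[0] == pytest.approx(np.log(2 * 0.25))

    def test_zero_probability_category_is_minus_inf(self):
        model = ot.parse_eqn("T x p\nT y (1-p)")
        table = ot.FrequencyTable(
            participants=("a",), categories={"T": ("x", "y")}, counts={"T": np.array([[0, 2]])}
        )
        ll = ot.log_likelihood(model, {"p": 1.0}, table)
        assert ll[0] == -np.inf

    def test_brute_force_enumeration_oracle(self, htsm):
        """Sum item-level assignment probabilities for 3-item trees and compare."""
        theta = dict(D=0.5, d=0.5, b=0.5, g=0.5)
        probs = ot.category_probabilities(htsm, theta)
        counts = {
            "source_A": np.array([[2, 1, 0]]),
            "source_B": np.array([[0, 2, 1]]),
            "new": np.array([[1, 0, 2]]),
        }
        table = ot.FrequencyTable(
            participants=("a",),
            categories={t.name: t.categories for t in htsm.trees},
            counts=counts,
        )
        expected = 0.0
        for tree in htsm.trees:
            p = probs[tree.name]
            target = tuple(counts[tree.name][0])
            total = 0.0
            for assign in itertools.product(range(3), repeat=3):
                realized = tuple(assign.count(k) for k in range(3))
                if realized == target:
                    total += np.prod([p[a] for a in assign])
            expected += np.log(total)
        ll = ot.log_likelihood(htsm, theta, table)
        assert ll[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_multinomial(self, htsm, small_dataset):
        table, _ = small_dataset
        theta = np.full((table.n_participants, 4), 0.4)
        ll = ot.log_likelihood(htsm, theta, table)
        probs = ot.category_probabilities(htsm, dict(D=0.4, d=0.4, b=0.4, g=0.4))
        expected = np.zeros(table.n_participants)
        for tree in htsm.trees:
            n = table.items_per_tree[tree.name]
            expected += stats.multinomial.logpmf(
                table.counts[tree.name], n, probs[tree.name]
            )
        np.testing.assert_allclose(ll, expected, atol=1e-10)


class TestFitPosterior:
    def test_quadrature_oracle_no_hierarchy(self, binomial_toy):
        """Posterior mean of a 1-parameter model vs. deterministic quadrature."""
        model, prior = binomial_toy
        table = make_binomial_table(7, 10)
        fit = ot.fit_posterior(
            model, prior, table, ot.McmcSettings(draws=20_000, warmup=2_000, chains=2, seed=3)
        )
        post = fit.draws.group_prob[:, 0]

        def unnorm(p):
            return p**7 * (1 - p) ** 3  # uniform implied prior

        z, _ = integrate.quad(unnorm, 0, 1)
        mean_exact, _ = integrate.quad(lambda p: p * unnorm(p) / z, 0, 1)
        assert post.mean() == pytest.approx(mean_exact, abs=0.01)

    def test_empty_data_recovers_prior(self, htsm):
        """With zero trials the posterior must reproduce the prior (q-q slope 1)."""
        prior = ot.informative_preset(htsm)
        zero = {t.name: np.zeros((4, len(t.categories)), dtype=int) for t in htsm.trees}
        table = ot.FrequencyTable(
            participants=("a", "b", "c", "d"),
            categories={t.name: t.categories for t in htsm.trees},
            counts=zero,
        )
        fit = ot.fit_posterior(
            htsm, prior, table, ot.McmcSettings(draws=5_000, warmup=1_000, chains=2, seed=8)
        )
        prior_draws = ot.draw_prior(prior, htsm, 1, 10_000, seed=9)
        qs = np.linspace(0.05, 0.95, 19)
        for p in htsm.parameters:
            a = np.quantile(fit.draws.group_mu[:, fit.draws.index(p)], qs)
            b = np.quantile(prior_draws.group_mu[:, prior_draws.index(p)], qs)
            slope = np.polyfit(b, a, 1)[0]
            assert slope == pytest.approx(1.0, abs=0.05)

    def test_recovery_improves_with_sample_size(self, htsm):
        """Group-median RMSE decreases 25 -> 100 -> 400 participants (3-seed mean)."""
        design_items = {"source_A": 10, "source_B": 10, "new": 20}
        settings = dict(draws=600, warmup=500, chains=1)
        rmse = {}
        for n in (25, 100, 400):
            errs = []
            for seed in (0, 1, 2):
                design = ot.StudyDesign(items_per_tree=design_items, n_participants=n)
                table, truth = ot.generate_dataset(
                    htsm, design, ot.illustrative_truth(htsm), seed=100 + seed
                )
                fit = ot.fit_posterior(
                    htsm,
                    ot.informative_preset(htsm),
                    table,
                    ot.McmcSettings(seed=seed, **settings),
                )
                report = ot.recovery_report(fit, truth)
                errs.append(np.sqrt(np.mean(report["rmse"] ** 2)))
            rmse[n] = np.mean(errs)
        assert rmse[25] > rmse[100] > rmse[400]

    def test_seed_determinism(self, htsm, small_dataset):
        table, _ = small_dataset
        prior = ot.informative_preset(htsm)
        settings = ot.McmcSettings(draws=200, warmup=100, chains=1, seed=5)
        a = ot.fit_posterior(htsm, prior, table, settings)
        b = ot.fit_posterior(htsm, prior, table, settings)
        np.testing.assert_array_equal(a.draws.group_mu, b.draws.group_mu)


class TestDiagnostics:
    def test_table_shape_and_bounds(self, smoke_fit):
        frame = ot.diagnostics(smoke_fit)
        assert set(frame.columns) == {"rhat", "ess"}
        finite = frame["rhat"].dropna()
        assert (finite > 0.98).all()
        assert (frame["ess"].dropna() <= smoke_fit.n_draws + 1).all()

    def test_single_chain_flags_missing_rhat(self, htsm, small_dataset):
        table, _ = small_dataset
        fit = ot.fit_posterior(
            htsm,
            ot.informative_preset(htsm),
            table,
            ot.McmcSettings(draws=150, warmup=100, chains=1, seed=0),
        )
        assert any("single chain" in w for w in fit.warnings)
        assert all(np.isnan(v) for v in fit.rhat.values())
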