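"""Order/equality constraints and the two Bayes-factor identities."""

import numpy as np
import pytest
from scipy import stats

import ordtree as ot
from ordtree.bayesfactor import split_draw_segments
from ordtree.constraints import Inequality


@pytest.fixture(scope="module")
def bell_prior(bell_model):
    return ot.informative_preset(bell_model)


@pytest.fixture(scope="module")
def disordinal():
    return ot.ConstraintSpec.order(
        [
            "d_B_pleasant - d_A_pleasant > 0",
            "d_A_disgusting - d_B_disgusting > 0",
            "(d_B_pleasant - d_A_pleasant) > (d_A_disgusting - d_B_disgusting)",
        ]
    )


class TestEvaluateConstraint:
    def test_injected_values(self):
        cons = ot.ConstraintSpec.order(["q1 > 0", "q2 > 0", "q1 > q2"])
        values = {"q1": np.array([0.3, 0.1, -0.2]), "q2": np.array([0.1, 0.3, -0.5])}
        np.testing.assert_array_equal(
            ot.evaluate_constraint(cons, values), [True, False, False]
        )

    def test_exact_tie_is_nonconforming(self):
        cons = ot.ConstraintSpec.order(["q1 > q2"])
        values = {"q1": np.array([0.5]), "q2": np.array([0.5])}
        assert not ot.evaluate_constraint(cons, values)[0]

    def test_brute_force_loop_equivalence(self):
        rng = np.random.default_rng(0)
        q1, q2 = rng.standard_normal((2, 10_000))
        cons = ot.ConstraintSpec.order(["q1 > 0", "q2 > 0", "q1 > q2"])
        fast = ot.evaluate_constraint(cons, {"q1": q1, "q2": q2})
        slow = np.array(
            [a > 0 and b > 0 and a > b for a, b in zip(q1, q2)]
        )
        np.testing.assert_array_equal(fast, slow)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ot.ConstraintSpec.order(["q1 > q2", "q2 > q1"])

    def test_probit_scale_recomputed_from_probability_draws(self, bell_model, bell_prior):
        draws = ot.draw_prior(bell_prior, bell_model, 1, 2_000, seed=0)
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0"], scale="probit"
        )
        ok = ot.evaluate_constraint(cons, draws, bell_model)
        assert ok.dtype == bool and len(ok) == 2_000
        # sign constraints agree across scales (probit is monotone)
        cons_p = ot.ConstraintSpec.order(["d_B_pleasant - d_A_pleasant > 0"])
        np.testing.assert_array_equal(ok, ot.evaluate_constraint(cons_p, draws, bell_model))


class TestPriorProportion:
    def test_two_sign_constraints_quarter(self, bell_model, bell_prior):
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0", "d_A_disgusting - d_B_disgusting > 0"]
        )
        assert ot.prior_constraint_proportion(cons, bell_prior, bell_model) == 0.25

    def test_added_ordering_eighth(self, bell_model, bell_prior, disordinal):
        assert ot.prior_constraint_proportion(disordinal, bell_prior, bell_model) == 0.125

    def test_three_chain_uses_linear_extensions(self, bell_model, bell_prior):
        """A full chain among three sign-constrained differences: 0.5^3 / 3!."""
        cons = ot.ConstraintSpec.order(
            [
                "d_B_pleasant - d_A_pleasant > 0",
                "d_A_disgusting - d_B_disgusting > 0",
                "D_A_pleasant - D_B_pleasant > 0",
                "(d_B_pleasant - d_A_pleasant) > (d_A_disgusting - d_B_disgusting)",
                "(d_A_disgusting - d_B_disgusting) > (D_A_pleasant - D_B_pleasant)",
            ]
        )
        assert ot.prior_constraint_proportion(cons, bell_prior, bell_model) == pytest.approx(
            0.5**3 / 6
        )

    def test_monte_carlo_agrees_with_analytic(self, bell_model, bell_prior, disordinal):
        mc = ot.prior_constraint_proportion(
            disordinal, bell_prior, bell_model, method="monte_carlo", n_draws=200_000, seed=1
        )
        assert abs(mc.value - 0.125) < 3 * mc.se + 1e-4

    def test_shared_parameter_rejected_for_analytic(self, bell_model, bell_prior):
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0", "d_B_pleasant - d_B_disgusting > 0"]
        )
        with pytest.raises(ValueError, match="monte_carlo"):
            ot.prior_constraint_proportion(cons, bell_prior, bell_model)

    def test_unsigned_ordered_quantity_rejected_for_analytic(self, bell_model, bell_prior):
        cons = ot.ConstraintSpec.order(
            ["(d_B_pleasant - d_A_pleasant) > (d_A_disgusting - d_B_disgusting)"]
        )
        with pytest.raises(ValueError, match="monte_carlo"):
            ot.prior_constraint_proportion(cons, bell_prior, bell_model)


class TestEncompassingBf:
    def test_simple_ratio(self):
        cons = ot.ConstraintSpec.order(["q > 0"])
        values = {"q": np.array([1.0] * 50 + [-1.0] * 50)}
        bf = ot.encompassing_bf(cons, values, 0.125)
        assert bf.value == pytest.approx(0.5 / 0.125)

    def test_all_conforming_maximal(self):
        cons = ot.ConstraintSpec.order(["q > 0"])
        bf = ot.encompassing_bf(cons, {"q": np.ones(1000)}, 0.125)
        assert bf.value == pytest.approx(8.0)

    def test_normal_orthant_oracle(self):
        rng = np.random.default_rng(42)
        n = 100_000
        draws = {"q": rng.normal(1.0, 1.0, n)}
        cons = ot.ConstraintSpec.order(["q > 0"])
        bf = ot.encompassing_bf(cons, draws, 0.5)
        exact = stats.norm.cdf(1.0) / 0.5
        frac = stats.norm.cdf(1.0)
        se = np.sqrt(frac * (1 - frac) / n) / 0.5
        assert abs(bf.value - exact) < 3 * se

    def test_zero_conforming_upper_bound(self):
        cons = ot.ConstraintSpec.order(["q > 0"])
        bf = ot.encompassing_bf(cons, {"q": -np.ones(1000)}, 0.125)
        assert bf.value == pytest.approx(1.0 / (1000 * 0.125))
        assert any("upper bound" in f for f in bf.flags)

    def test_few_conforming_flagged(self):
        cons = ot.ConstraintSpec.order(["q > 0"])
        values = {"q": np.concatenate([np.ones(5), -np.ones(995)])}
        bf = ot.encompassing_bf(cons, values, 0.5)
        assert any("unreliable" in f for f in bf.flags)


class TestPriorDensityAtNull:
    def test_triangular_density_one_at_zero(self, bell_model, bell_prior):
        q = ot.DerivedQuantity.from_string("d_B_pleasant - d_A_pleasant")
        assert ot.prior_density_at_null(q, bell_prior, bell_model) == 1.0

    def test_support_edges_zero(self, bell_model, bell_prior):
        q = ot.DerivedQuantity.from_string("d_B_pleasant - d_A_pleasant")
        assert ot.prior_density_at_null(q, bell_prior, bell_model, null=1.0) == 0.0
        assert ot.prior_density_at_null(q, bell_prior, bell_model, null=-1.0) == 0.0

    def test_non_uniform_prior_directed_to_logspline(self, bell_model, bell_prior):
        q = ot.DerivedQuantity.from_string("g_pleasant - g_disgusting")
        with pytest.raises(ValueError, match="logspline"):
            ot.prior_density_at_null(q, bell_prior, bell_model)

    def test_logspline_matches_triangular(self, bell_model, bell_prior):
        q = ot.DerivedQuantity.from_string("d_B_pleasant - d_A_pleasant")
        est = ot.prior_density_at_null(
            q, bell_prior, bell_model, method="logspline", n_draws=100_000, seed=0
        )
        assert est == pytest.approx(1.0, abs=0.05)


class TestSavageDickey:
    def test_ratio_definition(self):
        rng = np.random.default_rng(0)
        post = {"q": rng.normal(0, 0.2, 20_000)}
        bf = ot.savage_dickey_bf(post, {"q": 1.0}, method="truncated_normal")
        assert bf.value == pytest.approx(stats.norm.pdf(0, 0, 0.2), rel=0.05)

    def test_conjugate_binomial_logspline(self):
        """Beta(8, 4) posterior (7/10 successes, uniform prior), null at p = 0.5."""
        rng = np.random.default_rng(1)
        post = {"p": rng.beta(8, 4, 100_000)}
        bf = ot.savage_dickey_bf(post, {"p": 1.0}, {"p": 0.5}, support=(0.0, 1.0))
        assert bf.value == pytest.approx(stats.beta.pdf(0.5, 8, 4), rel=0.05)

    def test_posterior_far_from_null_gives_evidence_against(self):
        rng = np.random.default_rng(2)
        post = {"q": np.clip(rng.normal(0.7, 0.05, 20_000), -0.999, 0.999)}
        bf = ot.savage_dickey_bf(post, {"q": 1.0}, method="truncated_normal")
        assert bf.value < 1.0

    def test_methods_agree_on_normal_posterior(self):
        rng = np.random.default_rng(3)
        post = {"q": rng.normal(0.1, 0.15, 100_000)}
        a = ot.savage_dickey_bf(post, {"q": 1.0}, method="logspline").value
        b = ot.savage_dickey_bf(post, {"q": 1.0}, method="truncated_normal").value
        assert a == pytest.approx(b, rel=0.10)

    def test_null_outside_support_rejected(self):
        post = {"q": np.linspace(0.2, 0.9, 1000)}
        with pytest.raises(ValueError, match="range|support"):
            ot.savage_dickey_bf(post, {"q": 1.0}, {"q": -0.5})


class TestTransitivity:
    def test_algebraic_closure(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            re_v, oe_v = rng.uniform(0.01, 10, 2)
            bf_re = ot.BayesFactorResult("r_vs_e", re_v)
            bf_0e = ot.BayesFactorResult("0_vs_e", oe_v)
            comp = ot.compose_by_transitivity(bf_re, bf_0e)
            assert comp.value * oe_v == pytest.approx(re_v, rel=1e-12)

    def test_mismatched_fingerprints_rejected(self):
        bf_re = ot.BayesFactorResult("r_vs_e", 2.0, encompassing_id="a")
        bf_0e = ot.BayesFactorResult("0_vs_e", 0.5, encompassing_id="b")
        with pytest.raises(ValueError, match="fingerprint"):
            ot.compose_by_transitivity(bf_re, bf_0e)


class TestRepetitionAndGrids:
    def test_identical_draws_zero_width(self):
        cons = ot.ConstraintSpec.order(["q > 0"])
        values = {"q": np.array([1.0] * 30 + [-1.0] * 10)}

        def analysis(seed):
            return ot.encompassing_bf(cons, values, 0.5)

        rep = ot.bf_repeat(analysis, 10)
        lo, hi = rep.range
        assert lo == hi == rep.median

    def test_stability_on_conjugate_toy(self):
        root = np.random.default_rng(0)
        exact = stats.beta.pdf(0.5, 8, 4)

        def analysis(seed):
            post = {"p": np.random.default_rng(seed).beta(8, 4, 20_000)}
            return ot.savage_dickey_bf(post, {"p": 1.0}, {"p": 0.5}, support=(0.0, 1.0))

        rep = ot.bf_repeat(analysis, 20)
        lo, hi = rep.range
        assert (hi - lo) / rep.median < 0.2
        assert rep.median == pytest.approx(exact, rel=0.05)

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError):
            ot.bf_repeat(lambda s: ot.BayesFactorResult("r_vs_e", 1.0), 1)

    def test_segments_are_disjoint_cover(self, smoke_fit):
        segments = split_draw_segments(smoke_fit.draws, 4)
        assert sum(s.n_draws for s in segments) == smoke_fit.draws.n_draws

    def test_sensitivity_grid_runs_and_summarizes(self, bell_model, disordinal):
        priors = [
            ot.informative_preset(bell_model),
            ot.informative_preset(bell_model, guessing_sd=0.5),
        ]
        rng = np.random.default_rng(9)
        draws = {
            "d_B_pleasant - d_A_pleasant": rng.normal(0.1, 0.1, 5000),
            "d_A_disgusting - d_B_disgusting": rng.normal(0.05, 0.1, 5000),
        }

        def analysis(prior):
            prop = ot.prior_constraint_proportion(disordinal, prior, bell_model)
            return ot.encompassing_bf(disordinal, draws, prop)

        grid = ot.sensitivity_grid(analysis, priors)
        assert len(grid) == 2
        assert grid.attrs["min"] <= grid.attrs["max"]
        assert grid["error"].isna().all() or (grid["error"] == None).all()  # noqa: E711

    def test_empty_grid_rejected(self, bell_model):
        with pytest.raises(ValueError):
            ot.sensitivity_grid(lambda p: None, [ot.informative_preset(bell_model)])


class TestIndividualLevel:
    def test_single_participant_flat_constraint_half(self, bell_model, bell_prior):
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0"], level="every_individual"
        )
        p = ot.prior_constraint_proportion(
            cons, bell_prior, bell_model, method="monte_carlo",
            n_draws=100_000, seed=0, n_participants=1,
        )
        assert p.value == pytest.approx(0.5, abs=3 * p.se + 0.005)

    def test_all_conforming_posterior_hits_bound(self, bell_model, bell_prior):
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0"], level="every_individual"
        )
        # injected posterior: every participant conforms in every draw
        values = {"d_B_pleasant - d_A_pleasant": np.full((500, 7), 0.2)}
        prop = ot.MonteCarloEstimate(0.01, 0.001, 100_000)
        bf = ot.encompassing_bf(cons, values, prop)
        assert bf.value == pytest.approx(1.0 / 0.01)

    def test_group_level_constraint_rejected(self, bell_model, bell_prior, smoke_fit, disordinal):
        with pytest.raises(ValueError, match="every_individual"):
            ot.individual_level_bf(disordinal, bell_prior, bell_model, smoke_fit)


class TestDescriptiveEffects:
    def _draws(self, bell_model, diff):
        """Synthetic posterior draws with a given per-participant d-difference sign."""
        rng = np.random.default_rng(0)
        n, I, P = 400, 10, 12
        base = ot.probit(0.5) + rng.normal(0, 0.05, size=(n, I, P))
        draws = ot.ParameterDraws(
            parameters=bell_model.parameters,
            group_mu=np.zeros((n, P)),
            sigma=np.full((n, P), 0.1),
            corr=np.broadcast_to(np.eye(P), (n, P, P)).copy(),
            individual_probit=base,
            provenance="posterior",
        )
        j_hi = bell_model.parameters.index("d_B_pleasant")
        j_lo = bell_model.parameters.index("d_A_pleasant")
        draws.individual_probit[:, :, j_hi] += diff
        draws.individual_probit[:, :, j_lo] -= diff
        return draws

    def test_all_mass_conforming(self, bell_model):
        draws = self._draws(bell_model, diff=1.0)
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0"], level="every_individual"
        )
        out = ot.descriptive_individual_effects(draws, cons, bell_model)
        assert out["point_estimate_conforming"] == 10
        assert out["interval_conforming"] == 10

    def test_symmetric_null_near_half(self, bell_model):
        draws = self._draws(bell_model, diff=0.0)
        cons = ot.ConstraintSpec.order(
            ["d_B_pleasant - d_A_pleasant > 0"], level="every_individual"
        )
        out = ot.descriptive_individual_effects(draws, cons, bell_model)
        assert 0 <= out["interval_conforming"] <= out["n_participants"]
        assert 0 <= out["point_estimate_conforming"] <= out["n_participants"]
        # under a symmetric posterior roughly half the point estimates conform
        assert 1 <= out["point_estimate_conforming"] <= 9


class TestConstraintSpecParsing:
    def test_point_null_builder(self):
        cons = ot.ConstraintSpec.point_null(["d_B_pleasant - d_A_pleasant"])
        assert cons.kind == "point_null"
        assert list(cons.null_values.values()) == [0.0]

    def test_inequality_names(self):
        ineq = Inequality(larger="a", smaller=0.0)
        assert ineq.names() == ("a",)

    def test_unknown_quantity_rejected(self):
        with pytest.raises(KeyError):
            ot.ConstraintSpec(
                quantities={}, kind="order", inequalities=(Inequality("q", 0.0),)
            )
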