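"""Predictive simulation and T1/T2 posterior-predictive checks."""

import numpy as np
import pytest

import ordtree as ot


def _degenerate_draws(htsm, n_draws=50, n_part=4):
    """Draws with perfect item and source memory for every participant."""
    theta = {"D": 1 - 1e-9, "d": 1 - 1e-9, "b": 0.5, "g": 0.5}
    probit = ot.probit(np.clip([theta[p] for p in htsm.parameters], 1e-12, 1 - 1e-12))
    z = np.broadcast_to(probit, (n_draws, n_part, 4)).copy()
    return ot.ParameterDraws(
        parameters=htsm.parameters,
        group_mu=np.broadcast_to(probit, (n_draws, 4)).copy(),
        sigma=np.zeros((n_draws, 4)),
        corr=np.broadcast_to(np.eye(4), (n_draws, 4, 4)).copy(),
        individual_probit=z,
        provenance="prior",
    )


class TestPredictiveSimulate:
    def test_perfect_memory_answers_correct_source(self, htsm, small_design):
        design = ot.StudyDesign(items_per_tree=small_design.items_per_tree, n_participants=4)
        draws = _degenerate_draws(htsm)
        pred = ot.predictive_simulate(draws, htsm, design, seed=0)
        tree = htsm.tree("source_A")
        j = tree.categories.index("A")
        assert np.all(pred.counts["source_A"][..., j] == design.items_per_tree["source_A"])

    def test_totals_conserved(self, htsm, smoke_fit, small_design):
        pred = ot.predictive_simulate(smoke_fit.draws, htsm, small_design, seed=1, n_rep=100)
        for tree, counts in pred.counts.items():
            assert np.all(counts.sum(axis=-1) == small_design.items_per_tree[tree])

    def test_binomial_moments(self):
        model = ot.parse_eqn("T x 0.5\nT y 0.3\nT z 0.2")
        n_rep = 10_000
        draws = ot.ParameterDraws(
            parameters=(),
            group_mu=np.zeros((n_rep, 0)),
            sigma=np.zeros((n_rep, 0)),
            corr=np.zeros((n_rep, 0, 0)),
            individual_probit=np.zeros((n_rep, 1, 0)),
            provenance="prior",
        )
        design = ot.StudyDesign(items_per_tree={"T": 10}, n_participants=1)
        pred = ot.predictive_simulate(draws, model, design, seed=2)
        means = pred.counts["T"][:, 0, :].mean(axis=0)
        p = np.array([0.5, 0.3, 0.2])
        se = np.sqrt(10 * p * (1 - p) / n_rep)
        np.testing.assert_array_less(np.abs(means - 10 * p), 3 * se + 1e-9)

    def test_seeded_repeatability(self, htsm, smoke_fit, small_design):
        a = ot.predictive_simulate(smoke_fit.draws, htsm, small_design, seed=9, n_rep=50)
        b = ot.predictive_simulate(smoke_fit.draws, htsm, small_design, seed=9, n_rep=50)
        for tree in a.counts:
            np.testing.assert_array_equal(a.counts[tree], b.counts[tree])

    def test_design_mismatch_rejected(self, htsm, smoke_fit):
        bad = ot.StudyDesign(items_per_tree={"source_A": 10}, n_participants=30)
        with pytest.raises(ValueError):
            ot.predictive_simulate(smoke_fit.draws, htsm, bad, seed=0)


class TestT1T2:
    def test_p_values_bounded_and_sane_under_truth(self, htsm, smoke_fit, small_dataset):
        table, _ = small_dataset
        out = ot.t1_t2(smoke_fit, table, htsm, n_rep=300, seed=3)
        assert 0.0 <= out["p_T1"] <= 1.0
        assert 0.0 <= out["p_T2"] <= 1.0

    def test_gross_misfit_detected(self, htsm, smoke_fit, small_dataset):
        table, _ = small_dataset
        counts = {t: c.copy() for t, c in table.counts.items()}
        counts["new"][:, 0] = 18
        counts["new"][:, 1] = 1
        counts["new"][:, 2] = 1
        bad = ot.FrequencyTable(
            participants=table.participants, categories=table.categories, counts=counts
        )
        out = ot.t1_t2(smoke_fit, bad, htsm, n_rep=300, seed=3)
        assert out["p_T1"] <= 0.01

    def test_single_participant_flags_t2(self, htsm, binomial_toy):
        model, prior = binomial_toy
        table = ot.FrequencyTable(
            participants=("a",),
            categories={"T": ("h", "t")},
            counts={"T": np.array([[6, 4]])},
        )
        fit = ot.fit_posterior(
            model, prior, table, ot.McmcSettings(draws=500, warmup=200, chains=1, seed=0)
        )
        out = ot.t1_t2(fit, table, model, n_rep=100, seed=0)
        assert out["p_T2"] is None
        assert "single participant" in out["note"]

    def test_n_rep_floor(self, htsm, smoke_fit, small_dataset):
        table, _ = small_dataset
        with pytest.raises(ValueError):
            ot.t1_t2(smoke_fit, table, htsm, n_rep=10)


class TestResponseRates:
    def test_degenerate_point_mass(self, htsm, small_design):
        design = ot.StudyDesign(items_per_tree=small_design.items_per_tree, n_participants=4)
        pred = ot.predictive_simulate(_degenerate_draws(htsm), htsm, design, seed=0)
        s = ot.response_rate_summary(pred, "source_A", "A")
        assert s["mean"] == pytest.approx(1.0)
        assert s["sd"] == pytest.approx(0.0)

    def test_unknown_category_rejected(self, htsm, smoke_fit, small_design):
        pred = ot.predictive_simulate(smoke_fit.draws, htsm, small_design, seed=0, n_rep=20)
        with pytest.raises(KeyError):
            ot.response_rate_summary(pred, "source_A", "nope")

    def test_monte_carlo_consistency(self, htsm):
        """Mean of P(A | source A) under uniform parameters vs. re-simulation."""
        prior = ot.matzke_klauer_preset(htsm)
        a = ot.draw_prior(prior, htsm, 1, 50_000, seed=1)
        b = ot.draw_prior(prior, htsm, 1, 50_000, seed=2)
        pa = ot.response_probability_draws(a, htsm, "source_A", "A").mean()
        pb = ot.response_probability_draws(b, htsm, "source_A", "A").mean()
        assert pa == pytest.approx(pb, abs=0.01)

    def test_prior_predictive_extremeness_contrast(self, htsm):
        """Individual response-rate mass near 0/1 is larger under the default priors."""
        inf_draws = ot.draw_prior(ot.informative_preset(htsm), htsm, 1, 30_000, seed=3)
        mk_draws = ot.draw_prior(ot.matzke_klauer_preset(htsm), htsm, 1, 30_000, seed=3)
        pi = ot.response_probability_draws(inf_draws, htsm, "source_A", "A").ravel()
        pm = ot.response_probability_draws(mk_draws, htsm, "source_A", "A").ravel()
        mass_i = np.mean((pi <= 0.1) | (pi >= 0.9))
        mass_m = np.mean((pm <= 0.1) | (pm >= 0.9))
        se = np.hypot(
            np.sqrt(mass_i * (1 - mass_i) / len(pi)), np.sqrt(mass_m * (1 - mass_m) / len(pm))
        )
        assert mass_m - mass_i > 3 * se
        # interior local minima: density dips between the modes for the default priors
        hist, _ = np.histogram(pm, bins=20, range=(0, 1))
        assert hist.min() < hist[0] and hist.min() < hist[-1]
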