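"""Bayes factors for equality and order constraints via the encompassing model.

Two identities carry the whole machinery:

* **Savage–Dickey density ratio** — for a point null nested in the
  encompassing model, ``BF_0e`` is the posterior density at the null divided
  by the prior density at the null (per quantity; independent quantities
  multiply).
* **Unconditional encompassing Bayes factor** — for an order-restricted
  model, ``BF_re`` is the ratio of the posterior to the prior proportion of
  encompassing-model draws that satisfy the restriction (a counting method).

The restricted-vs-null comparison follows by transitivity,
``BF_r0 = BF_re / BF_0e``.  Repetition across re-sampled posteriors gives a
median and range; sensitivity grids rerun an analysis across prior
specifications; the individual-level test applies the restriction to *every*
participant simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import (
    ConstraintSpec,
    DerivedQuantity,
    evaluate_constraint,
    prior_constraint_proportion,
    quantity_draws,
)
from .density import logspline_density, truncnorm_density
from .inference import FitResult
from .model import MPTModel
from .priors import MonteCarloEstimate, ParameterDraws, PriorSpec, draw_prior

__all__ = [
    "BayesFactorResult",
    "encompassing_bf",
    "prior_density_at_null",
    "savage_dickey_bf",
    "compose_by_transitivity",
    "bf_repeat",
    "split_draw_segments",
    "individual_level_bf",
    "sensitivity_grid",
    "descriptive_individual_effects",
]

_MIN_CONFORMING = 10


@dataclass
class BayesFactorResult:
    """A Bayes factor with method metadata, stability range and reliability flags."""

    comparison: Literal["r_vs_e", "0_vs_e", "r_vs_0"]
    value: float
    method: dict = field(default_factory=dict)
    components: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    repetitions: list[float] | None = None
    encompassing_id: str | None = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("Bayes factors must be positive")

    @property
    def median(self) -> float:
        if self.repetitions:
            return float(np.median(self.repetitions))
        return self.value

    @property
    def range(self) -> tuple[float, float]:
        if self.repetitions:
            return (float(min(self.repetitions)), float(max(self.repetitions)))
        return (self.value, self.value)

    def summary(self) -> str:
        lo, hi = self.range
        tag = {"r_vs_e": "BF_re", "0_vs_e": "BF_0e", "r_vs_0": "BF_r0"}[self.comparison]
        text = f"{tag} = {self.median:.4g}"
        if self.repetitions:
            text += f" [{lo:.4g}, {hi:.4g}] ({len(self.repetitions)} repetitions)"
        if self.flags:
            text += f"  flags: {', '.join(self.flags)}"
        return text


def encompassing_bf(
    constraint: ConstraintSpec,
    posterior: ParameterDraws | Mapping[str, np.ndarray] | np.ndarray,
    prior_proportion: float | MonteCarloEstimate,
    model: MPTModel | None = None,
    encompassing_id: str | None = None,
) -> BayesFactorResult:
    """Order-restricted vs. encompassing Bayes factor by counting.

    ``posterior`` is either posterior :class:`ParameterDraws`, injected draws
    of the constrained quantities, or a precomputed boolean conformity array.
    A reliability flag is raised when fewer than 10 posterior draws conform;
    with zero conforming draws the reported value is the Monte-Carlo upper
    bound ``1 / (n * prior_proportion)``.
    """
    p_prior = float(prior_proportion)
    if not 0.0 < p_prior < 1.0:
        raise ValueError("prior proportion must be in (0, 1)")
    if isinstance(posterior, np.ndarray) and posterior.dtype == bool:
        ok = posterior
    else:
        ok = evaluate_constraint(constraint, posterior, model)
    n = len(ok)
    count = int(ok.sum())
    frac = count / n
    flags: list[str] = []
    if count == 0:
        flags.append("no conforming posterior draws: value is an upper bound")
        value = 1.0 / (n * p_prior)
    else:
        value = frac / p_prior
        if count < _MIN_CONFORMING:
            flags.append(f"only {count} conforming posterior draws; unreliable")
    se_post = float(np.sqrt(max(frac * (1 - frac), 1.0 / n) / n))
    components = {
        "posterior_proportion": frac,
        "posterior_proportion_se": se_post,
        "posterior_conforming": count,
        "posterior_draws": n,
        "prior_proportion": p_prior,
    }
    if isinstance(prior_proportion, MonteCarloEstimate):
        components["prior_proportion_se"] = prior_proportion.se
        source = "monte_carlo"
    else:
        source = "analytic"
    return BayesFactorResult(
        comparison="r_vs_e",
        value=value,
        method={"method": "counting", "prior_proportion_source": source},
        components=components,
        flags=flags,
        encompassing_id=encompassing_id,
    )


def prior_density_at_null(
    quantity: DerivedQuantity,
    prior: PriorSpec,
    model: MPTModel,
    method: Literal["analytic", "logspline"] = "analytic",
    null: float = 0.0,
    support: tuple[float, float] = (-1.0, 1.0),
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Prior density of a derived quantity at the null point.

    The analytic path covers the canonical case: the difference of two
    parameters whose probit-normal priors are standard normal, hence uniform
    on the probability scale — the difference is triangular on [-1, 1] with
    density ``1 - |x|`` (density exactly 1 at zero).  Otherwise the density
    is estimated by log-spline from prior draws.
    """
    if method == "analytic":
        from .constraints import _difference_parameters

        if quantity.scale != "probability":
            raise ValueError(
                "analytic triangular density applies on the probability scale "
                "(use method='logspline')"
            )
        a, b = _difference_parameters(quantity)
        for p in (a, b):
            spec = prior.group_mean.get(p)
            if spec is None:
                raise KeyError(f"no group-mean prior for {p!r}")
            if spec.loc != 0.0 or abs(spec.sd - 1.0) > 1e-12:
                raise ValueError(
                    f"prior for {p!r} does not imply a uniform probability-scale "
                    "distribution (use method='logspline')"
                )
        return max(0.0, 1.0 - abs(null))
    if method != "logspline":
        raise ValueError(f"unknown method {method!r}")
    draws = draw_prior(prior, model, n_participants=1, n_draws=n_draws, seed=seed)
    samples = quantity_draws(quantity, draws, model, level="group")
    return float(logspline_density(samples, support=support)(null))


def savage_dickey_bf(
    posterior_samples: Mapping[str, np.ndarray],
    prior_density: Mapping[str, float],
    null_points: Mapping[str, float] | None = None,
    method: Literal["logspline", "truncated_normal"] = "logspline",
    support: tuple[float, float] = (-1.0, 1.0),
    encompassing_id: str | None = None,
) -> BayesFactorResult:
    """Point-null vs. encompassing Bayes factor via the Savage–Dickey ratio.

    ``BF_0e`` multiplies, over quantities, the posterior density at the null
    divided by the prior density there (valid when the test-relevant
    quantities have independent priors; this is the within-condition testing
    scheme, one difference per condition).
    """
    nulls = dict(null_points or {name: 0.0 for name in posterior_samples})
    per_quantity: dict[str, dict[str, float]] = {}
    log_bf = 0.0
    for name, samples in posterior_samples.items():
        prior_d = prior_density[name]
        if prior_d <= 0:
            raise ValueError(f"prior density for {name!r} must be positive at the null")
        null = nulls[name]
        samples = np.asarray(samples, dtype=float)
        if not (support[0] <= null <= support[1]):
            raise ValueError(f"null point {null} for {name!r} lies outside the support")
        if method == "logspline":
            if not (samples.min() <= null <= samples.max()):
                raise ValueError(
                    f"null point {null} for {name!r} lies outside the posterior draw "
                    "range; the log-spline tail is not estimable there "
                    "(consider method='truncated_normal')"
                )
            post_d = float(logspline_density(samples, support=support)(null))
        elif method == "truncated_normal":
            post_d = float(truncnorm_density(samples, null, bounds=support))
        else:
            raise ValueError(f"unknown method {method!r}")
        if post_d <= 0:
            raise ValueError(
                f"estimated posterior density at the null for {name!r} is zero "
                f"({method}); the null is too deep in the tail"
            )
        per_quantity[name] = {"prior_density": prior_d, "posterior_density": post_d}
        log_bf += np.log(post_d) - np.log(prior_d)
    return BayesFactorResult(
        comparison="0_vs_e",
        value=float(np.exp(log_bf)),
        method={"method": method, "support": support},
        components=per_quantity,
        encompassing_id=encompassing_id,
    )


def compose_by_transitivity(
    bf_re: BayesFactorResult, bf_0e: BayesFactorResult
) -> BayesFactorResult:
    """Restricted vs. null Bayes factor: ``BF_r0 = BF_re / BF_0e``.

    Both inputs must refer to the same encompassing posterior (matching
    fingerprints when present).
    """
    if bf_re.comparison != "r_vs_e" or bf_0e.comparison != "0_vs_e":
        raise ValueError("transitivity needs a r-vs-e and a 0-vs-e result")
    if (
        bf_re.encompassing_id is not None
        and bf_0e.encompassing_id is not None
        and bf_re.encompassing_id != bf_0e.encompassing_id
    ):
        raise ValueError("mismatched encompassing-model fingerprints")
    repetitions = None
    if (
        bf_re.repetitions
        and bf_0e.repetitions
        and len(bf_re.repetitions) == len(bf_0e.repetitions)
    ):
        repetitions = [a / b for a, b in zip(bf_re.repetitions, bf_0e.repetitions)]
    return BayesFactorResult(
        comparison="r_vs_0",
        value=bf_re.value / bf_0e.value,
        method={"method": "transitivity", "re": bf_re.method, "0e": bf_0e.method},
        components={"bf_re": bf_re.value, "bf_0e": bf_0e.value},
        flags=sorted(set(bf_re.flags) | set(bf_0e.flags)),
        repetitions=repetitions,
        encompassing_id=bf_re.encompassing_id or bf_0e.encompassing_id,
    )


def bf_repeat(
    analysis: Callable[[int], BayesFactorResult],
    n_repetitions: int,
    base_seed: int = 0,
) -> BayesFactorResult:
    """Repeat a Bayes-factor analysis with fresh seeds; report median and range.

    ``analysis`` maps a seed to a :class:`BayesFactorResult` (in full mode it
    should re-run posterior sampling; in fast mode, resample stored draws).
    Individual failures are recorded, not raised, as long as at least one
    repetition succeeds.
    """
    if n_repetitions < 2:
        raise ValueError("need at least 2 repetitions")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_repetitions) % (2**31 - 1)
    values: list[float] = []
    failures = 0
    last: BayesFactorResult | None = None
    for s in seeds:
        try:
            last = analysis(int(s))
            values.append(last.value)
        except Exception:  # noqa: BLE001 - per-repetition failures are data
            failures += 1
    if last is None:
        raise RuntimeError("all repetitions failed")
    flags = list(last.flags)
    if failures:
        flags.append(f"{failures}/{n_repetitions} repetitions failed")
    return replace(
        last,
        value=float(np.median(values)),
        repetitions=values,
        flags=flags,
        method={**last.method, "n_repetitions": n_repetitions, "failures": failures},
    )


def split_draw_segments(draws: ParameterDraws, n_segments: int) -> list[ParameterDraws]:
    """Disjoint contiguous segments of stored draws (fast-mode repetition)."""
    if n_segments < 2 or n_segments > draws.n_draws:
        raise ValueError("invalid segment count")
    bounds = np.linspace(0, draws.n_draws, n_segments + 1).astype(int)
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out.append(
            ParameterDraws(
                parameters=draws.parameters,
                group_mu=draws.group_mu[lo:hi],
                sigma=draws.sigma[lo:hi],
                corr=draws.corr[lo:hi],
                individual_probit=draws.individual_probit[lo:hi],
                provenance=draws.provenance,
                seed=draws.seed,
            )
        )
    return out


def individual_level_bf(
    constraint: ConstraintSpec,
    prior: PriorSpec,
    model: MPTModel,
    fit: FitResult | ParameterDraws,
    n_prior_draws: int = 1_000_000,
    seed: int = 0,
) -> BayesFactorResult:
    """Restricted vs. encompassing Bayes factor for "every participant shows the effect".

    Both proportions come from counting: the prior proportion by Monte Carlo
    (the hierarchy makes it analytically intractable), the posterior
    proportion from the fitted draws.  This is an intentionally risky model:
    under realistic priors the prior proportion for ~100 participants is of
    order 1e-4.
    """
    if constraint.level != "every_individual":
        raise ValueError("constraint level must be 'every_individual'")
    draws = fit.draws if isinstance(fit, FitResult) else fit
    n_participants = draws.n_participants
    prior_prop = prior_constraint_proportion(
        constraint,
        prior,
        model,
        method="monte_carlo",
        n_draws=n_prior_draws,
        seed=seed,
        n_participants=n_participants,
    )
    assert isinstance(prior_prop, MonteCarloEstimate)
    if prior_prop.value == 0.0:
        raise ValueError(
            f"no conforming prior draws in {n_prior_draws}; increase n_prior_draws"
        )
    result = encompassing_bf(
        constraint,
        draws,
        prior_prop,
        model=model,
        encompassing_id=(
            fit.fingerprints.get("data") if isinstance(fit, FitResult) else None
        ),
    )
    prior_count = round(prior_prop.value * prior_prop.n)
    if prior_count < _MIN_CONFORMING:
        result.flags.append(f"only {prior_count} conforming prior draws; unreliable")
    result.method["level"] = "every_individual"
    result.components["n_participants"] = n_participants
    return result


def sensitivity_grid(
    analysis: Callable[[PriorSpec], BayesFactorResult],
    priors: Sequence[PriorSpec],
) -> pd.DataFrame:
    """Rerun a Bayes-factor analysis across prior specifications.

    Per-cell failures are recorded in the table; the grid continues.  The
    returned frame carries ``min``/``max`` of successful values in ``attrs``.
    """
    if len(priors) < 2:
        raise ValueError("a sensitivity grid needs at least 2 prior specifications")
    rows = []
    for i, prior in enumerate(priors):
        row: dict = {"cell": i, "preset": prior.preset}
        try:
            result = analysis(prior)
            row["value"] = result.value
            row["flags"] = "; ".join(result.flags)
            row["error"] = None
        except Exception as exc:  # noqa: BLE001 - per-cell failures are data
            row["value"] = np.nan
            row["flags"] = ""
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("cell")
    ok = frame["value"].dropna()
    frame.attrs["min"] = float(ok.min()) if len(ok) else np.nan
    frame.attrs["max"] = float(ok.max()) if len(ok) else np.nan
    return frame


def descriptive_individual_effects(
    fit: FitResult | ParameterDraws,
    constraint: ConstraintSpec,
    model: MPTModel,
    interval_mass: float = 0.8,
) -> dict[str, int]:
    """Count participants whose estimates conform to the order constraint.

    Two counts: participants whose per-quantity posterior *medians* satisfy
    every inequality, and participants whose equal-tailed credible interval
    of each inequality's difference lies wholly on the conforming side.
    """
    if not 0.0 < interval_mass < 1.0:
        raise ValueError("interval_mass must be in (0, 1)")
    draws = fit.draws if isinstance(fit, FitResult) else fit
    level_constraint = constraint
    values = {
        name: quantity_draws(q, draws, model, level="individual")
        for name, q in level_constraint.quantities.items()
    }  # (n, I) arrays
    n_participants = next(iter(values.values())).shape[1]
    lo_q = (1.0 - interval_mass) / 2.0

    point_ok = np.ones(n_participants, dtype=bool)
    interval_ok = np.ones(n_participants, dtype=bool)
    for ineq in level_constraint.inequalities:
        larger = values[ineq.larger] if isinstance(ineq.larger, str) else ineq.larger
        smaller = values[ineq.smaller] if isinstance(ineq.smaller, str) else ineq.smaller
        diff = np.asarray(larger) - np.asarray(smaller)  # (n, I)
        point_ok &= np.median(diff, axis=0) > 0
        lo = np.quantile(diff, lo_q, axis=0)
        interval_ok &= lo > 0
    return {
        "point_estimate_conforming": int(point_ok.sum()),
        "interval_conforming": int(interval_ok.sum()),
        "n_participants": n_participants,
        "interval_mass": interval_mass,
    }
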