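"""Declarative equality and order constraints on derived quantities.

A :class:`DerivedQuantity` is an arithmetic expression over model parameters
(free or model-derived), evaluated on the probability scale (default) or the
probit scale.  A :class:`ConstraintSpec` collects strict inequalities among
quantities (and zero), e.g. the disordinal interaction

    d_B_pleasant - d_A_pleasant > 0
    d_A_disgusting - d_B_disgusting > 0
    (d_B_pleasant - d_A_pleasant) > (d_A_disgusting - d_B_disgusting)

or pins quantities to a point null.  Constraints can be evaluated per draw at
the group level or per draw x participant at the individual level ("every
participant shows the effect").
"""

from __future__ import annotations

import ast
import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .expressions import Expression
from .model import MPTModel
from .priors import (
    MonteCarloEstimate,
    NormalSpec,
    ParameterDraws,
    PriorSpec,
    draw_prior,
    probit,
)

__all__ = [
    "DerivedQuantity",
    "Inequality",
    "ConstraintSpec",
    "evaluate_constraint",
    "quantity_draws",
    "prior_constraint_proportion",
]

Scale = Literal["probability", "probit"]


@dataclass(frozen=True)
class DerivedQuantity:
    """A named arithmetic function of model parameters with an explicit scale."""

    name: str
    expression: Expression
    scale: Scale = "probability"

    @classmethod
    def from_string(cls, source: str, scale: Scale = "probability", name: str | None = None):
        return cls(name=name or source.strip(), expression=Expression(source), scale=scale)


@dataclass(frozen=True)
class Inequality:
    """Strict inequality ``larger > smaller``; either side a quantity name or a number."""

    larger: str | float
    smaller: str | float

    def names(self) -> tuple[str, ...]:
        return tuple(s for s in (self.larger, self.smaller) if isinstance(s, str))


@dataclass(frozen=True)
class ConstraintSpec:
    """A conjunction of order constraints, or a set of point nulls."""

    quantities: dict[str, DerivedQuantity]
    kind: Literal["order", "point_null"] = "order"
    inequalities: tuple[Inequality, ...] = ()
    null_values: dict[str, float] = field(default_factory=dict)
    level: Literal["group", "every_individual"] = "group"

    def __post_init__(self) -> None:
        if self.kind == "order":
            if not self.inequalities:
                raise ValueError("order constraint needs at least one inequality")
            for ineq in self.inequalities:
                for name in ineq.names():
                    if name not in self.quantities:
                        raise KeyError(f"inequality references unknown quantity {name!r}")
            self._check_acyclic()
        else:
            if not self.null_values:
                raise ValueError("point-null constraint needs at least one pinned quantity")
            for name in self.null_values:
                if name not in self.quantities:
                    raise KeyError(f"null pins unknown quantity {name!r}")

    def _check_acyclic(self) -> None:
        edges = [
            (i.larger, i.smaller)
            for i in self.inequalities
            if isinstance(i.larger, str) and isinstance(i.smaller, str)
        ]
        graph: dict[str, list[str]] = {}
        for a, b in edges:
            graph.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for nxt in graph.get(node, []):
                if state.get(nxt) == 1:
                    raise ValueError("inequality graph contains a cycle")
                if state.get(nxt, 0) == 0:
                    visit(nxt)
            state[node] = 2

        for node in graph:
            if state.get(node, 0) == 0:
                visit(node)

    @classmethod
    def order(
        cls,
        relations: Sequence[str],
        scale: Scale = "probability",
        level: Literal["group", "every_individual"] = "group",
    ) -> "ConstraintSpec":
        """Build an order constraint from strings like ``"d_b - d_a > 0"``.

        Each relation must contain exactly one ``>``; sides are numeric
        literals or expressions (expressions become named quantities keyed by
        their normalized source).
        """
        quantities: dict[str, DerivedQuantity] = {}
        inequalities: list[Inequality] = []

        def side(text: str) -> str | float:
            text = text.strip()
            try:
                return float(text)
            except ValueError:
                pass
            if text.startswith("(") and text.endswith(")"):
                # strip redundant outer parens if they balance
                depth = 0
                ok = True
                for i, ch in enumerate(text):
                    depth += ch == "("
                    depth -= ch == ")"
                    if depth == 0 and i < len(text) - 1:
                        ok = False
                        break
                if ok:
                    text = text[1:-1].strip()
            if text not in quantities:
                quantities[text] = DerivedQuantity.from_string(text, scale=scale)
            return text

        for rel in relations:
            parts = rel.split(">")
            if len(parts) != 2:
                raise ValueError(f"relation {rel!r} must contain exactly one '>'")
            inequalities.append(Inequality(larger=side(parts[0]), smaller=side(parts[1])))
        return cls(
            quantities=quantities,
            kind="order",
            inequalities=tuple(inequalities),
            level=level,
        )

    @classmethod
    def point_null(
        cls,
        expressions: Sequence[str],
        value: float = 0.0,
        scale: Scale = "probability",
    ) -> "ConstraintSpec":
        quantities = {
            e.strip(): DerivedQuantity.from_string(e.strip(), scale=scale) for e in expressions
        }
        return cls(
            quantities=quantities,
            kind="point_null",
            null_values={name: value for name in quantities},
        )


def _parameter_values(
    draws: ParameterDraws, model: MPTModel, level: str, scale: Scale
) -> dict[str, np.ndarray]:
    """Probability- or probit-scale values of all model parameters (incl. derived)."""
    if level == "group":
        base = draws.group_prob_dict()
    else:
        base = draws.individual_prob_dict()
    full = model.full_theta(base)  # adds model-derived parameters on the probability scale
    if scale == "probit":
        eps = 1e-12
        full = {k: probit(np.clip(v, eps, 1.0 - eps)) for k, v in full.items()}
    return full


def quantity_draws(
    quantity: DerivedQuantity,
    draws: ParameterDraws,
    model: MPTModel,
    level: Literal["group", "individual"] = "group",
) -> np.ndarray:
    """Draws of a derived quantity: (n,) at group level, (n, I) at individual level."""
    values = _parameter_values(draws, model, level, quantity.scale)
    return np.asarray(quantity.expression(values), dtype=float)


def evaluate_constraint(
    constraint: ConstraintSpec,
    draws: ParameterDraws | Mapping[str, np.ndarray],
    model: MPTModel | None = None,
    reduce_individuals: bool = True,
) -> np.ndarray:
    """Per-draw conformity indicator for an order constraint.

    ``draws`` may be :class:`ParameterDraws` (quantities are computed from the
    model) or a mapping of quantity name to pre-computed draws ("injected"
    values, shape (n,) or (n, I)).  Exact ties violate strict inequalities.
    At the individual level the result is reduced by AND over participants
    unless ``reduce_individuals`` is false.
    """
    if constraint.kind != "order":
        raise ValueError("only order constraints can be evaluated draw-wise")
    level = "individual" if constraint.level == "every_individual" else "group"
    if isinstance(draws, ParameterDraws):
        if model is None:
            raise ValueError("model required to evaluate quantities from ParameterDraws")
        # evaluate the shared parameter dictionaries once per scale
        scales = {q.scale for q in constraint.quantities.values()}
        by_scale = {s: _parameter_values(draws, model, level, s) for s in scales}
        values = {
            name: np.asarray(q.expression(by_scale[q.scale]), dtype=float)
            for name, q in constraint.quantities.items()
        }
    else:
        values = {k: np.asarray(v, dtype=float) for k, v in draws.items()}
        for ineq in constraint.inequalities:
            for name in ineq.names():
                if name not in values:
                    raise KeyError(f"injected draws lack quantity {name!r}")

    ok: np.ndarray | None = None
    for ineq in constraint.inequalities:
        larger = values[ineq.larger] if isinstance(ineq.larger, str) else ineq.larger
        smaller = values[ineq.smaller] if isinstance(ineq.smaller, str) else ineq.smaller
        this = np.asarray(larger > smaller)
        ok = this if ok is None else (ok & this)
    assert ok is not None
    if ok.ndim == 2 and constraint.level == "every_individual" and reduce_individuals:
        ok = ok.all(axis=1)
    return ok


# ---------------------------------------------------------------------------
# analytic prior proportions
# ---------------------------------------------------------------------------


def _difference_parameters(q: DerivedQuantity) -> tuple[str, str]:
    """Return (a, b) if the quantity is exactly the difference ``a - b``."""
    tree = ast.parse(q.expression.source, mode="eval").body
    if (
        isinstance(tree, ast.BinOp)
        and isinstance(tree.op, ast.Sub)
        and isinstance(tree.left, ast.Name)
        and isinstance(tree.right, ast.Name)
        and tree.left.id != tree.right.id
    ):
        return tree.left.id, tree.right.id
    raise ValueError(
        f"analytic prior proportion requires quantities of the form 'a - b'; "
        f"got {q.expression.source!r} (use method='monte_carlo')"
    )


def _validate_analytic(constraint: ConstraintSpec, prior: PriorSpec) -> tuple[int, list[str]]:
    """Check symmetry/independence/exchangeability; return (m sign constraints, DAG names)."""
    if constraint.level != "group":
        raise ValueError("analytic proportions apply to group-level constraints only")
    sign_constrained: set[str] = set()
    dag_names: set[str] = set()
    n_sign = 0
    for ineq in constraint.inequalities:
        names = ineq.names()
        if len(names) == 1:
            other = ineq.larger if isinstance(ineq.larger, float) else ineq.smaller
            if other != 0.0:
                raise ValueError(
                    "analytic proportions support sign constraints against 0 only "
                    "(use method='monte_carlo')"
                )
            n_sign += 1
            sign_constrained.add(names[0])
        elif len(names) == 2:
            dag_names.update(names)
        else:
            raise ValueError("inequality between two constants is not a constraint")

    involved: dict[str, tuple[str, str]] = {}
    for name in set(sign_constrained) | dag_names:
        involved[name] = _difference_parameters(constraint.quantities[name])

    # independence: parameter sets disjoint across quantities
    seen: set[str] = set()
    specs: list[NormalSpec] = []
    for a, b in involved.values():
        for p in (a, b):
            if p in seen:
                raise ValueError(
                    f"parameter {p!r} appears in several quantities; differences are "
                    "not independent (use method='monte_carlo')"
                )
            seen.add(p)
            spec = prior.group_mean.get(p)
            if spec is None:
                raise KeyError(f"no group-mean prior for parameter {p!r}")
            if spec.loc != 0.0:
                raise ValueError(
                    f"prior for {p!r} is not symmetric about 0 (use method='monte_carlo')"
                )
            specs.append(spec)
    if len({(s.loc, s.sd) for s in specs}) > 1:
        raise ValueError(
            "analytic proportions require identical priors on all involved parameters "
            "(use method='monte_carlo')"
        )
    not_signed = dag_names - sign_constrained
    if not_signed:
        raise ValueError(
            f"quantities {sorted(not_signed)} are ordered but not sign-constrained; the "
            "sign/order factorization does not hold (use method='monte_carlo')"
        )
    return n_sign, sorted(dag_names)


def _linear_extension_fraction(constraint: ConstraintSpec, dag_names: list[str]) -> float:
    """Fraction of orderings of the DAG quantities consistent with the constraints."""
    if not dag_names:
        return 1.0
    if len(dag_names) > 8:
        raise ValueError("too many ordered quantities for exact enumeration")
    edges = [
        (i.larger, i.smaller)
        for i in constraint.inequalities
        if isinstance(i.larger, str) and isinstance(i.smaller, str)
    ]
    pos_of = {}
    count = 0
    total = 0
    for perm in itertools.permutations(dag_names):
        total += 1
        pos_of = {name: k for k, name in enumerate(perm)}  # rank 0 = largest
        if all(pos_of[a] < pos_of[b] for a, b in edges):
            count += 1
    return count / total


def prior_constraint_proportion(
    constraint: ConstraintSpec,
    prior: PriorSpec,
    model: MPTModel,
    method: Literal["analytic", "monte_carlo"] = "analytic",
    n_draws: int = 100_000,
    seed: int = 0,
    n_participants: int = 1,
    batch_size: int | None = None,
) -> float | MonteCarloEstimate:
    """Prior probability mass of the constrained region under the encompassing model.

    The analytic path applies when every constrained quantity is a difference
    of two distinct parameters with identical, independent, zero-symmetric
    group-mean priors and every ordered quantity is also sign-constrained;
    it returns ``0.5^m x (#linear extensions)/k!`` — e.g. 0.25 for two sign
    constraints and 0.125 with one added pairwise ordering.  Otherwise use
    Monte Carlo, which returns the conforming fraction of prior draws with
    its standard error.
    """
    if method == "analytic":
        n_sign, dag_names = _validate_analytic(constraint, prior)
        return 0.5**n_sign * _linear_extension_fraction(constraint, dag_names)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")

    individual = constraint.level == "every_individual"
    n_part = n_participants if individual else 1
    if batch_size is None:
        target = 20_000_000
        batch_size = max(1_000, min(n_draws, target // max(1, n_part * model.n_parameters)))
    conform = 0
    for batch_id, b, batch_seed in _batches(n_draws, batch_size, seed):
        if individual:
            ok = _marginal_individual_conform(
                constraint, prior, model, n_part, b, batch_seed
            )
        else:
            draws = draw_prior(prior, model, n_participants=1, n_draws=b, seed=batch_seed)
            ok = evaluate_constraint(constraint, draws, model)
        conform += int(ok.sum())
    p = conform / n_draws
    se = float(np.sqrt(max(p * (1.0 - p), 1.0 / n_draws) / n_draws))
    return MonteCarloEstimate(value=p, se=se, n=n_draws)


def _batches(n_draws: int, batch_size: int, seed: int):
    """Deterministic (id, size, seed) triples covering ``n_draws``."""
    root = np.random.SeedSequence(seed)
    remaining = n_draws
    batch_id = 0
    while remaining > 0:
        b = min(batch_size, remaining)
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(batch_id,))
        yield batch_id, b, int(child.generate_state(1)[0] % (2**31 - 1))
        remaining -= b
        batch_id += 1


def _marginal_individual_conform(
    constraint: ConstraintSpec,
    prior: PriorSpec,
    model: MPTModel,
    n_participants: int,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """All-participants-conform indicators, simulating only the needed parameters.

    The group structure (means, SDs, full correlation matrix) is drawn for the
    complete model so the implied marginal over the constrained parameters is
    exact; individual deviations are then drawn from that marginal MVN, which
    cuts memory and time by the ratio of constrained to total parameters.
    """
    from .priors import _draw_scale_structure  # shared sampling internals

    needed: set[str] = set()
    derived_needed: set[str] = set()
    for q in constraint.quantities.values():
        for name in q.expression.names:
            if name in model.derived:
                derived_needed.add(name)
                needed.update(model.derived[name].names)
            else:
                needed.add(name)
    sub = [p for p in model.parameters if p in needed]
    idx = np.array([model.parameters.index(p) for p in sub])

    rng = np.random.default_rng(seed)
    dim = model.n_parameters
    loc, sd = prior.means(model.parameters)
    mu = loc + sd * rng.standard_normal((n_draws, dim))
    sigma, chol_corr = _draw_scale_structure(prior, n_draws, dim, rng)
    corr = chol_corr @ np.swapaxes(chol_corr, -1, -2)
    corr_sub = corr[:, idx[:, None], idx[None, :]]
    sigma_sub = sigma[:, idx]
    cov_sub = corr_sub * (sigma_sub[:, :, None] * sigma_sub[:, None, :])
    chol_sub = np.linalg.cholesky(cov_sub + 1e-12 * np.eye(len(idx)))
    eps = rng.standard_normal((n_draws, n_participants, len(idx)))
    z = mu[:, None, idx] + eps @ np.swapaxes(chol_sub, -1, -2)

    from scipy.special import ndtr as _ndtr

    prob = {p: _ndtr(z[..., k]) for k, p in enumerate(sub)}
    for name in derived_needed:
        prob[name] = model.derived[name](prob)
    by_scale: dict[str, dict[str, np.ndarray]] = {"probability": prob}
    if any(q.scale == "probit" for q in constraint.quantities.values()):
        eps_c = 1e-12
        by_scale["probit"] = {
            k: probit(np.clip(v, eps_c, 1.0 - eps_c)) for k, v in prob.items()
        }
    values = {
        name: np.asarray(q.expression(by_scale[q.scale]), dtype=float)
        for name, q in constraint.quantities.items()
    }
    ok: np.ndarray | None = None
    for ineq in constraint.inequalities:
        larger = values[ineq.larger] if isinstance(ineq.larger, str) else ineq.larger
        smaller = values[ineq.smaller] if isinstance(ineq.smaller, str) else ineq.smaller
        this = np.asarray(larger > smaller)
        ok = this if ok is None else (ok & this)
    assert ok is not None
    return ok.all(axis=1)
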