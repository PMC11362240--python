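"""Multinomial processing tree (MPT) model structures.

An MPT model expresses the category probabilities of a multinomial task as
sums, over tree branches, of products of latent process probabilities.  The
canonical example here is the two-high-threshold source-monitoring model
(2HTSM): three trees (items from source A, items from source B, new items)
whose branches are governed by item memory ``D``, source memory ``d``, item
guessing ``b`` and source guessing ``g``.

Models carry *free* parameters (probabilities in [0, 1]) and optionally
*derived* parameters defined by arithmetic expressions over free parameters,
evaluated deterministically before branch products (e.g. the distractor
detection rate ``D_New = (D_A + D_B) / 2`` in the Bell-style variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expressions import Expression

__all__ = [
    "Factor",
    "Branch",
    "Tree",
    "MPTModel",
    "StructuralError",
    "category_probabilities",
    "build_2htsm",
    "build_2htsm_bell",
]


class StructuralError(ValueError):
    """Raised when a model violates MPT structural invariants."""


@dataclass(frozen=True)
class Factor:
    """One multiplicative factor of a branch: ``p``, ``1 - p`` or a constant."""

    name: str | None = None
    complement: bool = False
    constant: float | None = None

    def __post_init__(self) -> None:
        if (self.name is None) == (self.constant is None):
            raise ValueError("factor must reference a parameter or be a constant, not both")
        if self.constant is not None and not 0.0 <= self.constant <= 1.0:
            raise ValueError(f"constant factor {self.constant} outside [0, 1]")

    def to_eqn(self) -> str:
        if self.constant is not None:
            return repr(self.constant)
        return f"(1-{self.name})" if self.complement else str(self.name)


@dataclass(frozen=True)
class Branch:
    category: str
    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("branch factor list must be non-empty")


@dataclass(frozen=True)
class Tree:
    """A single response tree: ordered categories and their branches."""

    name: str
    categories: tuple[str, ...]
    branches: tuple[Branch, ...]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise StructuralError(f"duplicate category names in tree {self.name!r}")
        covered = {b.category for b in self.branches}
        missing = set(self.categories) - covered
        if missing:
            raise StructuralError(f"tree {self.name!r}: categories without branches: {sorted(missing)}")
        unknown = covered - set(self.categories)
        if unknown:
            raise StructuralError(f"tree {self.name!r}: branches map to unknown categories {sorted(unknown)}")


@dataclass(frozen=True)
class MPTModel:
    """An MPT model: free parameters, trees, and derived-parameter expressions."""

    parameters: tuple[str, ...]
    trees: tuple[Tree, ...]
    derived: dict[str, Expression] = field(default_factory=dict)
    name: str = "mpt"

    def __post_init__(self) -> None:
        if len(set(self.parameters)) != len(self.parameters):
            raise StructuralError("duplicate free-parameter names")
        clash = set(self.parameters) & set(self.derived)
        if clash:
            raise StructuralError(f"names both free and derived: {sorted(clash)}")
        known = set(self.parameters) | set(self.derived)
        for expr in self.derived.values():
            bad = set(expr.names) - set(self.parameters)
            if bad:
                raise StructuralError(
                    f"derived expression {expr.source!r} references undeclared parameters {sorted(bad)}"
                )
        for tree in self.trees:
            for branch in tree.branches:
                for factor in branch.factors:
                    if factor.name is not None and factor.name not in known:
                        raise StructuralError(
                            f"tree {tree.name!r} references undeclared parameter {factor.name!r}"
                        )

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def tree(self, name: str) -> Tree:
        for tree in self.trees:
            if tree.name == name:
                return tree
        raise KeyError(f"no tree named {name!r}")

    def tree_parameters(self, tree_name: str) -> frozenset[str]:
        """Free parameters a tree's branch terms depend on (resolving derived)."""
        names: set[str] = set()
        for branch in self.tree(tree_name).branches:
            for factor in branch.factors:
                if factor.name is None:
                    continue
                if factor.name in self.derived:
                    names.update(self.derived[factor.name].names)
                else:
                    names.add(factor.name)
        return frozenset(names)

    def full_theta(self, theta: Mapping[str, np.ndarray | float]) -> dict[str, np.ndarray | float]:
        """Extend a free-parameter assignment with the derived parameters."""
        missing = [p for p in self.parameters if p not in theta]
        if missing:
            raise KeyError(f"missing parameter value(s): {missing}")
        full = {p: theta[p] for p in self.parameters}
        for name, expr in self.derived.items():
            full[name] = expr(full)
        return full

    def validate_branch_sums(self, n_points: int = 100, tol: float = 1e-9, seed: int = 0) -> None:
        """Check every tree's branch products sum to one at quasi-random points."""
        rng = np.random.default_rng(seed)
        theta = {p: rng.uniform(0.0, 1.0, size=n_points) for p in self.parameters}
        probs = category_probabilities(self, theta)
        for tree in self.trees:
            total = np.sum(probs[tree.name], axis=-1)
            if not np.allclose(total, 1.0, atol=tol):
                raise StructuralError(
                    f"tree {tree.name!r}: branch products sum to {total.ravel()[:3]}... != 1; "
                    "the tree is not a valid MPT tree"
                )


def category_probabilities(
    model: MPTModel,
    theta: Mapping[str, np.ndarray | float],
    trees: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Evaluate per-tree category probabilities at a parameter assignment.

    ``theta`` maps each free parameter to a scalar or an array (arrays
    broadcast; the category axis is appended last).  Returns a dict mapping
    tree name to an array of shape ``(*batch, n_categories)``; ``trees``
    restricts evaluation to a subset.
    """
    full = model.full_theta(theta)
    full = {k: np.asarray(v, dtype=float) for k, v in full.items()}
    batch = np.broadcast_shapes(*(v.shape for v in full.values())) if full else ()
    selected = model.trees if trees is None else [model.tree(t) for t in trees]
    out: dict[str, np.ndarray] = {}
    for tree in selected:
        cat_index = {c: i for i, c in enumerate(tree.categories)}
        probs = np.zeros(batch + (len(tree.categories),))
        for branch in tree.branches:
            term = np.ones(batch)
            for factor in branch.factors:
                if factor.constant is not None:
                    term = term * factor.constant
                else:
                    value = full[factor.name]
                    term = term * ((1.0 - value) if factor.complement else value)
            probs[..., cat_index[branch.category]] += term
        out[tree.name] = probs
    return out


def _f(name: str, complement: bool = False) -> Factor:
    return Factor(name=name, complement=complement)


def _tree_source(
    name: str,
    D: str,
    d: str,
    b: str,
    g: str,
    own: str,
    other: str,
    new: str,
    guess_own_is_g: bool,
) -> Tree:
    """2HTSM tree for old items from source ``own``.

    Branches: detect+remember source -> own; detect without source memory ->
    guess between sources; no detection -> guess old (then guess source) or new.
    ``guess_own_is_g`` says whether guessing ``own`` happens with probability
    ``g`` (source A) or ``1 - g`` (source B).
    """
    g_own = _f(g, complement=not guess_own_is_g)
    g_other = _f(g, complement=guess_own_is_g)
    branches = (
        Branch(own, (_f(D), _f(d))),
        Branch(own, (_f(D), _f(d, True), g_own)),
        Branch(other, (_f(D), _f(d, True), g_other)),
        Branch(own, (_f(D, True), _f(b), g_own)),
        Branch(other, (_f(D, True), _f(b), g_other)),
        Branch(new, (_f(D, True), _f(b, True))),
    )
    return Tree(name, (own, other, new) if guess_own_is_g else (other, own, new), branches)


def _tree_new(name: str, D: str, b: str, g: str, first: str, second: str, new: str) -> Tree:
    branches = (
        Branch(new, (_f(D),)),
        Branch(first, (_f(D, True), _f(b), _f(g))),
        Branch(second, (_f(D, True), _f(b), _f(g, True))),
        Branch(new, (_f(D, True), _f(b, True))),
    )
    return Tree(name, (first, second, new), branches)


def build_2htsm() -> MPTModel:
    """The four-parameter 2HTSM (its most parsimonious submodel).

    Trees ``source_A``, ``source_B`` and ``new`` with categories A, B, New.
    ``D`` is item memory (and distractor detection), ``d`` source memory,
    ``b`` item guessing ("old"), ``g`` source guessing (guess "A").
    """
    trees = (
        _tree_source("source_A", "D", "d", "b", "g", "A", "B", "New", guess_own_is_g=True),
        _tree_source("source_B", "D", "d", "b", "g", "B", "A", "New", guess_own_is_g=False),
        _tree_new("new", "D", "b", "g", "A", "B", "New"),
    )
    model = MPTModel(parameters=("D", "d", "b", "g"), trees=trees, name="2htsm")
    model.validate_branch_sums()
    return model


def build_2htsm_bell(condition_labels: Sequence[str] = ("pleasant", "disgusting")) -> MPTModel:
    """Bell-style 2HTSM variant with two within-subject conditions.

    Per condition the model frees item memory and source memory separately per
    source (``D_A``, ``D_B``, ``d_A``, ``d_B``) plus item and source guessing
    (``b``, ``g``), with distractor detection for new items fixed to the mean
    item memory, ``D_New = (D_A + D_B) / 2``.  Twelve free parameters total.
    """
    labels = tuple(condition_labels)
    if len(labels) != 2 or labels[0] == labels[1]:
        raise ValueError(f"need two distinct condition labels, got {labels!r}")
    params: list[str] = []
    trees: list[Tree] = []
    derived: dict[str, Expression] = {}
    for cond in labels:
        DA, DB = f"D_A_{cond}", f"D_B_{cond}"
        dA, dB = f"d_A_{cond}", f"d_B_{cond}"
        b, g = f"b_{cond}", f"g_{cond}"
        Dnew = f"D_New_{cond}"
        params += [DA, DB, dA, dB, b, g]
        derived[Dnew] = Expression(f"({DA} + {DB}) / 2")
        trees += [
            _tree_source(f"source_A_{cond}", DA, dA, b, g, "A", "B", "New", guess_own_is_g=True),
            _tree_source(f"source_B_{cond}", DB, dB, b, g, "B", "A", "New", guess_own_is_g=False),
            _tree_new(f"new_{cond}", Dnew, b, g, "A", "B", "New"),
        ]
    model = MPTModel(parameters=tuple(params), trees=tuple(trees), derived=derived, name="2htsm_bell")
    model.validate_branch_sums()
    return model
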