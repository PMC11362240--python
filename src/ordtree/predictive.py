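"""Prior/posterior predictive simulation and Klauer-style T1/T2 fit checks.

``predictive_simulate`` replays the generative story for retained parameter
draws, producing replicated frequency tables.  ``t1_t2`` computes
posterior-predictive p-values for two discrepancy statistics: T1 compares the
observed mean category frequencies with their model expectation (Pearson-type
discrepancy), T2 does the analogous comparison for the across-participant
covariance matrix of category frequencies.  Under the joint draw of
parameters and replicated data, ``p = Pr(T(rep) >= T(obs))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FrequencyTable, StudyDesign
from .inference import FitResult
from .model import MPTModel, category_probabilities
from .priors import ParameterDraws

__all__ = [
    "PredictiveSample",
    "predictive_simulate",
    "t1_t2",
    "response_rate_summary",
    "response_probability_draws",
]


@dataclass
class PredictiveSample:
    """Replicated count tables: one (draws, participants, categories) array per tree."""

    counts: dict[str, np.ndarray]
    categories: dict[str, tuple[str, ...]]
    draw_indices: np.ndarray
    design: StudyDesign
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return len(self.draw_indices)


def _select_draws(n_total: int, n_rep: int) -> np.ndarray:
    """Evenly strided draw indices (thinning) covering the whole chain."""
    if n_rep >= n_total:
        return np.arange(n_total)
    return np.unique(np.linspace(0, n_total - 1, n_rep).astype(int))


def _tree_probabilities(
    model: MPTModel, theta_prob: np.ndarray
) -> dict[str, np.ndarray]:
    theta = {p: theta_prob[..., j] for j, p in enumerate(model.parameters)}
    probs = category_probabilities(model, theta)
    batch = theta_prob.shape[:-1]
    out = {}
    for t, p in probs.items():
        p = np.broadcast_to(p, batch + p.shape[-1:])  # constant-only trees
        out[t] = p / p.sum(axis=-1, keepdims=True)
    return out


def predictive_simulate(
    draws: ParameterDraws,
    model: MPTModel,
    design: StudyDesign,
    seed: int = 0,
    n_rep: int | None = None,
) -> PredictiveSample:
    """Simulate replicated datasets from retained (prior or posterior) draws."""
    if draws.n_participants != design.n_participants:
        raise ValueError(
            f"draws carry {draws.n_participants} participants but the design has "
            f"{design.n_participants}"
        )
    for tree in model.trees:
        if tree.name not in design.items_per_tree:
            raise ValueError(f"design lacks item count for tree {tree.name!r}")
    rng = np.random.default_rng(seed)
    idx = _select_draws(draws.n_draws, n_rep or draws.n_draws)
    theta = draws.individual_prob[idx]  # (J, I, P)
    probs = _tree_probabilities(model, theta)
    counts = {
        tree.name: rng.multinomial(design.items_per_tree[tree.name], probs[tree.name])
        for tree in model.trees
    }
    return PredictiveSample(
        counts=counts,
        categories={t.name: t.categories for t in model.trees},
        draw_indices=idx,
        design=design,
        seed=seed,
    )


def _concat_counts(counts: dict[str, np.ndarray], trees: list[str]) -> np.ndarray:
    """Stack per-tree count arrays along the category axis."""
    return np.concatenate([counts[t] for t in trees], axis=-1)


def _t1(mean_obs: np.ndarray, mean_exp: np.ndarray) -> float:
    mask = mean_exp > 0
    return float(np.sum((mean_obs[mask] - mean_exp[mask]) ** 2 / mean_exp[mask]))


def _t2(cov_obs: np.ndarray, cov_exp: np.ndarray) -> float:
    d = np.sqrt(np.abs(np.diag(cov_exp)))
    d = np.where(d > 0, d, 1.0)
    scale = np.outer(d, d)
    iu = np.triu_indices(cov_exp.shape[0])
    return float(np.sum(((cov_obs - cov_exp)[iu] / scale[iu]) ** 2))


def t1_t2(
    fit: FitResult,
    data: FrequencyTable,
    model: MPTModel,
    n_rep: int = 1_000,
    seed: int = 0,
) -> dict[str, float | None]:
    """Posterior-predictive p-values for mean (T1) and covariance (T2) structure.

    For each retained posterior draw the expected frequencies (and their
    across-participant covariance, including multinomial sampling noise) are
    computed analytically; one replicated dataset per draw provides the
    reference distribution.  Ties count as exceedances.  With a single
    participant T2 is undefined and reported as ``None``.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100 for stable p-values")
    data.check_against_model(model)
    draws = fit.draws
    rng = np.random.default_rng(seed)
    idx = _select_draws(draws.n_draws, n_rep)
    theta = draws.individual_prob[idx]  # (J, I, P)
    probs = _tree_probabilities(model, theta)
    trees = [t.name for t in model.trees]
    items = np.concatenate(
        [
            np.full(len(model.tree(t).categories), data.items_per_tree[t])
            for t in trees
        ]
    )
    n_i = data.n_participants
    obs = _concat_counts(data.counts, trees).astype(float)  # (I, C)
    mean_obs = obs.mean(axis=0)
    cov_obs = np.cov(obs, rowvar=False, ddof=1) if n_i > 1 else None

    expected = np.concatenate(
        [data.items_per_tree[t] * probs[t] for t in trees], axis=-1
    )  # (J, I, C)
    rep = np.concatenate(
        [rng.multinomial(data.items_per_tree[t], probs[t]) for t in trees], axis=-1
    ).astype(float)

    t1_obs = np.empty(len(idx))
    t1_rep = np.empty(len(idx))
    t2_obs = np.empty(len(idx))
    t2_rep = np.empty(len(idx))
    for j in range(len(idx)):
        e = expected[j]
        mean_exp = e.mean(axis=0)
        t1_obs[j] = _t1(mean_obs, mean_exp)
        t1_rep[j] = _t1(rep[j].mean(axis=0), mean_exp)
        if cov_obs is not None:
            # expected covariance: spread of expectations + multinomial noise
            cov_e = np.cov(e, rowvar=False, ddof=1)
            noise = np.zeros_like(cov_e)
            offset = 0
            for t in trees:
                k = len(model.tree(t).categories)
                p = probs[t][j]  # (I, K)
                n_items = data.items_per_tree[t]
                mean_diag = np.mean(p, axis=0)
                block = n_items * (np.diag(mean_diag) - np.einsum("ik,il->kl", p, p) / n_i)
                noise[offset : offset + k, offset : offset + k] = block
                offset += k
            cov_exp = cov_e + noise
            t2_obs[j] = _t2(cov_obs, cov_exp)
            t2_rep[j] = _t2(np.cov(rep[j], rowvar=False, ddof=1), cov_exp)

    out: dict[str, float | None] = {
        "p_T1": float(np.mean(t1_rep >= t1_obs)),
        "p_T2": float(np.mean(t2_rep >= t2_obs)) if cov_obs is not None else None,
        "n_rep": len(idx),
    }
    if cov_obs is None:
        out["note"] = "single participant: T2 undefined"
    return out


def response_probability_draws(
    draws: ParameterDraws, model: MPTModel, tree: str, category: str
) -> np.ndarray:
    """Per-draw, per-participant probability of one response category (J, I)."""
    t = model.tree(tree)
    if category not in t.categories:
        raise KeyError(f"tree {tree!r} has no category {category!r}")
    probs = _tree_probabilities(model, draws.individual_prob)
    return probs[tree][..., t.categories.index(category)]


def response_rate_summary(
    pred: PredictiveSample, tree: str, category: str, bins: int = 20
) -> dict:
    """Distribution summary of predicted response rates for one category.

    The per-draw rate is the replicated count share pooled over participants.
    """
    if pred.n_draws == 0:
        raise ValueError("empty predictive sample")
    if tree not in pred.counts:
        raise KeyError(f"no tree {tree!r} in predictive sample")
    cats = pred.categories[tree]
    if category not in cats:
        raise KeyError(f"tree {tree!r} has no category {category!r}")
    j = cats.index(category)
    counts = pred.counts[tree]  # (J, I, K)
    rates = counts[..., j].sum(axis=1) / counts.sum(axis=(1, 2))
    hist, edges = np.histogram(rates, bins=bins, range=(0.0, 1.0))
    qs = np.quantile(rates, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "mean": float(rates.mean()),
        "sd": float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        "quantiles": dict(zip(["2.5%", "25%", "50%", "75%", "97.5%"], map(float, qs))),
        "histogram": (hist, edges),
        "n_draws": int(pred.n_draws),
    }
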