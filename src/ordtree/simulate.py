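"""Generate synthetic source-monitoring datasets from the hierarchical model.

The generator instantiates the full generative story: group probit means,
individual deviations drawn from the multivariate normal, probit-inverse to
probabilities, and per-tree multinomial counts.  A ``TruthRecord`` travels
with each dataset so parameter-recovery studies can score estimates against
the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .data import FrequencyTable, StudyDesign
from .model import MPTModel, category_probabilities
from .priors import PriorSpec, draw_prior, probit

__all__ = [
    "TruthRecord",
    "illustrative_truth",
    "generate_dataset",
    "recovery_report",
]


@dataclass
class TruthRecord:
    """Generating values of a synthetic dataset (probit-scale group structure)."""

    parameters: tuple[str, ...]
    group_mu: np.ndarray  # (P,) probit scale
    sigma: np.ndarray  # (P,)
    corr: np.ndarray  # (P, P)
    individual_prob: np.ndarray | None = None  # (I, P), filled by the generator
    seed: int | None = None

    @property
    def group_prob(self) -> np.ndarray:
        """Probability-scale group medians Phi(mu)."""
        return ndtr(self.group_mu)

    def group_prob_dict(self) -> dict[str, float]:
        return dict(zip(self.parameters, map(float, self.group_prob)))

    def to_json(self) -> str:
        payload = {
            "parameters": list(self.parameters),
            "group_mu": self.group_mu.tolist(),
            "sigma": self.sigma.tolist(),
            "corr": self.corr.tolist(),
            "seed": self.seed,
        }
        if self.individual_prob is not None:
            payload["individual_prob"] = self.individual_prob.tolist()
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        payload = json.loads(text)
        return cls(
            parameters=tuple(payload["parameters"]),
            group_mu=np.asarray(payload["group_mu"]),
            sigma=np.asarray(payload["sigma"]),
            corr=np.asarray(payload["corr"]),
            individual_prob=(
                np.asarray(payload["individual_prob"])
                if "individual_prob" in payload
                else None
            ),
            seed=payload.get("seed"),
        )


_ILLUSTRATIVE_BASE = {"D": 0.5, "d": 0.3, "b": 0.5, "g": 0.5}


def illustrative_truth(
    model: MPTModel,
    group_prob: Mapping[str, float] | None = None,
    sigma: float | Sequence[float] = 0.4,
    corr: np.ndarray | None = None,
) -> TruthRecord:
    """Demo truth with realistic source-monitoring magnitudes.

    Defaults (item memory around .5, source memory around .3, guessing around
    .5) mirror the magnitudes typically estimated in face/behavior source
    studies; they are illustrative, not ground truth for any experiment.
    """
    prob = {}
    for p in model.parameters:
        if group_prob and p in group_prob:
            prob[p] = group_prob[p]
        else:
            prob[p] = _ILLUSTRATIVE_BASE.get(p.split("_")[0], 0.5)
    dim = model.n_parameters
    sigma_arr = np.broadcast_to(np.asarray(sigma, dtype=float), (dim,)).copy()
    corr_arr = np.eye(dim) if corr is None else np.asarray(corr, dtype=float)
    return TruthRecord(
        parameters=model.parameters,
        group_mu=probit(np.array([prob[p] for p in model.parameters])),
        sigma=sigma_arr,
        corr=corr_arr,
    )


def _truth_from_prior(model: MPTModel, prior: PriorSpec, seed: int) -> TruthRecord:
    one = draw_prior(prior, model, n_participants=1, n_draws=1, seed=seed)
    return TruthRecord(
        parameters=model.parameters,
        group_mu=one.group_mu[0],
        sigma=one.sigma[0],
        corr=one.corr[0],
    )


def generate_dataset(
    model: MPTModel,
    design: StudyDesign,
    truth: TruthRecord | PriorSpec | None = None,
    seed: int = 0,
) -> tuple[FrequencyTable, TruthRecord]:
    """Simulate one dataset; returns the table plus the completed truth record.

    ``truth`` may be a :class:`TruthRecord`, a :class:`PriorSpec` (the truth is
    then itself drawn from that prior), or ``None`` for the illustrative
    defaults.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = illustrative_truth(model)
    elif isinstance(truth, PriorSpec):
        truth = _truth_from_prior(model, truth, seed=rng.integers(2**31 - 1))
    if tuple(truth.parameters) != tuple(model.parameters):
        raise ValueError("truth parameters do not match the model")
    for tree in model.trees:
        if tree.name not in design.items_per_tree:
            raise ValueError(f"design lacks an item count for model tree {tree.name!r}")

    dim = model.n_parameters
    n = design.n_participants
    cov_chol = np.linalg.cholesky(
        truth.corr * np.outer(truth.sigma, truth.sigma) + 1e-12 * np.eye(dim)
    )
    z = truth.group_mu + rng.standard_normal((n, dim)) @ cov_chol.T
    theta_prob = ndtr(z)
    theta = {p: theta_prob[:, j] for j, p in enumerate(model.parameters)}
    probs = category_probabilities(model, theta)

    counts: dict[str, np.ndarray] = {}
    categories: dict[str, tuple[str, ...]] = {}
    for tree in model.trees:
        items = design.items_per_tree[tree.name]
        p = probs[tree.name]
        p = p / p.sum(axis=-1, keepdims=True)  # guard against fp drift in multinomial
        counts[tree.name] = rng.multinomial(items, p)
        categories[tree.name] = tree.categories
    table = FrequencyTable(
        participants=tuple(f"p{i + 1}" for i in range(n)),
        categories=categories,
        counts=counts,
        items_per_tree={t.name: design.items_per_tree[t.name] for t in model.trees},
    )
    completed = TruthRecord(
        parameters=truth.parameters,
        group_mu=truth.group_mu,
        sigma=truth.sigma,
        corr=truth.corr,
        individual_prob=theta_prob,
        seed=seed,
    )
    return table, completed


def write_dataset(
    table: FrequencyTable, truth: TruthRecord, path: str | Path
) -> tuple[Path, Path]:
    """Write the table and its truth sidecar; returns both paths."""
    path = Path(path)
    truth_path = path.with_suffix(".truth.json")
    table.write_csv(path)
    truth_path.write_text(truth.to_json())
    return path, truth_path


def recovery_report(
    fits: "FitResult | Sequence[FitResult]",  # noqa: F821 - forward ref, see inference
    truths: TruthRecord | Sequence[TruthRecord],
    interval_mass: float = 0.95,
):
    """Score posterior fits against generating values.

    For each free parameter, compares the posterior probability-scale group
    median ``Phi(mu_p)`` against the generating ``Phi(mu_p)``: bias (mean
    error across fits), RMSE, and coverage of the central credible interval.
    With a single fit the report degenerates gracefully (RMSE = |bias|,
    coverage in {0, 1}).
    """
    import pandas as pd

    if not isinstance(fits, Sequence):
        fits = [fits]
    if isinstance(truths, TruthRecord):
        truths = [truths]
    if len(fits) != len(truths):
        raise ValueError("need one truth record per fit")
    parameters = truths[0].parameters
    lo_q = (1.0 - interval_mass) / 2.0
    errors = {p: [] for p in parameters}
    covered = {p: [] for p in parameters}
    for fit, truth in zip(fits, truths):
        draws = fit.draws
        true_prob = truth.group_prob_dict()
        for p in parameters:
            samples = draws.group_prob[:, draws.index(p)]
            est = float(np.mean(samples))
            errors[p].append(est - true_prob[p])
            lo, hi = np.quantile(samples, [lo_q, 1.0 - lo_q])
            covered[p].append(lo <= true_prob[p] <= hi)
    rows = []
    for p in parameters:
        err = np.asarray(errors[p])
        rows.append(
            {
                "parameter": p,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "coverage": float(np.mean(covered[p])),
                "n_fits": len(err),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
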