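"""Hierarchical latent-trait prior structure for MPT parameters.

Individual MPT parameters are probit-transformed to a latent space where
participant vectors follow a multivariate normal around group-level means:

    theta_ip = Phi(mu_p + delta_ip),   delta_i ~ MVN(0, Sigma),
    Sigma = diag(sigma) * Omega * diag(sigma).

Priors live on the group means (normal, per parameter), the deviation scales
``sigma`` and the correlation matrix ``Omega``.  Two named presets are
provided:

``informative``
    Normal(0, 0.28) probit means for guessing-type parameters (mildly
    favoring the nominal guessing level 0.5), Normal(0, 1) for memory-type
    parameters, sigma ~ Gamma(shape 2, rate 3), Omega ~ LKJ(1).

``matzke_klauer``
    Normal(0, 1) probit means for all parameters (uniform implied
    probability-scale prior) and the TreeBUGS-style covariance construction:
    precision ~ Wishart(identity scale, df = P + 1) with parameter-expanded
    scaling factors xi ~ Uniform(0, 10).  Seemingly vague, this construction
    places heavy prior mass on extreme individual-level parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from .model import MPTModel

__all__ = [
    "probit",
    "probit_inverse",
    "NormalSpec",
    "GammaSpec",
    "FixedSpec",
    "LKJSpec",
    "TreeBUGSDeviation",
    "PriorSpec",
    "ParameterDraws",
    "MonteCarloEstimate",
    "parameter_types",
    "informative_preset",
    "matzke_klauer_preset",
    "draw_prior",
    "extremeness_index",
    "group_prob_summary",
    "sample_lkj_cholesky",
]


def probit(p):
    """Probit transform: the standard-normal quantile function."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("probit requires values strictly inside (0, 1)")
    out = ndtri(p)
    return float(out) if out.ndim == 0 else out


def probit_inverse(z):
    """Inverse probit: the standard-normal CDF, mapping latent values to (0, 1)."""
    out = ndtr(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NormalSpec:
    """Normal prior on a probit-scale group mean.

    ``scale_is`` selects whether ``scale`` is read as a standard deviation
    (default) or a variance.
    """

    loc: float = 0.0
    scale: float = 1.0
    scale_is: Literal["sd", "var"] = "sd"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def sd(self) -> float:
        return self.scale if self.scale_is == "sd" else float(np.sqrt(self.scale))


@dataclass(frozen=True)
class GammaSpec:
    """Gamma(shape, rate) prior on a probit-scale deviation SD."""

    shape: float = 2.0
    rate: float = 3.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def median(self) -> float:
        return float(stats.gamma.ppf(0.5, self.shape, scale=1.0 / self.rate))


@dataclass(frozen=True)
class FixedSpec:
    """Deviation SD fixed at a constant (0 collapses the hierarchy)."""

    value: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("fixed deviation must be non-negative")


@dataclass(frozen=True)
class LKJSpec:
    """LKJ(eta) prior on the correlation matrix."""

    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("LKJ eta must be positive")


@dataclass(frozen=True)
class TreeBUGSDeviation:
    """TreeBUGS-style covariance construction (Wishart precision + expansion).

    Precision ~ Wishart(identity scale, ``df``; default P + 1) and
    parameter-expanded scaling factors xi_p ~ Uniform(0, ``xi_upper``); the
    implied deviation SD is sigma_p = xi_p * sqrt(V_pp) with V the inverse
    Wishart draw, and the correlation matrix is V rescaled to unit diagonal.
    """

    df: int | None = None
    xi_upper: float = 10.0


DeviationSpec = GammaSpec | FixedSpec | TreeBUGSDeviation


@dataclass(frozen=True)
class PriorSpec:
    """Complete prior specification for a latent-trait MPT model."""

    group_mean: dict[str, NormalSpec]
    deviation: DeviationSpec = field(default_factory=GammaSpec)
    correlation: LKJSpec | None = field(default_factory=LKJSpec)
    preset: str | None = None

    def validate(self, model: MPTModel) -> None:
        missing = [p for p in model.parameters if p not in self.group_mean]
        if missing:
            raise ValueError(f"no group-mean prior for parameter(s): {missing}")
        if isinstance(self.deviation, TreeBUGSDeviation) and self.correlation is not None:
            raise ValueError("TreeBUGS deviation construction induces its own correlation prior")
        if isinstance(self.deviation, (GammaSpec, FixedSpec)) and self.correlation is None:
            raise ValueError("gamma/fixed deviation priors require a correlation spec")

    def means(self, parameters: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        loc = np.array([self.group_mean[p].loc for p in parameters])
        sd = np.array([self.group_mean[p].sd for p in parameters])
        return loc, sd


@dataclass
class MonteCarloEstimate:
    """A Monte-Carlo proportion/mean with its standard error."""

    value: float
    se: float
    n: int

    def __float__(self) -> float:
        return self.value


@dataclass
class ParameterDraws:
    """Matched group-, scale- and individual-level draws (prior or posterior).

    Shapes: ``group_mu`` and ``sigma`` are (draws, P); ``corr`` is
    (draws, P, P); ``individual_probit``/``individual_prob`` are
    (draws, participants, P).
    """

    parameters: tuple[str, ...]
    group_mu: np.ndarray
    sigma: np.ndarray
    corr: np.ndarray
    individual_probit: np.ndarray
    provenance: Literal["prior", "posterior"]
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.group_mu.shape[0]

    @property
    def n_participants(self) -> int:
        return self.individual_probit.shape[1]

    @property
    def individual_prob(self) -> np.ndarray:
        return ndtr(self.individual_probit)

    @property
    def group_prob(self) -> np.ndarray:
        """Probability-scale group-level values Phi(mu) (group medians)."""
        return ndtr(self.group_mu)

    def index(self, parameter: str) -> int:
        try:
            return self.parameters.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}") from None

    def group_prob_dict(self) -> dict[str, np.ndarray]:
        return {p: self.group_prob[:, i] for i, p in enumerate(self.parameters)}

    def individual_prob_dict(self) -> dict[str, np.ndarray]:
        prob = self.individual_prob
        return {p: prob[:, :, i] for i, p in enumerate(self.parameters)}


_MEMORY_BASES = {"D", "d"}
_GUESSING_BASES = {"b", "g"}


def parameter_types(
    model: MPTModel, overrides: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Tag each free parameter as ``memory`` or ``guessing``.

    The tag is inferred from the base name (the part before the first
    underscore): D/d are memory processes, b/g guessing processes.  Anything
    else must be supplied via ``overrides``.
    """
    overrides = dict(overrides or {})
    types: dict[str, str] = {}
    for p in model.parameters:
        if p in overrides:
            kind = overrides[p]
            if kind not in ("memory", "guessing"):
                raise ValueError(f"parameter type for {p!r} must be 'memory' or 'guessing'")
            types[p] = kind
            continue
        base = p.split("_")[0]
        if base in _MEMORY_BASES:
            types[p] = "memory"
        elif base in _GUESSING_BASES:
            types[p] = "guessing"
        else:
            raise ValueError(
                f"cannot infer type of parameter {p!r}; pass overrides={{'{p}': 'memory'|'guessing'}}"
            )
    return types


def informative_preset(
    model: MPTModel,
    overrides: Mapping[str, str] | None = None,
    guessing_sd: float = 0.28,
) -> PriorSpec:
    """Theory-informed priors: guessing near chance, constrained heterogeneity."""
    types = parameter_types(model, overrides)
    group = {
        p: NormalSpec(0.0, guessing_sd if types[p] == "guessing" else 1.0)
        for p in model.parameters
    }
    return PriorSpec(
        group_mean=group,
        deviation=GammaSpec(2.0, 3.0),
        correlation=LKJSpec(1.0),
        preset="informative",
    )


def matzke_klauer_preset(
    model: MPTModel, overrides: Mapping[str, str] | None = None
) -> PriorSpec:
    """The TreeBUGS-default latent-trait priors (uniform implied group means)."""
    parameter_types(model, overrides)  # validates that every parameter is taggable
    group = {p: NormalSpec(0.0, 1.0) for p in model.parameters}
    return PriorSpec(
        group_mean=group,
        deviation=TreeBUGSDeviation(),
        correlation=None,
        preset="matzke_klauer",
    )


def sample_lkj_cholesky(
    n: int, dim: int, eta: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample lower Cholesky factors of LKJ(eta) correlation matrices (onion method)."""
    L = np.zeros((n, dim, dim))
    L[:, 0, 0] = 1.0
    beta = eta + (dim - 2) / 2.0
    for i in range(1, dim):
        y = rng.beta(i / 2.0, beta, size=n)
        beta -= 0.5
        u = rng.standard_normal((n, i))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        L[:, i, :i] = np.sqrt(y)[:, None] * u
        L[:, i, i] = np.sqrt(1.0 - y)
    return L


def _draw_scale_structure(
    prior: PriorSpec, n_draws: int, dim: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (sigma, corr_cholesky) of shape (n, P) and (n, P, P)."""
    dev = prior.deviation
    if isinstance(dev, FixedSpec):
        sigma = np.full((n_draws, dim), dev.value)
        chol = np.broadcast_to(np.eye(dim), (n_draws, dim, dim)).copy()
        return sigma, chol
    if isinstance(dev, GammaSpec):
        sigma = rng.gamma(dev.shape, scale=1.0 / dev.rate, size=(n_draws, dim))
        eta = prior.correlation.eta if prior.correlation is not None else 1.0
        chol = (
            sample_lkj_cholesky(n_draws, dim, eta, rng)
            if dim > 1
            else np.ones((n_draws, 1, 1))
        )
        return sigma, chol
    if isinstance(dev, TreeBUGSDeviation):
        df = dev.df if dev.df is not None else dim + 1
        precision = stats.wishart.rvs(df=df, scale=np.eye(dim), size=n_draws, random_state=rng)
        precision = precision.reshape(n_draws, dim, dim)
        V = np.linalg.inv(precision)
        xi = rng.uniform(0.0, dev.xi_upper, size=(n_draws, dim))
        v_sd = np.sqrt(np.einsum("npp->np", V))
        sigma = xi * v_sd
        corr = V / (v_sd[:, :, None] * v_sd[:, None, :])
        chol = np.linalg.cholesky(_nearest_pd_jitter(corr))
        return sigma, chol
    raise TypeError(f"unknown deviation spec {type(dev).__name__}")


def _nearest_pd_jitter(corr: np.ndarray, max_tries: int = 5) -> np.ndarray:
    """Add a tiny diagonal jitter to correlation draws that fail Cholesky."""
    out = corr.copy()
    eps = 1e-12
    for _ in range(max_tries):
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            dim = out.shape[-1]
            out = out + eps * np.eye(dim)
            out /= np.sqrt(np.einsum("...pp->...p", out))[..., :, None]
            out /= np.sqrt(np.einsum("...pp->...p", out))[..., None, :]
            eps *= 100
    return out


def draw_prior(
    prior: PriorSpec,
    model: MPTModel,
    n_participants: int,
    n_draws: int,
    seed: int,
) -> ParameterDraws:
    """Draw jointly from the hierarchical prior.

    Returns matched group-level, scale and individual-level draws; individual
    probit vectors are ``mu + L_sigma @ eps`` with ``L_sigma`` the Cholesky
    factor of the full covariance.
    """
    if n_participants < 1 or n_draws < 1:
        raise ValueError("n_participants and n_draws must be >= 1")
    prior.validate(model)
    rng = np.random.default_rng(seed)
    dim = model.n_parameters
    loc, sd = prior.means(model.parameters)
    mu = loc + sd * rng.standard_normal((n_draws, dim))
    sigma, chol_corr = _draw_scale_structure(prior, n_draws, dim, rng)
    scale_chol = sigma[:, :, None] * chol_corr  # Cholesky of diag(s) Omega diag(s)
    eps = rng.standard_normal((n_draws, n_participants, dim))
    delta = eps @ np.swapaxes(scale_chol, -1, -2)
    individual_probit = mu[:, None, :] + delta
    corr = chol_corr @ np.swapaxes(chol_corr, -1, -2)
    return ParameterDraws(
        parameters=model.parameters,
        group_mu=mu,
        sigma=sigma,
        corr=corr,
        individual_probit=individual_probit,
        provenance="prior",
        seed=seed,
    )


def extremeness_index(
    draws: ParameterDraws, parameter: str, band: float = 0.1
) -> MonteCarloEstimate:
    """Proportion of individual-level prior mass within ``band`` of 0 or 1.

    A large index is the signature of the mixture-of-extreme-populations
    pathology: the prior expects participants who almost always or almost
    never engage the process.
    """
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    if not 0 < band < 0.5:
        raise ValueError("band must be in (0, 0.5)")
    prob = draws.individual_prob[:, :, draws.index(parameter)]
    extreme = (prob <= band) | (prob >= 1.0 - band)
    per_draw = extreme.mean(axis=1)  # participants within a draw share group parameters
    value = float(per_draw.mean())
    se = float(per_draw.std(ddof=1) / np.sqrt(draws.n_draws)) if draws.n_draws > 1 else np.inf
    return MonteCarloEstimate(value=value, se=se, n=draws.n_draws)


def group_prob_summary(draws: ParameterDraws, parameter: str) -> dict[str, float]:
    """Probability-scale location summaries of a group-level parameter.

    Because the probit transform is nonlinear, ``Phi(mu_p)`` is the
    group-level *median* on the probability scale, not the mean.  The
    individual-level mean is computed in closed form per draw as
    ``Phi(mu / sqrt(1 + sigma^2))`` and averaged over draws.
    """
    j = draws.index(parameter)
    mu = draws.group_mu[:, j]
    sigma = draws.sigma[:, j]
    median = float(ndtr(np.median(mu)))
    mean = float(np.mean(ndtr(mu / np.sqrt(1.0 + sigma**2))))
    return {"median": median, "mean": mean}


def replace_deviation(prior: PriorSpec, deviation: DeviationSpec) -> PriorSpec:
    """A copy of ``prior`` with the deviation spec replaced (hierarchy knobs)."""
    correlation = prior.correlation
    if isinstance(deviation, TreeBUGSDeviation):
        correlation = None
    elif correlation is None:
        correlation = LKJSpec(1.0)
    return replace(prior, deviation=deviation, correlation=correlation, preset=None)
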