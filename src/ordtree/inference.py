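"""Posterior sampling for the hierarchical latent-trait MPT model.

The joint model: per participant ``i`` and tree ``t``, counts follow a
multinomial with category probabilities given by the MPT equations at
``theta_i = Phi(z_i)``; the probit vectors ``z_i`` follow MVN(mu, Sigma);
priors on ``mu`` (independent normals), on the deviation SDs (gamma, fixed,
or the Wishart-based TreeBUGS construction) and on the correlation matrix
(LKJ) complete the specification.

The sampler is an adaptive Metropolis-within-Gibbs over the unconstrained
parameterization:

* individual probit vectors — vectorized per-participant random-walk MH;
* group means ``mu`` — exact conjugate Gibbs given ``z`` and ``Sigma``
  (or, when the hierarchy is collapsed, random-walk MH on ``mu`` directly);
* ``log sigma`` — joint random-walk MH with the gamma prior and Jacobian;
* correlation off-diagonals — random-walk MH with a Cholesky
  positive-definiteness check and the LKJ density;
* TreeBUGS construction — conjugate inverse-Wishart Gibbs for the scale
  matrix plus MH on the parameter-expansion factors ``xi``.

Proposal scales adapt during warmup by Robbins–Monro toward standard
acceptance targets and are frozen afterwards.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, ndtr

from .data import FrequencyTable
from .model import MPTModel
from .priors import (
    FixedSpec,
    GammaSpec,
    ParameterDraws,
    PriorSpec,
    TreeBUGSDeviation,
)

__all__ = [
    "McmcSettings",
    "FitResult",
    "log_likelihood",
    "fit_posterior",
    "diagnostics",
]

_TARGET_MULTI = 0.234
_TARGET_UNI = 0.44


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run configuration (draws are per chain, post-warmup)."""

    draws: int = 50_000
    warmup: int = 10_000
    chains: int = 3
    seed: int = 0
    thin: int = 1
    init_jitter: float = 0.1
    max_init_retries: int = 10

    def __post_init__(self) -> None:
        if self.draws < 1 or self.warmup < 0 or self.chains < 1 or self.thin < 1:
            raise ValueError("invalid MCMC settings")

    @classmethod
    def smoke(cls, seed: int = 0, chains: int = 2) -> "McmcSettings":
        """Desk-scale profile for tests and quick exploration."""
        return cls(draws=2_000, warmup=1_000, chains=chains, seed=seed)

    @classmethod
    def paper(cls, seed: int = 0) -> "McmcSettings":
        """The full-scale profile: 50,000 retained draws after 10,000 burn-in."""
        return cls(draws=50_000, warmup=10_000, chains=3, seed=seed)


class _CompiledLikelihood:
    """Multinomial log-likelihood of a frequency table, vectorized over participants."""

    def __init__(self, model: MPTModel, data: FrequencyTable):
        data.check_against_model(model)
        self.model = model
        self.parameters = model.parameters
        self.counts = {t.name: data.counts[t.name] for t in model.trees}
        self.n_participants = data.n_participants
        const = np.zeros(self.n_participants)
        for tree in model.trees:
            c = self.counts[tree.name]
            const += gammaln(c.sum(axis=1) + 1.0) - gammaln(c + 1.0).sum(axis=1)
        self.log_coefficient = const
        # which trees each parameter column touches (for componentwise moves)
        self.tree_names = tuple(t.name for t in model.trees)
        self.trees_of_param = tuple(
            tuple(t for t in self.tree_names if p in model.tree_parameters(t))
            for p in self.parameters
        )
        # precompiled evaluation plan: extended columns = free params + derived
        n_free = len(self.parameters)
        self._col = {p: j for j, p in enumerate(self.parameters)}
        self._derived = []  # (column, Expression)
        for name, expr in model.derived.items():
            self._col[name] = n_free + len(self._derived)
            self._derived.append((self._col[name], expr))
        self._n_ext = n_free + len(self._derived)
        self._plan: dict[str, list] = {}
        self._n_categories = {}
        for tree in model.trees:
            cat_index = {c: i for i, c in enumerate(tree.categories)}
            branches = []
            for branch in tree.branches:
                factors = [
                    (self._col[f.name], f.complement) if f.name is not None else f.constant
                    for f in branch.factors
                ]
                branches.append((cat_index[branch.category], factors))
            self._plan[tree.name] = branches
            self._n_categories[tree.name] = len(tree.categories)

    def _extend(self, theta_prob: np.ndarray) -> np.ndarray:
        if not self._derived:
            return theta_prob
        ext = np.empty(theta_prob.shape[:-1] + (self._n_ext,))
        ext[..., : theta_prob.shape[-1]] = theta_prob
        views = {p: theta_prob[..., j] for j, p in enumerate(self.parameters)}
        for col, expr in self._derived:
            ext[..., col] = expr(views)
        return ext

    def by_tree(
        self, theta_prob: np.ndarray, trees: tuple[str, ...] | None = None
    ) -> dict[str, np.ndarray]:
        """Per-tree log-likelihood contributions per participant."""
        ext = self._extend(theta_prob)
        out: dict[str, np.ndarray] = {}
        batch = theta_prob.shape[:-1]
        for tree_name in trees if trees is not None else self.tree_names:
            probs = np.zeros(batch + (self._n_categories[tree_name],))
            for cat_idx, factors in self._plan[tree_name]:
                term = None
                for f in factors:
                    if isinstance(f, tuple):
                        col, complement = f
                        v = 1.0 - ext[..., col] if complement else ext[..., col]
                    else:
                        v = f
                    term = v if term is None else term * v
                probs[..., cat_idx] += term
            c = self.counts[tree_name]
            with np.errstate(divide="ignore", invalid="ignore"):
                logp = np.where(probs > 0.0, np.log(np.maximum(probs, 1e-300)), -np.inf)
                term = np.where(c > 0, c * logp, 0.0)
            out[tree_name] = term.sum(axis=-1)
        return out

    def __call__(self, theta_prob: np.ndarray, include_coefficient: bool = False) -> np.ndarray:
        """Log-likelihood per participant at probability-scale parameters (I, P)."""
        contributions = self.by_tree(theta_prob)
        total = np.zeros(theta_prob.shape[:-1])
        for value in contributions.values():
            total = total + value
        if include_coefficient:
            total = total + self.log_coefficient
        return total


def log_likelihood(
    model: MPTModel,
    theta_individual: Mapping[str, np.ndarray | float] | np.ndarray,
    data: FrequencyTable,
) -> np.ndarray:
    """Multinomial log-likelihood per participant, including the coefficient.

    ``theta_individual`` maps each free parameter to a scalar or a length-I
    array (or is an (I, P) array in model parameter order).
    """
    compiled = _CompiledLikelihood(model, data)
    if isinstance(theta_individual, Mapping):
        cols = []
        for p in model.parameters:
            if p not in theta_individual:
                raise KeyError(f"missing parameter {p!r}")
            cols.append(np.broadcast_to(np.asarray(theta_individual[p], dtype=float), (data.n_participants,)))
        theta = np.stack(cols, axis=-1)
    else:
        theta = np.asarray(theta_individual, dtype=float)
        if theta.shape != (data.n_participants, model.n_parameters):
            raise ValueError(
                f"theta shape {theta.shape} != ({data.n_participants}, {model.n_parameters})"
            )
    if np.any((theta < 0.0) | (theta > 1.0)):
        raise ValueError("individual parameters must lie in [0, 1]")
    return compiled(theta, include_coefficient=True)


@dataclass
class FitResult:
    """Posterior draws plus convergence diagnostics and provenance."""

    draws: ParameterDraws
    rhat: dict[str, float]
    ess: dict[str, float]
    accept_rates: dict[str, float]
    settings: McmcSettings
    warnings: list[str] = field(default_factory=list)
    fingerprints: dict[str, str] = field(default_factory=dict)
    chain_group_mu: np.ndarray | None = None  # (chains, draws, P)
    chain_sigma: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.n_draws


def _fingerprint(*parts: str) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(part.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def _prior_fingerprints(model: MPTModel, prior: PriorSpec, data: FrequencyTable) -> dict[str, str]:
    return {
        "model": _fingerprint(repr(model.parameters), repr([t.name for t in model.trees])),
        "prior": _fingerprint(repr(prior)),
        "data": _fingerprint(repr({t: c.tolist() for t, c in data.counts.items()})),
    }


def _mvn_quad(deltas: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Per-row quadratic form d' Lam d for (I, P) deltas."""
    return np.einsum("ip,pq,iq->i", deltas, lam, deltas)


def _gamma_logpdf_sum(x: np.ndarray, shape: float, rate: float) -> float:
    """Sum of gamma log-densities up to an additive constant (cancels in MH ratios)."""
    return float(np.sum((shape - 1.0) * np.log(x) - rate * x))


class _Adapter:
    """Robbins–Monro adaptation of log proposal scales toward a target rate."""

    def __init__(self, shape, target: float, initial: float = -1.0):
        self.log_scale = np.full(shape, initial, dtype=float)
        self.target = target
        self.t = 0

    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted) -> None:
        self.t += 1
        gamma = (self.t + 10.0) ** -0.6
        self.log_scale += gamma * (np.asarray(accepted, dtype=float) - self.target)


def _run_chain(
    compiled: _CompiledLikelihood,
    prior: PriorSpec,
    settings: McmcSettings,
    rng: np.random.Generator,
):
    model = compiled.model
    P = model.n_parameters
    I = compiled.n_participants
    loc0, sd0 = prior.means(model.parameters)
    prec0 = 1.0 / sd0**2
    dev = prior.deviation
    collapsed = isinstance(dev, FixedSpec) and dev.value == 0.0
    eta_lkj = prior.correlation.eta if prior.correlation is not None else 1.0
    n_store = settings.draws // settings.thin

    store = {
        "mu": np.empty((n_store, P)),
        "sigma": np.empty((n_store, P)),
        "corr": np.empty((n_store, P, P)),
        "z": np.empty((n_store, I, P)),
    }

    # ---- initialization (retry on non-finite likelihood) --------------------
    for attempt in range(settings.max_init_retries):
        mu = settings.init_jitter * rng.standard_normal(P)
        if isinstance(dev, GammaSpec):
            sigma = np.full(P, dev.median())
        elif isinstance(dev, FixedSpec):
            sigma = np.full(P, dev.value)
        else:  # TreeBUGS construction
            xi = np.full(P, 1.0)
            V = np.eye(P)
            sigma = xi * np.sqrt(np.diag(V))
        corr = np.eye(P)
        z = mu + (0.0 if collapsed else settings.init_jitter * rng.standard_normal((I, P)))
        z = np.broadcast_to(mu, (I, P)).copy() if collapsed else z
        theta = ndtr(z)
        ll_tree = compiled.by_tree(theta)
        cur_ll = sum(ll_tree.values())
        if np.all(np.isfinite(cur_ll)):
            break
    else:
        raise RuntimeError("could not find a finite starting point for the chain")

    def cov_precision(sigma, corr):
        cov = corr * np.outer(sigma, sigma)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(P))
        inv_chol = np.linalg.inv(chol)
        lam = inv_chol.T @ inv_chol
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return lam, logdet

    if not collapsed:
        lam, logdet = cov_precision(sigma, corr)

    adapt_z = _Adapter(I, _TARGET_MULTI if P > 1 else _TARGET_UNI, initial=-1.0)
    adapt_mu = _Adapter((), _TARGET_MULTI if P > 1 else _TARGET_UNI, initial=-1.0)
    adapt_s = _Adapter((), _TARGET_MULTI if P > 1 else _TARGET_UNI, initial=-2.0)
    adapt_s_nc = _Adapter(P, _TARGET_UNI, initial=-1.5)
    adapt_mu_nc = _Adapter(P, _TARGET_UNI, initial=-1.5)
    adapt_o = _Adapter((), _TARGET_MULTI, initial=-2.5)
    acc_counts = {
        "z": 0.0, "mu": 0.0, "mu_nc": 0.0, "sigma": 0.0, "sigma_nc": 0.0, "corr": 0.0,
    }
    n_kept = 0
    idx_off = np.triu_indices(P, k=1)

    total_iters = settings.warmup + settings.draws
    for it in range(total_iters):
        warm = it < settings.warmup

        if collapsed:
            # ---- no hierarchy: RW-MH directly on mu -------------------------
            step = adapt_mu.scale()
            prop = mu + step * rng.standard_normal(P)
            z_prop = np.broadcast_to(prop, (I, P))
            theta_prop = ndtr(z_prop)
            ll_tree_prop = compiled.by_tree(theta_prop)
            ll_prop = sum(ll_tree_prop.values())
            log_r = (
                np.sum(ll_prop) - np.sum(cur_ll)
                - 0.5 * np.sum(prec0 * (prop - loc0) ** 2)
                + 0.5 * np.sum(prec0 * (mu - loc0) ** 2)
            )
            if np.log(rng.uniform()) < log_r:
                mu = prop
                z = np.broadcast_to(mu, (I, P)).copy()
                theta = theta_prop
                ll_tree = ll_tree_prop
                cur_ll = ll_prop.copy()
                accepted = 1.0
            else:
                accepted = 0.0
            if warm:
                adapt_mu.update(accepted)
            else:
                acc_counts["mu"] += accepted
        else:
            # ---- 1. individual probit vectors (vectorized per-participant MH)
            step = adapt_z.scale()[:, None]
            prop = z + step * rng.standard_normal((I, P))
            theta_prop = ndtr(prop)
            ll_tree_prop = compiled.by_tree(theta_prop)
            ll_prop = sum(ll_tree_prop.values())
            quad_cur = _mvn_quad(z - mu, lam)
            quad_prop = _mvn_quad(prop - mu, lam)
            log_r = (ll_prop - cur_ll) - 0.5 * (quad_prop - quad_cur)
            accept = np.log(rng.uniform(size=I)) < log_r
            z[accept] = prop[accept]
            theta[accept] = theta_prop[accept]
            for t in ll_tree:
                ll_tree[t][accept] = ll_tree_prop[t][accept]
            cur_ll[accept] = ll_prop[accept]
            if warm:
                adapt_z.update(accept)
            else:
                acc_counts["z"] += accept.mean()

            # ---- 2. group means: conjugate Gibbs ----------------------------
            a_prec = I * lam + np.diag(prec0)
            b = lam @ (I * z.mean(axis=0)) + prec0 * loc0
            a_chol = np.linalg.cholesky(a_prec)
            mean = np.linalg.solve(a_prec, b)
            noise = np.linalg.solve(a_chol.T, rng.standard_normal(P))
            mu = mean + noise

            # ---- 2b. non-centered translation moves, one component at a time.
            # Shift mu_p and every participant's z_p together (deviations
            # fixed): the MVN prior cancels, so only the likelihood and the
            # normal prior on mu_p enter.  This decouples mu_p from the
            # narrow conditional of the centered Gibbs step for weakly
            # identified parameters.
            tr_accepted = np.zeros(P)
            for p_idx in range(P):
                trees_p = compiled.trees_of_param[p_idx]
                shift = adapt_mu_nc.scale()[p_idx] * rng.standard_normal()
                col_prop = z[:, p_idx] + shift
                mu_prop_p = mu[p_idx] + shift
                theta_tmp = theta.copy()
                theta_tmp[:, p_idx] = ndtr(col_prop)
                contrib = compiled.by_tree(theta_tmp, trees=trees_p)
                delta_ll = sum(float(np.sum(contrib[t] - ll_tree[t])) for t in trees_p)
                log_r = (
                    delta_ll
                    - 0.5 * prec0[p_idx] * (
                        (mu_prop_p - loc0[p_idx]) ** 2 - (mu[p_idx] - loc0[p_idx]) ** 2
                    )
                )
                if np.log(rng.uniform()) < log_r:
                    mu = mu.copy()
                    mu[p_idx] = mu_prop_p
                    z[:, p_idx] = col_prop
                    theta = theta_tmp
                    for t in trees_p:
                        ll_tree[t] = contrib[t]
                    cur_ll = sum(ll_tree.values())
                    tr_accepted[p_idx] = 1.0
            if warm:
                adapt_mu_nc.update(tr_accepted)
            else:
                acc_counts["mu_nc"] += tr_accepted.mean()

            deltas = z - mu

            # ---- 3. deviation scales ---------------------------------------
            if isinstance(dev, GammaSpec):
                ls = np.log(sigma)
                prop_ls = ls + adapt_s.scale() * rng.standard_normal(P)
                prop_sigma = np.exp(prop_ls)
                lam_p, logdet_p = cov_precision(prop_sigma, corr)
                log_r = (
                    -0.5 * I * (logdet_p - logdet)
                    - 0.5 * (np.sum(_mvn_quad(deltas, lam_p)) - np.sum(_mvn_quad(deltas, lam)))
                    + _gamma_logpdf_sum(prop_sigma, dev.shape, dev.rate)
                    - _gamma_logpdf_sum(sigma, dev.shape, dev.rate)
                    + np.sum(prop_ls) - np.sum(ls)
                )
                accepted = float(np.log(rng.uniform()) < log_r)
                if accepted:
                    sigma, lam, logdet = prop_sigma, lam_p, logdet_p
                if warm:
                    adapt_s.update(accepted)
                else:
                    acc_counts["sigma"] += accepted

                # ---- 3b. non-centered rescale moves, one component at a time.
                # Hold the standardized deviations eta_p = (z_p - mu_p)/sigma_p
                # fixed and rescale; the MVN prior on eta cancels, so only the
                # likelihood, the gamma prior and the log-scale Jacobian enter.
                # This breaks the funnel between sigma_p and the individual
                # deviations of weakly identified parameters.
                nc_accepted = np.zeros(P)
                for p_idx in range(P):
                    trees_p = compiled.trees_of_param[p_idx]
                    ls_p = np.log(sigma[p_idx])
                    prop_ls_p = ls_p + adapt_s_nc.scale()[p_idx] * rng.standard_normal()
                    prop_sigma_p = np.exp(prop_ls_p)
                    col_prop = mu[p_idx] + deltas[:, p_idx] * (prop_sigma_p / sigma[p_idx])
                    theta_tmp = theta.copy()
                    theta_tmp[:, p_idx] = ndtr(col_prop)
                    contrib = compiled.by_tree(theta_tmp, trees=trees_p)
                    delta_ll = sum(float(np.sum(contrib[t] - ll_tree[t])) for t in trees_p)
                    log_r = (
                        delta_ll
                        + (dev.shape - 1.0) * (prop_ls_p - ls_p)
                        - dev.rate * (prop_sigma_p - sigma[p_idx])
                        + (prop_ls_p - ls_p)
                    )
                    if np.log(rng.uniform()) < log_r:
                        sigma = sigma.copy()
                        sigma[p_idx] = prop_sigma_p
                        z[:, p_idx] = col_prop
                        theta = theta_tmp
                        for t in trees_p:
                            ll_tree[t] = contrib[t]
                        cur_ll = sum(ll_tree.values())
                        nc_accepted[p_idx] = 1.0
                if nc_accepted.any():
                    deltas = z - mu
                    lam, logdet = cov_precision(sigma, corr)
                if warm:
                    adapt_s_nc.update(nc_accepted)
                else:
                    acc_counts["sigma_nc"] += nc_accepted.mean()

                # ---- 4. correlation off-diagonals (LKJ target) -------------
                if P > 1:
                    pert = adapt_o.scale() * rng.standard_normal(len(idx_off[0]))
                    prop_corr = corr.copy()
                    prop_corr[idx_off] += pert
                    prop_corr[(idx_off[1], idx_off[0])] += pert
                    accepted = 0.0
                    if np.all(np.abs(prop_corr[idx_off]) < 1.0):
                        try:
                            np.linalg.cholesky(prop_corr)
                            ok = True
                        except np.linalg.LinAlgError:
                            ok = False
                        if ok:
                            lam_p, logdet_p = cov_precision(sigma, prop_corr)
                            sign_c, ld_c = np.linalg.slogdet(corr)
                            sign_p, ld_p = np.linalg.slogdet(prop_corr)
                            log_r = (
                                -0.5 * I * (logdet_p - logdet)
                                - 0.5 * (np.sum(_mvn_quad(deltas, lam_p)) - np.sum(_mvn_quad(deltas, lam)))
                                + (eta_lkj - 1.0) * (ld_p - ld_c)
                            )
                            if np.log(rng.uniform()) < log_r:
                                corr, lam, logdet = prop_corr, lam_p, logdet_p
                                accepted = 1.0
                    if warm:
                        adapt_o.update(accepted)
                    else:
                        acc_counts["corr"] += accepted
            elif isinstance(dev, TreeBUGSDeviation):
                # scale matrix: conjugate inverse-Wishart Gibbs on V
                df0 = dev.df if dev.df is not None else P + 1
                eta_i = deltas / xi
                scale_post = np.eye(P) + eta_i.T @ eta_i
                V = stats.invwishart.rvs(df=df0 + I, scale=scale_post, random_state=rng)
                V = np.atleast_2d(V)
                # expansion factors xi: RW-MH on log xi with Uniform(0, upper)
                lxi = np.log(xi)
                prop_lxi = lxi + adapt_s.scale() * rng.standard_normal(P)
                prop_xi = np.exp(prop_lxi)
                accepted = 0.0
                if np.all(prop_xi < dev.xi_upper):
                    v_sd = np.sqrt(np.diag(V))
                    corr_v = V / np.outer(v_sd, v_sd)
                    lam_c, logdet_c = cov_precision(xi * v_sd, corr_v)
                    lam_p, logdet_p = cov_precision(prop_xi * v_sd, corr_v)
                    log_r = (
                        -0.5 * I * (logdet_p - logdet_c)
                        - 0.5 * (np.sum(_mvn_quad(deltas, lam_p)) - np.sum(_mvn_quad(deltas, lam_c)))
                        + np.sum(prop_lxi) - np.sum(lxi)
                    )
                    if np.log(rng.uniform()) < log_r:
                        xi = prop_xi
                        accepted = 1.0
                if warm:
                    adapt_s.update(accepted)
                else:
                    acc_counts["sigma"] += accepted
                v_sd = np.sqrt(np.diag(V))
                sigma = xi * v_sd
                corr = V / np.outer(v_sd, v_sd)
                lam, logdet = cov_precision(sigma, corr)
            # FixedSpec with value > 0: sigma constant; correlation still sampled
            elif isinstance(dev, FixedSpec) and P > 1:
                pert = adapt_o.scale() * rng.standard_normal(len(idx_off[0]))
                prop_corr = corr.copy()
                prop_corr[idx_off] += pert
                prop_corr[(idx_off[1], idx_off[0])] += pert
                accepted = 0.0
                if np.all(np.abs(prop_corr[idx_off]) < 1.0):
                    try:
                        np.linalg.cholesky(prop_corr)
                        ok = True
                    except np.linalg.LinAlgError:
                        ok = False
                    if ok:
                        lam_p, logdet_p = cov_precision(sigma, prop_corr)
                        sign_c, ld_c = np.linalg.slogdet(corr)
                        sign_p, ld_p = np.linalg.slogdet(prop_corr)
                        log_r = (
                            -0.5 * I * (logdet_p - logdet)
                            - 0.5 * (np.sum(_mvn_quad(deltas, lam_p)) - np.sum(_mvn_quad(deltas, lam)))
                            + (eta_lkj - 1.0) * (ld_p - ld_c)
                        )
                        if np.log(rng.uniform()) < log_r:
                            corr, lam, logdet = prop_corr, lam_p, logdet_p
                            accepted = 1.0
                if warm:
                    adapt_o.update(accepted)
                else:
                    acc_counts["corr"] += accepted

        if not warm:
            k = it - settings.warmup
            if k % settings.thin == 0:
                j = k // settings.thin
                if j < n_store:
                    store["mu"][j] = mu
                    store["sigma"][j] = sigma
                    store["corr"][j] = corr
                    store["z"][j] = z
                    n_kept += 1

    rates = {k: v / max(settings.draws, 1) for k, v in acc_counts.items()}
    return store, rates


def fit_posterior(
    model: MPTModel,
    prior: PriorSpec,
    data: FrequencyTable,
    settings: McmcSettings | None = None,
) -> FitResult:
    """Sample the joint posterior given a frequency table.

    Runs ``settings.chains`` independent adaptive MwG chains and reports
    split-R-hat and effective sample sizes for all group-level quantities.
    A convergence warning (``max R-hat >= 1.05``) is attached, not raised.
    """
    import arviz as az

    settings = settings or McmcSettings()
    prior.validate(model)
    compiled = _CompiledLikelihood(model, data)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    stores = []
    rates_all = []
    for chain_seed in seeds:
        store, rates = _run_chain(compiled, prior, settings, np.random.default_rng(chain_seed))
        stores.append(store)
        rates_all.append(rates)

    P = model.n_parameters
    chain_mu = np.stack([s["mu"] for s in stores])  # (C, T, P)
    chain_sigma = np.stack([s["sigma"] for s in stores])
    flat = {
        key: np.concatenate([s[key] for s in stores], axis=0)
        for key in ("mu", "sigma", "corr", "z")
    }
    draws = ParameterDraws(
        parameters=model.parameters,
        group_mu=flat["mu"],
        sigma=flat["sigma"],
        corr=flat["corr"],
        individual_probit=flat["z"],
        provenance="posterior",
        seed=settings.seed,
    )

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    warnings: list[str] = []
    for j, p in enumerate(model.parameters):
        for name, arr in (("mu", chain_mu), ("sigma", chain_sigma)):
            label = f"{name}_{p}"
            series = arr[:, :, j]
            if np.allclose(series.std(), 0.0):
                rhat[label] = np.nan
                ess[label] = np.nan
                continue
            if settings.chains > 1:
                rhat[label] = float(az.rhat(az.convert_to_dataset(series[:, :, None]))["x"].values[0])
            else:
                rhat[label] = np.nan
            ess[label] = float(az.ess(az.convert_to_dataset(series[:, :, None]))["x"].values[0])
    if settings.chains == 1:
        warnings.append("single chain: R-hat not available")
    finite_rhat = [v for v in rhat.values() if np.isfinite(v)]
    if finite_rhat and max(finite_rhat) >= 1.05:
        warnings.append(
            f"convergence warning: max R-hat = {max(finite_rhat):.3f} >= 1.05; "
            "consider more draws or warmup"
        )

    mean_rates = {
        k: float(np.mean([r[k] for r in rates_all])) for k in rates_all[0]
    }
    return FitResult(
        draws=draws,
        rhat=rhat,
        ess=ess,
        accept_rates=mean_rates,
        settings=settings,
        warnings=warnings,
        fingerprints=_prior_fingerprints(model, prior, data),
        chain_group_mu=chain_mu,
        chain_sigma=chain_sigma,
    )


def diagnostics(fit: FitResult) -> pd.DataFrame:
    """R-hat and effective sample size per group-level quantity."""
    rows = [
        {"quantity": q, "rhat": fit.rhat.get(q, np.nan), "ess": fit.ess.get(q, np.nan)}
        for q in fit.rhat
    ]
    frame = pd.DataFrame(rows).set_index("quantity")
    frame.attrs["warnings"] = list(fit.warnings)
    return frame
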