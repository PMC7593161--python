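"""Adaptive Metropolis-within-Gibbs sampler for Bernoulli-logit posteriors.

The daily survival models are logistic known-fate likelihoods with
independent Normal(0, precision 0.001) priors on every coefficient and
random-effect level.  Sampling is componentwise random-walk Metropolis:
each parameter gets a Gaussian proposal whose scale adapts during burn-in
toward a 30-45% acceptance rate and is frozen afterwards, so the retained
draws come from a valid fixed-kernel chain.  The inner sweep is compiled
with numba; a chain is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; defaults follow the nest-model run specification.

    ``n_iter`` counts total iterations per chain including burn-in; after
    discarding ``burn_in`` and thinning by ``thin`` each chain keeps
    ``(n_iter - burn_in) // thin`` draws.
    """

    n_chains: int = 3
    n_iter: int = 4_000
    burn_in: int = 1_000
    thin: int = 3
    seed: int = 0
    adapt_interval: int = 50
    target_accept: tuple = (0.30, 0.45)
    init_scale: float = 1.0
    initial_proposal_sd: float = 0.2

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def nest_default(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=3, n_iter=4_000, burn_in=1_000, thin=3, seed=seed)

    @classmethod
    def female_default(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=3, n_iter=7_000, burn_in=2_000, thin=3, seed=seed)

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class Chains:
    """Post burn-in, thinned draws: array (n_chains, n_draws, n_params)."""

    draws: np.ndarray
    names: list

    def __post_init__(self):
        if self.draws.ndim != 3:
            raise ValueError("draws must be (n_chains, n_draws, n_params)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self, name: str | None = None) -> np.ndarray:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        if name is None:
            return flat
        return flat[:, self.names.index(name)]


@njit(cache=True)
def _sweep(X, y, prior_prec, n_iter, burn_in, thin, seed, adapt_interval,
           acc_lo, acc_hi, beta0, prop_sd0):  # pragma: no cover - numba
    np.random.seed(seed)
    n, p = X.shape
    beta = beta0.copy()
    prop_sd = prop_sd0.copy()
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * beta[j]
        eta[i] = s
    ll = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            ll += y[i] * e - e - np.log1p(np.exp(-e))
        else:
            ll += y[i] * e - np.log1p(np.exp(e))
    n_keep = (n_iter - burn_in + thin - 1) // thin
    draws = np.empty((n_keep, p))
    acc = np.zeros(p)
    tries = np.zeros(p)
    kept = 0
    for it in range(n_iter):
        for j in range(p):
            step = prop_sd[j] * np.random.normal()
            b_new = beta[j] + step
            ll_new = 0.0
            for i in range(n):
                e = eta[i] + step * X[i, j]
                if e > 0.0:
                    ll_new += y[i] * e - e - np.log1p(np.exp(-e))
                else:
                    ll_new += y[i] * e - np.log1p(np.exp(e))
            log_ratio = (ll_new - ll) + 0.5 * prior_prec * (beta[j] ** 2 - b_new**2)
            tries[j] += 1.0
            if np.log(np.random.random()) < log_ratio:
                for i in range(n):
                    eta[i] += step * X[i, j]
                beta[j] = b_new
                ll = ll_new
                acc[j] += 1.0
        if it < burn_in and (it + 1) % adapt_interval == 0:
            for j in range(p):
                rate = acc[j] / tries[j]
                if rate > acc_hi:
                    prop_sd[j] *= 1.3
                elif rate < acc_lo:
                    prop_sd[j] /= 1.3
                acc[j] = 0.0
                tries[j] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(p):
                draws[kept, j] = beta[j]
            kept += 1
    return draws


def run_mcmc(X, y, config: McmcConfig, names=None, prior_precision: float = 0.001) -> Chains:
    """Sample the Bernoulli-logit posterior for design matrix X and fates y.

    Chains are initialized with dispersed normal draws of SD ``init_scale``
    (the flat prior rescaled so starting points are plausible) and are
    reproducible given ``config.seed``; per-chain seeds are spawned
    deterministically.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2 or len(y) != X.shape[0] or X.shape[0] == 0:
        raise ValueError("X must be (n, p) with matching non-empty y")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design matrix")
    p = X.shape[1]
    names = list(names) if names is not None else [f"b{j}" for j in range(p)]
    ss = np.random.SeedSequence(config.seed)
    chain_draws = []
    for child in ss.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        beta0 = rng.normal(0.0, config.init_scale, p)
        numba_seed = int(rng.integers(2**31 - 1))
        draws = _sweep(
            X, y, prior_precision, config.n_iter, config.burn_in, config.thin,
            numba_seed, config.adapt_interval, config.target_accept[0],
            config.target_accept[1], beta0,
            np.full(p, config.initial_proposal_sd),
        )
        chain_draws.append(draws)
    return Chains(draws=np.stack(chain_draws), names=names)


def gelman_rubin(chains) -> np.ndarray:
    """Potential scale reduction factor (R-hat) per parameter.

    Classic between/within form: with m chains of n draws each,
    ``var+ = (n-1)/n * W + B/n`` and ``R-hat = sqrt(var+/W)``.  Requires at
    least two chains and ten draws per chain.
    """
    draws = chains.draws if isinstance(chains, Chains) else np.asarray(chains, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    m, n, p = draws.shape
    if m < 2:
        raise ValueError("R-hat needs at least two chains")
    if n < 10:
        raise ValueError("R-hat needs at least ten draws per chain")
    chain_means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where((w == 0) & (b_over_n == 0), 1.0, rhat)
    return rhat


def with_seed(config: McmcConfig, seed: int) -> McmcConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
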