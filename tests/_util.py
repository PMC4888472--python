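"""Shared test helpers: independent oracles and model-based samplers."""
from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import norm, truncnorm

from nsdlsm.hmm import LatentStateParams
from nsdlsm.nsd import NSDSeries


def make_series(y: np.ndarray, observed=None, animal_id: str = "test") -> NSDSeries:
    """Wrap a standardized value vector into an NSDSeries."""
    y = np.asarray(y, dtype=float)
    T = y.size
    if observed is None:
        observed = ~np.isnan(y)
    observed = np.asarray(observed, dtype=bool)
    return NSDSeries(
        animal_id=animal_id,
        day_index=np.arange(1, T + 1),
        dates=np.datetime64("2000-01-01") + np.arange(T),
        nsd_raw=y.copy(),
        observed=observed,
        origin=(0.0, 0.0),
        nsd_std=y,
        std_range=(0.0, 1.0),
    )


def emission_probs(y, observed, params):
    """(T, 3) emission likelihoods computed independently with scipy."""
    T = y.size
    B = np.ones((T, 3))
    mu = params.full_mu
    sd = params.full_sigma
    for t in range(T):
        if observed[t]:
            B[t] = norm.pdf(y[t], mu, sd)
    return B


def brute_force_loglik(y, observed, params: LatentStateParams) -> float:
    """Exhaustive sum over all 3^T latent paths (small T only)."""
    T = y.size
    B = emission_probs(y, observed, params)
    total = 0.0
    for path in product(range(3), repeat=T):
        p = params.pi0[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= params.Q[path[t - 1], path[t]] * B[t, path[t]]
        total += p
    return float(np.log(total))


def brute_force_viterbi(y, observed, params: LatentStateParams):
    """Argmax over all 3^T latent paths (small T only); 0-based states."""
    T = y.size
    B = emission_probs(y, observed, params)
    best_p, best_path = -1.0, None
    for path in product(range(3), repeat=T):
        p = params.pi0[path[0]] * B[0, path[0]]
        for t in range(1, T):
            p *= params.Q[path[t - 1], path[t]] * B[t, path[t]]
        if p > best_p:
            best_p, best_path = p, path
    return np.array(best_path)


def random_params(rng: np.random.Generator) -> LatentStateParams:
    """A random valid parameter set for oracle comparisons."""
    Q = rng.dirichlet(np.ones(3) * rng.uniform(0.5, 5.0), size=3)
    pi0 = rng.dirichlet(np.ones(3))
    mu = np.sort(rng.uniform(0.05, 0.95, size=2))
    sigma = rng.uniform(0.02, 0.3, size=2)
    return LatentStateParams(mu=mu, sigma=sigma, Q=Q, pi0=pi0)


def sample_from_model(params: LatentStateParams, T: int, rng: np.random.Generator):
    """Draw (values, modes) from the latent-state model itself.

    Emissions are truncated to [0, 1], matching the support of
    range-standardized NSD.
    """
    modes = np.empty(T, dtype=int)
    modes[0] = rng.choice(3, p=params.pi0)
    for t in range(1, T):
        modes[t] = rng.choice(3, p=params.Q[modes[t - 1]])
    mu = params.full_mu[modes]
    sd = params.full_sigma[modes]
    y = truncnorm.rvs((0 - mu) / sd, (1 - mu) / sd, loc=mu, scale=sd,
                      random_state=rng)
    return np.asarray(y), modes


RECOVERY_TRUTH = LatentStateParams(
    mu=np.array([0.1, 0.8]),
    sigma=np.array([0.05, 0.05]),
    Q=np.array([[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.05, 0.05, 0.90]]),
    pi0=np.array([1.0, 0.0, 0.0]),
)
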