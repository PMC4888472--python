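"""Gibbs sampling for the latent-state model, with convergence diagnostics.

Mirrors the Bayesian treatment of the model: a forward-filtering
backward-sampling (FFBS) step draws the full latent mode path, after which
the emission and switching parameters have standard conditional
distributions.  Priors: mu_i ~ Uniform(0, 1) and sigma_i ~ Uniform(floor, 1)
for the two free encamped modes, Dirichlet(1, 1, 1) on each row of Q and on
pi0.  The pseudo-uniform mode's emission parameters stay fixed throughout.

Convergence follows the classic Gelman-Rubin potential scale reduction
factor computed across chains on the monitored scalars (deviance, mu,
sigma and all Q entries); R-hat below 1.1 for every one of them counts as
converged.  On failure the sampler escalates once to a longer run with
fresh starting values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from . import _kernels
from .hmm import (
    FitDiagnostics,
    LatentStateParams,
    MU3_FIXED,
    SIGMA3_FIXED,
    emission_matrix,
)
from .nsd import NSDSeries
from .trajectory import MIN_SERIES_DAYS

RHAT_THRESHOLD = 1.1


@dataclass
class GibbsConfig:
    n_chains: int = 3
    n_iter: int = 5000
    escalation_iter: int = 20000
    seed: Optional[int] = None
    sigma_floor: float = 0.005
    sigma_max: float = 1.0          # upper bound of the uniform prior on sigma
    dirichlet_prior: float = 1.0    # symmetric concentration for Q rows and pi0
    min_observed_days: int = MIN_SERIES_DAYS


@dataclass
class GibbsResult:
    draws: Dict[str, np.ndarray]    # name -> (n_chains, n_kept) post-burn-in draws
    params: LatentStateParams       # posterior-median parameters
    diagnostics: FitDiagnostics


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (m, n): m >= 2 chains of equal length n >= 10.
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance (n * variance of the chain
    means).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful R-hat")
    W = chains.var(axis=1, ddof=1).mean()
    if W <= 0.0:
        raise ValueError("degenerate chains: zero within-chain variance")
    B = n * chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _sample_sigma2(
    rng: np.random.Generator, n: float, ss: float, lo: float, hi: float
) -> float:
    """Draw sigma^2 given n weighted points with residual sum of squares ss.

    Flat prior on sigma over [lo, hi] implies an inverse-gamma-shaped
    conditional on sigma^2, truncated; drawn by rejection with a grid
    fallback for pathological cases.
    """
    shape = max((n - 1.0) / 2.0, 0.5)
    scale = max(ss / 2.0, 1e-12)
    for _ in range(100):
        s2 = scale / rng.gamma(shape)
        if lo * lo <= s2 <= hi * hi:
            return s2
    # fallback: inverse-CDF on a log-spaced grid of the truncated density
    grid = np.geomspace(lo * lo, hi * hi, 512)
    logp = -(shape + 1.0) * np.log(grid) - scale / grid
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(rng.choice(grid, p=p))


def _run_chain(
    series: NSDSeries, cfg: GibbsConfig, n_iter: int, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    T = series.T
    obs = series.observed
    y_obs = series.nsd_std[obs]
    # overdispersed start
    mu = np.sort(rng.uniform(0.0, 1.0, size=2))
    sigma = rng.uniform(0.05, 0.3, size=2)
    Q = rng.dirichlet(np.full(3, cfg.dirichlet_prior), size=3)
    pi0 = rng.dirichlet(np.full(3, cfg.dirichlet_prior))
    names = ["deviance", "mu1", "mu2", "sigma1", "sigma2"] + [
        f"q{i+1}{j+1}" for i in range(3) for j in range(3)
    ]
    out = {k: np.empty(n_iter) for k in names}
    alpha = cfg.dirichlet_prior
    for it in range(n_iter):
        params = LatentStateParams(
            mu=np.clip(mu, 0.0, 1.0), sigma=np.maximum(sigma, cfg.sigma_floor),
            Q=Q, pi0=pi0,
        )
        B = emission_matrix(series, params)
        path = _kernels.ffbs(B, Q, pi0, rng.uniform(size=T))
        loglik, _, _ = _kernels.forward(B, Q, pi0)
        # conditional draws for the two free Gaussian modes
        path_obs = path[obs]
        for i in range(2):
            sel = y_obs[path_obs == i]
            n_i = sel.size
            if n_i > 0:
                # flat prior on mu over [0,1] -> truncated normal conditional
                m = sel.mean()
                sd = sigma[i] / np.sqrt(n_i)
                for _ in range(100):
                    draw = rng.normal(m, sd)
                    if 0.0 <= draw <= 1.0:
                        mu[i] = draw
                        break
                else:
                    mu[i] = min(max(m, 0.0), 1.0)
                ss = float(((sel - mu[i]) ** 2).sum())
                sigma[i] = np.sqrt(
                    _sample_sigma2(rng, n_i, ss, cfg.sigma_floor, cfg.sigma_max)
                )
            else:
                mu[i] = rng.uniform(0.0, 1.0)
                sigma[i] = rng.uniform(cfg.sigma_floor, cfg.sigma_max)
        # transition counts over the full path (missing days included)
        counts = np.zeros((3, 3))
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
        Q = np.vstack([rng.dirichlet(alpha + counts[i]) for i in range(3)])
        e0 = np.zeros(3)
        e0[path[0]] = 1.0
        pi0 = rng.dirichlet(alpha + e0)
        out["deviance"][it] = -2.0 * loglik
        out["mu1"][it], out["mu2"][it] = mu
        out["sigma1"][it], out["sigma2"][it] = sigma
        for i in range(3):
            for j in range(3):
                out[f"q{i+1}{j+1}"][it] = Q[i, j]
    return out


def gibbs_fit(series: NSDSeries, config: Optional[GibbsConfig] = None) -> GibbsResult:
    """Run multiple Gibbs chains, assess convergence and summarize.

    Burn-in is the first half of each chain.  If any monitored R-hat is at
    or above 1.1 the sampler reruns once with ``escalation_iter``
    iterations and new starting values; a still-unconverged result is
    returned flagged (``diagnostics.converged`` False), never silently.
    """
    cfg = config or GibbsConfig()
    if series.nsd_std is None:
        raise ValueError("series must be standardized")
    if series.n_observed < cfg.min_observed_days:
        raise ValueError("series too short for fitting")
    ss = np.random.SeedSequence(cfg.seed)

    def run(n_iter: int, round_idx: int) -> Tuple[Dict[str, np.ndarray], dict, bool]:
        chains = []
        for c in range(cfg.n_chains):
            rng = np.random.default_rng(
                np.random.SeedSequence((ss.entropy if ss.entropy is not None else 0,
                                        round_idx, c))
            )
            chains.append(_run_chain(series, cfg, n_iter, rng))
        keep = slice(n_iter // 2, None)
        draws = {
            k: np.vstack([ch[k][keep] for ch in chains]) for k in chains[0]
        }
        rhat = {}
        ok = True
        for k, v in draws.items():
            try:
                rhat[k] = gelman_rubin(v)
            except ValueError:
                rhat[k] = np.nan
                continue
            if rhat[k] >= RHAT_THRESHOLD:
                ok = False
        return draws, rhat, ok

    draws, rhat, ok = run(cfg.n_iter, 0)
    n_used = cfg.n_iter
    if not ok and cfg.escalation_iter > cfg.n_iter:
        draws, rhat, ok = run(cfg.escalation_iter, 1)
        n_used = cfg.escalation_iter

    med = {k: float(np.median(v)) for k, v in draws.items()}
    Q = np.array(
        [[med[f"q{i+1}{j+1}"] for j in range(3)] for i in range(3)]
    )
    Q = Q / Q.sum(axis=1, keepdims=True)   # medians need not be exactly stochastic
    params = LatentStateParams(
        mu=np.array([med["mu1"], med["mu2"]]),
        sigma=np.array([med["sigma1"], med["sigma2"]]),
        Q=Q,
        pi0=np.full(3, 1.0 / 3.0),
        mu3_fixed=MU3_FIXED,
        sigma3_fixed=SIGMA3_FIXED,
    )
    diag = FitDiagnostics(
        loglik_trace=-0.5 * np.median(draws["deviance"], axis=0),
        converged=ok,
        n_iterations=n_used,
        seed=cfg.seed,
        rhat=rhat,
    )
    return GibbsResult(draws=draws, params=params, diagnostics=diag)


def credible_interval(draws: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """Equal-tailed posterior credible interval from pooled draws."""
    lo = (1.0 - level) / 2.0
    a, b = np.quantile(np.asarray(draws).ravel(), [lo, 1.0 - lo])
    return float(a), float(b)
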