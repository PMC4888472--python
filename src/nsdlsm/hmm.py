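"""Three-mode latent-state model on standardized NSD.

The model is a hidden Markov model with M = 3 modes.  Modes 1 and 2 are
"encamped" modes with free Gaussian emissions N(mu_i, sigma_i) on the
range-standardized NSD; mode 3 is an "exploratory" mode whose emission is
a Gaussian with *fixed* mean and large fixed standard deviation — a
pseudo-uniform that is nearly flat over [0, 1] and so absorbs the
transient travel days between ranges.  A 3x3 row-stochastic switching
matrix Q carries the first-order Markov dependence; its diagonal entries
q_ii (the probabilities of remaining in a mode) are the quantities the
strategy-classification rules operate on.

Estimation here is by expectation-maximization (Baum-Welch) with the
mode-3 emission parameters held fixed; a Gibbs sampler mirroring the
Bayesian treatment lives in :mod:`nsdlsm.gibbs`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .nsd import NSDSeries
from .trajectory import MIN_SERIES_DAYS

#: Fixed pseudo-uniform emission parameters on the standardized scale.
#: With sigma = 1 the density varies by less than 12% across [0, 1],
#: i.e. it is effectively flat over the observable range.
MU3_FIXED = 0.5
SIGMA3_FIXED = 1.0

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class LatentStateParams:
    """Parameters of the three-mode latent-state model.

    ``mu`` and ``sigma`` hold the two free encamped modes; the exploratory
    mode's emission is fixed at (``mu3_fixed``, ``sigma3_fixed``) and is
    never updated during fitting.
    """

    mu: np.ndarray                      # shape (2,), in [0, 1]
    sigma: np.ndarray                   # shape (2,), > 0
    Q: np.ndarray                       # shape (3, 3), row-stochastic
    pi0: np.ndarray                     # shape (3,), sums to 1
    mu3_fixed: float = MU3_FIXED
    sigma3_fixed: float = SIGMA3_FIXED

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mu.shape != (2,) or self.sigma.shape != (2,):
            raise ValueError("mu and sigma must each have two free entries")
        if np.any(self.mu < 0) or np.any(self.mu > 1):
            raise ValueError("mu must lie in [0, 1]")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if self.Q.shape != (3, 3):
            raise ValueError("Q must be 3x3")
        if np.any(self.Q < -1e-12) or np.any(self.Q > 1 + 1e-12):
            raise ValueError("Q entries must lie in [0, 1]")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of Q must sum to 1")
        if self.pi0.shape != (3,) or not np.isclose(self.pi0.sum(), 1.0, atol=1e-8):
            raise ValueError("pi0 must be a length-3 distribution")

    @property
    def full_mu(self) -> np.ndarray:
        return np.array([self.mu[0], self.mu[1], self.mu3_fixed])

    @property
    def full_sigma(self) -> np.ndarray:
        return np.array([self.sigma[0], self.sigma[1], self.sigma3_fixed])

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "mu3_fixed": self.mu3_fixed,
            "sigma3_fixed": self.sigma3_fixed,
            "Q": self.Q.tolist(),
            "pi0": self.pi0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentStateParams":
        return cls(
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            Q=np.array(d["Q"]),
            pi0=np.array(d["pi0"]),
            mu3_fixed=d.get("mu3_fixed", MU3_FIXED),
            sigma3_fixed=d.get("sigma3_fixed", SIGMA3_FIXED),
        )


@dataclass
class StateSequence:
    """Decoded per-day modes and posterior mode probabilities."""

    modes: np.ndarray        # 1-based labels in {1, 2, 3}, length T
    posterior: np.ndarray    # shape (T, 3), rows sum to 1
    decode_method: str       # "viterbi" or "posterior"


@dataclass
class FitDiagnostics:
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int
    seed: Optional[int] = None
    rhat: Optional[dict] = None


@dataclass
class FitConfig:
    """Settings for EM fitting.

    Defaults: convergence when the log-likelihood improves by less than
    ``tol`` between iterations; five jittered restarts around a
    percentile-based initialization; Gaussian modes whose standard
    deviation drops below ``sigma_floor`` abort that start (emission
    collapse onto a single point).
    """

    tol: float = 1e-6
    max_iter: int = 500
    n_starts: int = 5
    seed: Optional[int] = None
    sigma_floor: float = 0.005
    decode_method: str = "posterior"
    min_observed_days: int = MIN_SERIES_DAYS


class CollapsedStartError(RuntimeError):
    """A Gaussian mode collapsed (sigma below the floor) during one start."""


def emission_density(value: float, state: int, params: LatentStateParams) -> float:
    """Emission density of one standardized NSD value under one mode.

    ``state`` is 1-based.  A missing value (NaN/None) returns 1: it
    contributes no information and the Markov chain bridges the day.
    """
    if state not in (1, 2, 3):
        raise ValueError("state must be 1, 2 or 3")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return 1.0
    mu = params.full_mu[state - 1]
    sd = params.full_sigma[state - 1]
    z = (value - mu) / sd
    return math.exp(-0.5 * z * z) / (sd * _SQRT2PI)


def emission_matrix(series: NSDSeries, params: LatentStateParams) -> np.ndarray:
    """(T, 3) emission likelihoods; unobserved days carry 1 in all columns."""
    if series.nsd_std is None:
        raise ValueError("series must be standardized")
    T = series.T
    B = np.ones((T, 3))
    obs = series.observed
    y = series.nsd_std[obs][:, None]
    mu = params.full_mu[None, :]
    sd = params.full_sigma[None, :]
    z = (y - mu) / sd
    B[obs] = np.exp(-0.5 * z * z) / (sd * _SQRT2PI)
    return B


def forward_loglik(series: NSDSeries, params: LatentStateParams) -> float:
    """Log-likelihood of the observed series via the scaled forward pass."""
    B = emission_matrix(series, params)
    loglik, _, _ = _kernels.forward(B, params.Q, params.pi0)
    if not np.isfinite(loglik):
        raise FloatingPointError("numerical underflow in forward recursion")
    return float(loglik)


def decode(
    series: NSDSeries, params: LatentStateParams, method: str = "posterior"
) -> StateSequence:
    """Decode the latent mode sequence.

    ``posterior`` labels each day with the argmax of its forward-backward
    marginal (each location gets its most probable mode); ``viterbi``
    returns the jointly most probable path.  Missing days are decoded like
    any other: their posteriors are driven by the neighbors and Q.
    """
    B = emission_matrix(series, params)
    _, gamma, _ = _kernels.forward_backward(B, params.Q, params.pi0)
    if method == "posterior":
        modes = np.argmax(gamma, axis=1) + 1
    elif method == "viterbi":
        modes = _kernels.viterbi(B, params.Q, params.pi0) + 1
    else:
        raise ValueError("method must be 'posterior' or 'viterbi'")
    return StateSequence(modes=modes, posterior=gamma, decode_method=method)


def relabel_states(
    params: LatentStateParams, seq: StateSequence
) -> Tuple[LatentStateParams, StateSequence]:
    """Canonicalize encamped-mode labels.

    Gaussian mixture labels are arbitrary; the classification rules need
    "the first encamped mode" to be well defined.  Mode 1 is therefore the
    encamped mode occupied earliest in the decoded sequence; mode 3 is
    always the pseudo-uniform.
    """
    modes = seq.modes
    first1 = np.argmax(modes == 1) if np.any(modes == 1) else None
    first2 = np.argmax(modes == 2) if np.any(modes == 2) else None
    if first1 is None and first2 is None:
        raise ValueError("exploratory-only fit: neither encamped mode is visited")
    swap = first1 is None or (first2 is not None and first2 < first1)
    if not swap:
        return params, seq
    perm = np.array([1, 0, 2])
    new_params = replace(
        params,
        mu=params.mu[[1, 0]].copy(),
        sigma=params.sigma[[1, 0]].copy(),
        Q=params.Q[np.ix_(perm, perm)].copy(),
        pi0=params.pi0[perm].copy(),
    )
    new_modes = modes.copy()
    new_modes[modes == 1] = 2
    new_modes[modes == 2] = 1
    new_seq = StateSequence(
        modes=new_modes,
        posterior=seq.posterior[:, perm].copy(),
        decode_method=seq.decode_method,
    )
    return new_params, new_seq


def _kmeans2_1d(y: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Two-means cluster centers of a 1-d sample (deterministic Lloyd)."""
    c = np.array([y.min(), y.max()], dtype=float)
    for _ in range(n_iter):
        mid = c.mean()
        lo = y[y <= mid]
        hi = y[y > mid]
        if lo.size == 0 or hi.size == 0:
            break
        new = np.array([lo.mean(), hi.mean()])
        if np.allclose(new, c):
            break
        c = new
    return c


def _initial_params(
    y: np.ndarray, rng: np.random.Generator, start: int
) -> LatentStateParams:
    """Starting values for one EM run.

    Start 0 places the encamped means at the 20th/80th percentiles of the
    observed values; start 1 at the two-means cluster centers (robust when
    one mode holds most of the mass and the percentiles both land in it);
    later starts spread the means over random quantile pairs.
    """
    if start == 0:
        mu = np.percentile(y, [20, 80])
        diag = 0.9
    elif start == 1:
        mu = _kmeans2_1d(y)
        diag = 0.9
    else:
        qs = np.array([rng.uniform(2, 45), rng.uniform(55, 98)])
        mu = np.percentile(y, qs) + rng.uniform(-0.05, 0.05, size=2)
        diag = rng.uniform(0.7, 0.97)
    off = (1.0 - diag) / 2.0
    Q = np.full((3, 3), off)
    np.fill_diagonal(Q, diag)
    return LatentStateParams(
        mu=np.clip(mu, 0.0, 1.0),
        sigma=np.array([0.1, 0.1]),
        Q=Q,
        pi0=np.full(3, 1.0 / 3.0),
    )


def _em_single_start(
    series: NSDSeries, params: LatentStateParams, cfg: FitConfig
) -> Tuple[LatentStateParams, np.ndarray, bool]:
    """Run Baum-Welch from one starting point.

    Returns (params, loglik_trace, converged).  Raises
    :class:`CollapsedStartError` if a free Gaussian mode collapses.
    """
    obs = series.observed
    y_obs = series.nsd_std[obs]
    trace: List[float] = []
    converged = False
    for _ in range(cfg.max_iter):
        B = emission_matrix(series, params)
        loglik, gamma, xi_sum = _kernels.forward_backward(B, params.Q, params.pi0)
        trace.append(loglik)
        # M-step: emissions from observed days only, transitions from all
        g_obs = gamma[obs]
        mu = params.mu.copy()
        sigma = params.sigma.copy()
        for i in range(2):
            w = g_obs[:, i]
            wsum = w.sum()
            if wsum > 1e-12:
                mu[i] = float(w @ y_obs / wsum)
                var = float(w @ (y_obs - mu[i]) ** 2 / wsum)
                # constrained M-step: the floor blocks the sigma -> 0
                # likelihood singularity while keeping EM monotone
                sigma[i] = max(math.sqrt(max(var, 0.0)), cfg.sigma_floor)
            else:
                raise CollapsedStartError("mode lost all posterior mass")
        rows = xi_sum.sum(axis=1, keepdims=True)
        Q = params.Q.copy()
        nz = rows[:, 0] > 1e-300
        Q[nz] = xi_sum[nz] / rows[nz]
        pi0 = gamma[0] / gamma[0].sum()
        params = LatentStateParams(
            mu=np.clip(mu, 0.0, 1.0), sigma=sigma, Q=Q, pi0=pi0,
            mu3_fixed=params.mu3_fixed, sigma3_fixed=params.sigma3_fixed,
        )
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol:
            converged = True
            break
    # final E-step likelihood so the trace ends at the returned params
    trace.append(forward_loglik(series, params))
    return params, np.array(trace), converged


def em_fit(
    series: NSDSeries, config: Optional[FitConfig] = None
) -> Tuple[LatentStateParams, StateSequence, FitDiagnostics]:
    """Fit the latent-state model by multi-start EM and decode.

    The best start by final log-likelihood wins; its parameters are
    relabeled canonically (first-occupied encamped mode becomes mode 1)
    before the decoded sequence is returned.  Deterministic under
    ``config.seed``.
    """
    cfg = config or FitConfig()
    if series.nsd_std is None:
        raise ValueError("series must be standardized")
    if series.n_observed < cfg.min_observed_days:
        raise ValueError(
            f"series too short: {series.n_observed} observed days, "
            f"need at least {cfg.min_observed_days}"
        )
    rng = np.random.default_rng(cfg.seed)
    y = series.nsd_std[series.observed]
    best: Optional[Tuple[LatentStateParams, np.ndarray, bool]] = None
    for start in range(cfg.n_starts):
        init = _initial_params(y, rng, start)
        try:
            fit = _em_single_start(series, init, cfg)
        except CollapsedStartError:
            continue
        if best is None or fit[1][-1] > best[1][-1]:
            best = fit
    if best is None:
        raise RuntimeError("degenerate fit: every EM start collapsed")
    params, trace, converged = best
    seq = decode(series, params, cfg.decode_method)
    params, seq = relabel_states(params, seq)
    diag = FitDiagnostics(
        loglik_trace=trace,
        converged=converged,
        n_iterations=len(trace) - 1,
        seed=cfg.seed,
    )
    return params, seq, diag
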