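"""Compiled inner loops for the latent-state model.

All kernels operate on a precomputed emission-likelihood matrix B of shape
(T, M) in which unobserved days carry 1.0 in every column (a missing
observation contributes no information; the Markov chain alone carries the
state through the gap).
"""
import numpy as np
from numba import njit


@njit(cache=True)
def forward(B, Q, pi0):
    """Scaled forward recursion.

    Returns (loglik, alpha_hat, c) where alpha_hat[t] is the normalized
    forward vector and c[t] the per-step normalizer.
    """
    T, M = B.shape
    alpha = np.empty((T, M))
    c = np.empty(T)
    s = 0.0
    for i in range(M):
        alpha[0, i] = pi0[i] * B[0, i]
        s += alpha[0, i]
    c[0] = s
    for i in range(M):
        alpha[0, i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(M):
            a = 0.0
            for i in range(M):
                a += alpha[t - 1, i] * Q[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(M):
            alpha[t, j] /= s
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik, alpha, c


@njit(cache=True)
def forward_backward(B, Q, pi0):
    """Scaled forward-backward pass.

    Returns (loglik, gamma, xi_sum) with gamma[t, i] the posterior state
    probability on day t and xi_sum[i, j] the expected transition counts
    summed over t.
    """
    T, M = B.shape
    loglik, alpha, c = forward(B, Q, pi0)
    beta = np.empty((T, M))
    for i in range(M):
        beta[T - 1, i] = 1.0
    gamma = np.empty((T, M))
    xi_sum = np.zeros((M, M))
    for i in range(M):
        gamma[T - 1, i] = alpha[T - 1, i]
    for t in range(T - 2, -1, -1):
        for i in range(M):
            b = 0.0
            for j in range(M):
                b += Q[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]
        g = 0.0
        for i in range(M):
            gamma[t, i] = alpha[t, i] * beta[t, i]
            g += gamma[t, i]
        # guard renormalization against accumulated rounding
        for i in range(M):
            gamma[t, i] /= g
        for i in range(M):
            for j in range(M):
                xi_sum[i, j] += (
                    alpha[t, i] * Q[i, j] * B[t + 1, j] * beta[t + 1, j] / c[t + 1]
                )
    return loglik, gamma, xi_sum


@njit(cache=True)
def viterbi(B, Q, pi0):
    """Most probable joint state path (log space). Returns 0-based states."""
    T, M = B.shape
    tiny = 1e-300
    delta = np.empty((T, M))
    back = np.zeros((T, M), dtype=np.int64)
    for i in range(M):
        delta[0, i] = np.log(pi0[i] + tiny) + np.log(B[0, i] + tiny)
    logQ = np.empty((M, M))
    for i in range(M):
        for j in range(M):
            logQ[i, j] = np.log(Q[i, j] + tiny)
    for t in range(1, T):
        for j in range(M):
            best = -np.inf
            arg = 0
            for i in range(M):
                v = delta[t - 1, i] + logQ[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + np.log(B[t, j] + tiny)
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    for i in range(M):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            path[T - 1] = i
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@njit(cache=True)
def ffbs(B, Q, pi0, u):
    """Forward-filter backward-sample a state path.

    u is a length-T vector of Uniform(0,1) draws supplied by the caller so
    the sampler stays reproducible under a single seeded generator.
    Returns 0-based states.
    """
    T, M = B.shape
    p = np.empty((T, M))
    s = 0.0
    for i in range(M):
        p[0, i] = pi0[i] * B[0, i]
        s += p[0, i]
    for i in range(M):
        p[0, i] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(M):
            a = 0.0
            for i in range(M):
                a += p[t - 1, i] * Q[i, j]
            a *= B[t, j]
            p[t, j] = a
            s += a
        for j in range(M):
            p[t, j] /= s
    path = np.empty(T, dtype=np.int64)
    # sample I_T
    acc = 0.0
    path[T - 1] = M - 1
    for i in range(M):
        acc += p[T - 1, i]
        if u[T - 1] <= acc:
            path[T - 1] = i
            break
    for t in range(T - 2, -1, -1):
        s = 0.0
        w = np.empty(M)
        for i in range(M):
            w[i] = p[t, i] * Q[i, path[t + 1]]
            s += w[i]
        acc = 0.0
        path[t] = M - 1
        for i in range(M):
            acc += w[i] / s
            if u[t] <= acc:
                path[t] = i
                break
    return path
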