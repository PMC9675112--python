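"""Numba kernels for the zero-spiked Dirichlet-process Gibbs sampler.

Cluster bookkeeping per selection block: slot 0 is the distinguished spike
cluster (atom exactly 0.0, possibly empty); slots 1..n_clusters-1 are slab
clusters with real-valued atoms. ``e`` is the current residual
y - X@beta - Z@zeta - W@gamma and is updated in place whenever a
coefficient moves; coefficients equal the atom of their assigned cluster.

All weights are handled on the log scale; categorical draws use a single
uniform against the normalized cumulative sum, consuming the passed
numpy Generator's stream so runs are reproducible given one seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _log1p_exp(x):
    # log(1 + exp(x)) without overflow
    if x > 35.0:
        return x
    return np.log1p(np.exp(x))


@njit(cache=True)
def update_block_dp(xb, g, e, assign, atoms, counts, n_clusters,
                    sigma2, tau2, pi0, alpha, rng):
    """One Polya-urn sweep over a selection block; returns new cluster count.

    Assignment weights for coefficient j with partial-residual projection
    s = x_j'(e + theta_cur x_j):
      zero atom      : (n_spike + alpha*pi0) * N(r | 0)
      slab cluster k : n_k * N(r | theta_k x_j)
      new slab       : alpha*(1-pi0) * marginal with theta ~ N(0, tau2)
    with the common factor N(r | 0) divided out of every weight.
    """
    p = xb.shape[1]
    logw = np.empty(p + 2)
    for j in range(p):
        k_cur = assign[j]
        theta_cur = atoms[k_cur]
        counts[k_cur] -= 1
        if k_cur > 0 and counts[k_cur] == 0:
            last = n_clusters - 1
            if k_cur != last:
                atoms[k_cur] = atoms[last]
                counts[k_cur] = counts[last]
                for jj in range(p):
                    if assign[jj] == last:
                        assign[jj] = k_cur
            n_clusters -= 1

        gj = g[j]
        s = theta_cur * gj
        for i in range(xb.shape[0]):
            s += xb[i, j] * e[i]

        inv2s = 1.0 / (2.0 * sigma2)
        logw[0] = np.log(counts[0] + alpha * pi0)
        for k in range(1, n_clusters):
            th = atoms[k]
            logw[k] = np.log(float(counts[k])) + (2.0 * th * s - th * th * gj) * inv2s
        # new slab cluster: closed-form marginal via Sherman-Morrison
        denom = sigma2 + tau2 * gj
        logw[n_clusters] = (
            np.log(alpha * (1.0 - pi0))
            - 0.5 * np.log1p(tau2 * gj / sigma2)
            + tau2 * s * s * inv2s / denom
        )

        m = logw[0]
        for k in range(1, n_clusters + 1):
            if logw[k] > m:
                m = logw[k]
        total = 0.0
        for k in range(n_clusters + 1):
            logw[k] = np.exp(logw[k] - m)
            total += logw[k]
        u = rng.random() * total
        acc = 0.0
        k_new = n_clusters
        for k in range(n_clusters + 1):
            acc += logw[k]
            if u <= acc:
                k_new = k
                break

        if k_new == n_clusters:  # open a new slab cluster
            v = 1.0 / (gj / sigma2 + 1.0 / tau2)
            atoms[k_new] = rng.normal(v * s / sigma2, np.sqrt(v))
            counts[k_new] = 0
            n_clusters += 1
        assign[j] = k_new
        counts[k_new] += 1
        theta_new = atoms[k_new]
        if theta_new != theta_cur:
            diff = theta_new - theta_cur
            for i in range(xb.shape[0]):
                e[i] -= xb[i, j] * diff
    return n_clusters


@njit(cache=True)
def update_atoms(xb, e, assign, atoms, n_clusters, sigma2, tau2, rng):
    """Redraw each slab cluster's atom from its Normal full conditional."""
    n, p = xb.shape
    u = np.empty(n)
    for k in range(1, n_clusters):
        u[:] = 0.0
        for j in range(p):
            if assign[j] == k:
                for i in range(n):
                    u[i] += xb[i, j]
        gk = 0.0
        s = 0.0
        for i in range(n):
            gk += u[i] * u[i]
            s += u[i] * e[i]
        s += atoms[k] * gk
        v = 1.0 / (gk / sigma2 + 1.0 / tau2)
        theta_new = rng.normal(v * s / sigma2, np.sqrt(v))
        diff = theta_new - atoms[k]
        for i in range(n):
            e[i] -= u[i] * diff
        atoms[k] = theta_new


@njit(cache=True)
def update_block_independent(xb, g, e, beta, sigma2, tau2, pi0, rng):
    """Independent spike-and-slab sweep (cluster-free limit of the DP)."""
    n, p = xb.shape
    for j in range(p):
        gj = g[j]
        s = beta[j] * gj
        for i in range(n):
            s += xb[i, j] * e[i]
        denom = sigma2 + tau2 * gj
        # log odds slab vs spike
        lo = (
            np.log(1.0 - pi0)
            - np.log(pi0)
            - 0.5 * np.log1p(tau2 * gj / sigma2)
            + tau2 * s * s / (2.0 * sigma2 * denom)
        )
        p_slab = 1.0 / (1.0 + np.exp(-lo)) if lo < 35.0 else 1.0
        if rng.random() < p_slab:
            v = 1.0 / (gj / sigma2 + 1.0 / tau2)
            theta_new = rng.normal(v * s / sigma2, np.sqrt(v))
        else:
            theta_new = 0.0
        if theta_new != beta[j]:
            diff = theta_new - beta[j]
            for i in range(n):
                e[i] -= xb[i, j] * diff
            beta[j] = theta_new
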