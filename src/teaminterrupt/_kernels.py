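"""Numba kernel for the hierarchical-logistic log-posterior and gradient.

The HMC sampler evaluates the gradient tens of thousands of times per fit;
a fused single-pass kernel avoids the overhead of composing many small numpy
operations. The numpy reference implementation lives in
``HierarchicalLogistic._logp_grad_numpy`` and the two are asserted equal in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def hier_logit_leapfrog(q, p, grad, step, n_steps, inv_mass,
                        X, y, subjects, hier_idx, offset, S,
                        mu_scale, sigma_scale, centered):
    """Leapfrog trajectory fully inside numba; returns (q, p, logp, grad)."""
    q = q.copy()
    p = p + 0.5 * step * grad
    lp = -np.inf
    for i in range(n_steps):
        q += step * inv_mass * p
        lp, grad = hier_logit_logp_grad(q, X, y, subjects, hier_idx, offset, S,
                                        mu_scale, sigma_scale, centered)
        if not np.isfinite(lp):
            return q, p, -np.inf, grad
        if i < n_steps - 1:
            p += step * grad
    p += 0.5 * step * grad
    return q, p, lp, grad


@njit(cache=False, fastmath=True)
def hier_logit_logp_grad(theta, X, y, subjects, hier_idx, offset, S,
                         mu_scale, sigma_scale, centered):
    """Return (log posterior, gradient) for one parameter vector.

    Layout of ``theta``: population coefficients ``mu`` (P), log population
    SDs (H), then subject values (S x H) — non-centered offsets ``z`` or, with
    ``centered``, the subject coefficients themselves.
    """
    n, P = X.shape
    H = hier_idx.shape[0]
    dim = P + H + S * H
    grad = np.zeros(dim)

    mu = theta[:P]
    sigma = np.empty(H)
    for h in range(H):
        ls = theta[P + h]
        if ls > 30.0:
            ls = 30.0
        elif ls < -30.0:
            ls = -30.0
        sigma[h] = np.exp(ls)
    zoff = P + H

    ll = 0.0
    G = np.zeros((S, H))  # per-subject residual-weighted design sums
    gmu = np.zeros(P)
    for i in range(n):
        s = subjects[i]
        eta = offset[i]
        for p in range(P):
            eta += X[i, p] * mu[p]
        for h in range(H):
            zval = theta[zoff + s * H + h]
            if centered:
                # subject coefficient replaces mu on hierarchical columns
                eta += X[i, hier_idx[h]] * (zval - mu[hier_idx[h]])
            else:
                eta += X[i, hier_idx[h]] * sigma[h] * zval
        if not np.isfinite(eta):
            return -np.inf, np.zeros(dim)
        # Bernoulli log-likelihood, stable in both tails; one exp per event
        if eta > 0.0:
            e = np.exp(-eta)
            ll += y[i] * eta - eta - np.log1p(e)
            r = y[i] - 1.0 / (1.0 + e)
        else:
            e = np.exp(eta)
            ll += y[i] * eta - np.log1p(e)
            r = y[i] - e / (1.0 + e)
        for p in range(P):
            gmu[p] += r * X[i, p]
        for h in range(H):
            G[s, h] += r * X[i, hier_idx[h]]

    lp = ll
    for p in range(P):
        lp -= 0.5 * mu[p] * mu[p] / (mu_scale * mu_scale)
        grad[p] = gmu[p] - mu[p] / (mu_scale * mu_scale)

    for h in range(H):
        lp += -0.5 * sigma[h] * sigma[h] / (sigma_scale * sigma_scale) \
            + theta[P + h]
        grad[P + h] = -sigma[h] * sigma[h] / (sigma_scale * sigma_scale) + 1.0

    if centered:
        for h in range(H):
            hc = hier_idx[h]
            # mu on hierarchical columns enters only through the subject prior
            grad[hc] = -mu[hc] / (mu_scale * mu_scale)
            dev2 = 0.0
            for s in range(S):
                zval = theta[zoff + s * H + h]
                dev = zval - mu[hc]
                dev2 += dev * dev
                grad[hc] += dev / (sigma[h] * sigma[h])
                grad[zoff + s * H + h] = G[s, h] - dev / (sigma[h] * sigma[h])
            lp += -S * theta[P + h] - 0.5 * dev2 / (sigma[h] * sigma[h])
            grad[P + h] += -S + dev2 / (sigma[h] * sigma[h])
    else:
        for h in range(H):
            for s in range(S):
                zval = theta[zoff + s * H + h]
                lp += -0.5 * zval * zval
                grad[P + h] += sigma[h] * zval * G[s, h]
                grad[zoff + s * H + h] = sigma[h] * G[s, h] - zval
    return lp, grad
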