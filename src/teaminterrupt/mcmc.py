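"""Adaptive Hamiltonian Monte Carlo for models with analytic gradients.

A compact HMC implementation sufficient for the hierarchical logistic
posteriors in this package, which are smooth, log-concave in most directions,
and have cheap exact gradients. Warmup uses dual-averaging step-size
adaptation (Hoffman & Gelman 2014) and a single diagonal mass-matrix update
from mid-warmup draws; trajectories use a jittered number of leapfrog steps to
avoid resonance. Chains are run sequentially and are fully deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

#: energy error beyond which a trajectory is counted as divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class HMCResult:
    """Posterior draws and sampler telemetry.

    ``draws`` has shape (chains, n_draws, dim). ``divergences`` counts
    post-warmup divergent trajectories per chain.
    """

    draws: np.ndarray
    accept_rate: np.ndarray
    step_size: np.ndarray
    divergences: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        """Draws flattened to (chains * n_draws, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])


def _find_initial_step(logp_grad: LogpGrad, q: np.ndarray, inv_mass: np.ndarray,
                       rng: np.random.Generator, leapfrog) -> float:
    """Stan-style heuristic: double/halve until the one-step accept prob crosses 0.5."""
    step = 0.1
    lp0, g0 = logp_grad(q)
    with np.errstate(over="ignore", invalid="ignore"):
        p = rng.standard_normal(q.size) / np.sqrt(inv_mass)
        h0 = lp0 - 0.5 * np.sum(p**2 * inv_mass)
        q1, p1, lp1, _ = leapfrog(q, p, g0, step, 1, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
        direction = 1 if (h1 - h0) > np.log(0.5) else -1
        for _ in range(50):
            step *= 2.0**direction
            q1, p1, lp1, _ = leapfrog(q, p, g0, step, 1, inv_mass)
            h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            if direction == 1 and (h1 - h0) <= np.log(0.5):
                break
            if direction == -1 and (h1 - h0) > np.log(0.5):
                break
    return step


def _leapfrog(logp_grad: LogpGrad, q: np.ndarray, p: np.ndarray, grad: np.ndarray,
              step: float, n_steps: int, inv_mass: np.ndarray):
    """Leapfrog integrator; returns (q, p, logp, grad) at the trajectory end."""
    q = q.copy()
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        q += step * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf, grad
        if i < n_steps - 1:
            p += step * grad
    p += 0.5 * step * grad
    return q, p, lp, grad


def sample_hmc(
    logp_grad: LogpGrad,
    init: np.ndarray,
    *,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    target_accept: float = 0.9,
    max_leapfrog: int = 32,
    seed: int = 0,
    init_jitter: float = 0.5,
    leapfrog=None,
) -> HMCResult:
    """Sample a log-density with analytic gradient by adaptive HMC.

    Parameters
    ----------
    logp_grad
        Function returning ``(log density, gradient)`` at a point.
    init
        Starting point (dim,); each chain jitters it independently.
    max_leapfrog
        Upper bound of the leapfrog-step count, jittered uniformly over its
        upper half to avoid resonant trajectories.
    leapfrog
        Optional fused integrator ``(q, p, grad, step, n_steps, inv_mass) ->
        (q, p, logp, grad)``; defaults to a generic implementation calling
        ``logp_grad`` per step.
    """
    init = np.asarray(init, dtype=float)
    if leapfrog is None:
        def leapfrog(q, p, grad, step, n_steps, inv_mass):
            return _leapfrog(logp_grad, q, p, grad, step, n_steps, inv_mass)
    dim = init.size
    all_draws = np.empty((chains, draws, dim))
    accept_rate = np.empty(chains)
    final_step = np.empty(chains)
    divergences = np.zeros(chains, dtype=int)

    # two mass-adaptation windows: a coarse estimate mid-warmup, refined late
    mass_updates = [(int(0.2 * warmup), int(0.5 * warmup)),
                    (int(0.5 * warmup), int(0.85 * warmup))]

    for chain in range(chains):
        rng = np.random.default_rng([int(seed) % (2**31), chain])
        q = init + init_jitter * rng.standard_normal(dim)
        inv_mass = np.ones(dim)
        step = _find_initial_step(logp_grad, q, inv_mass, rng, leapfrog)

        # dual-averaging state (Hoffman & Gelman 2014, defaults)
        mu = np.log(10.0 * step)
        log_step_bar, h_bar, m_da = np.log(step), 0.0, 0
        gamma, t0, kappa = 0.05, 10.0, 0.75

        lp, grad = logp_grad(q)
        window: list[np.ndarray] = []
        n_accept = 0

        min_leapfrog = max(1, max_leapfrog // 2)
        for it in range(warmup + draws):
            p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
            n_steps = int(rng.integers(min_leapfrog, max_leapfrog + 1))
            h0 = lp - 0.5 * np.sum(p0**2 * inv_mass)
            q1, p1, lp1, grad1 = leapfrog(q, p0, grad, step, n_steps, inv_mass)
            with np.errstate(over="ignore", invalid="ignore"):
                h1 = lp1 - 0.5 * np.sum(p1**2 * inv_mass) if np.isfinite(lp1) else -np.inf
            delta_h = h1 - h0
            accept_prob = min(1.0, np.exp(min(delta_h, 0.0)))
            divergent = (not np.isfinite(delta_h)) or (-delta_h > DIVERGENCE_THRESHOLD)
            if not divergent and rng.random() < accept_prob:
                q, lp, grad = q1, lp1, grad1
                if it >= warmup:
                    n_accept += 1

            if it < warmup:
                # dual averaging toward the target acceptance statistic
                m_da += 1
                h_bar = (1 - 1 / (m_da + t0)) * h_bar + (target_accept - accept_prob) / (m_da + t0)
                log_step = mu - np.sqrt(m_da) / gamma * h_bar
                eta = m_da**-kappa
                log_step_bar = eta * log_step + (1 - eta) * log_step_bar
                step = float(np.exp(log_step))
                for w_start, w_end in mass_updates:
                    if w_start <= it < w_end:
                        window.append(q.copy())
                    if it == w_end - 1 and len(window) >= 10:
                        var = np.var(np.asarray(window), axis=0)
                        inv_mass = var + 1e-8
                        window = []
                        # re-initialize step-size search under the new metric
                        step = _find_initial_step(logp_grad, q, inv_mass, rng,
                                                  leapfrog)
                        mu = np.log(10.0 * step)
                        log_step_bar, h_bar, m_da = np.log(step), 0.0, 0
                if it == warmup - 1:
                    step = float(np.exp(log_step_bar))
            else:
                if divergent:
                    divergences[chain] += 1
                all_draws[chain, it - warmup] = q

        accept_rate[chain] = n_accept / draws
        final_step[chain] = step

    return HMCResult(
        draws=all_draws,
        accept_rate=accept_rate,
        step_size=final_step,
        divergences=divergences,
    )
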