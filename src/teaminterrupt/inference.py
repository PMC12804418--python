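"""Hierarchical Bayesian estimation of the interruption/response choice models.

Each candidate model (monotonic / non-monotonic x interrupt / respond) is a
hierarchical logistic model: every subject has their own bias and sensitivity
parameters drawn from Normal population distributions, and each binary decision
is Bernoulli with the model's choice probability. Fitting uses the package's
HMC sampler on a non-centered parameterization with analytic gradients:

    subject coefficient  theta[i, p] = mu[p] + sigma[p] * z[i, p]
    z ~ Normal(0, 1),  mu ~ Normal(0, 2),  sigma ~ Half-Normal(1)
    outcome_n ~ Bernoulli(logistic(sum_p theta[subject_n, p] * X[n, p]))

The same machinery (with a mix of pooled and subject-varying columns) also
powers the descriptive regressions in :mod:`teaminterrupt.regression_analysis`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from . import decision_models as dm
from .io import data_fingerprint, validate_events
from .mcmc import HMCResult, sample_hmc

DEFAULT_PRIOR_MU_SCALE = 2.0
DEFAULT_PRIOR_SIGMA_SCALE = 1.0


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC configuration. Defaults suit final analyses; tests reduce them."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    max_leapfrog: int = 32

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains required for split-Rhat")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, with priors and sampler settings.

    ``fixed_params`` pins named subject-level parameters to constants (their
    design column moves into an offset); used for degenerate-prior checks.
    ``time_per_task`` records the tp convention used upstream of the table.
    """

    model_kind: str
    decision_type: str
    prior_mu_scale: float = DEFAULT_PRIOR_MU_SCALE
    prior_sigma_scale: float = DEFAULT_PRIOR_SIGMA_SCALE
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    fixed_params: Mapping[str, float] = field(default_factory=dict)
    time_per_task: float = dm.DEFAULT_TIME_PER_TASK

    def __post_init__(self) -> None:
        if self.model_kind not in dm.MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {dm.MODEL_KINDS}")
        if self.decision_type not in dm.DECISION_TYPES:
            raise ValueError(f"decision_type must be one of {dm.DECISION_TYPES}")
        if self.prior_mu_scale <= 0 or self.prior_sigma_scale <= 0:
            raise ValueError("prior scales must be > 0")

    @property
    def param_names(self) -> tuple[str, ...]:
        return dm.PARAM_NAMES[(self.model_kind, self.decision_type)]


class HierarchicalLogistic:
    """Log-posterior (+gradient) of a logistic model with subject-varying columns.

    Parameters
    ----------
    X : (n, P) design matrix
    y : (n,) binary outcomes
    subjects : (n,) integer subject codes in [0, S)
    hier : (P,) bool — columns with subject-level variation; pooled columns
        get a single population coefficient.
    offset : (n,) fixed addition to the linear predictor.
    centered : parameterization of the subject effects. Non-centered
        (``theta = mu + sigma*z``, the default) suits the choice models with
        ~24 decisions per subject; centered (subject coefficients sampled
        directly with a ``Normal(mu, sigma)`` prior) mixes better when each
        subject contributes many observations, as in the descriptive
        regressions.
    """

    def __init__(self, X, y, subjects, hier=None, offset=None,
                 prior_mu_scale=DEFAULT_PRIOR_MU_SCALE,
                 prior_sigma_scale=DEFAULT_PRIOR_SIGMA_SCALE,
                 centered=False):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.ascontiguousarray(y, dtype=float)
        self.subjects = np.ascontiguousarray(subjects, dtype=np.int64)
        self.n, self.P = self.X.shape
        self.S = int(self.subjects.max()) + 1 if self.n else 0
        self.hier = np.ones(self.P, bool) if hier is None else np.asarray(hier, bool)
        self.offset = (np.zeros(self.n) if offset is None
                       else np.ascontiguousarray(offset, dtype=float))
        self.H = int(self.hier.sum())
        self.hier_idx = np.flatnonzero(self.hier).astype(np.int64)
        self.mu_scale = float(prior_mu_scale)
        self.sigma_scale = float(prior_sigma_scale)
        self.centered = bool(centered)
        self.dim = self.P + self.H + self.S * self.H

    # --- parameter vector layout: [mu (P)] [log_sigma (H)] [z (S*H)] ---
    # (z holds the subject coefficients themselves under centered=True)
    def unpack(self, theta: np.ndarray):
        mu = theta[: self.P]
        log_sigma = theta[self.P : self.P + self.H]
        z = theta[self.P + self.H :].reshape(self.S, self.H)
        return mu, log_sigma, z

    def subject_coefficients(self, theta: np.ndarray) -> np.ndarray:
        """(S, P) per-subject coefficients implied by a parameter vector."""
        mu, log_sigma, z = self.unpack(theta)
        coef = np.tile(mu, (self.S, 1))
        if self.centered:
            coef[:, self.hier_idx] = z
        else:
            coef[:, self.hier_idx] += np.exp(log_sigma) * z
        return coef

    def linear_predictor(self, theta: np.ndarray) -> np.ndarray:
        coef = self.subject_coefficients(theta)
        return np.einsum("np,np->n", self.X, coef[self.subjects]) + self.offset

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        """Pointwise Bernoulli log-likelihood (n,) at one parameter vector."""
        return dm.bernoulli_loglik(self.linear_predictor(theta), self.y)

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior and gradient (fused kernel; numpy reference below)."""
        from ._kernels import hier_logit_logp_grad

        lp, grad = hier_logit_logp_grad(
            np.ascontiguousarray(theta, dtype=float), self.X, self.y,
            self.subjects, self.hier_idx, self.offset, self.S,
            self.mu_scale, self.sigma_scale, self.centered,
        )
        return float(lp), grad

    def leapfrog(self, q, p, grad, step, n_steps, inv_mass):
        """Fused leapfrog trajectory (numba) for the HMC sampler."""
        from ._kernels import hier_logit_leapfrog

        q, p, lp, grad = hier_logit_leapfrog(
            np.ascontiguousarray(q, dtype=float),
            np.ascontiguousarray(p, dtype=float),
            np.ascontiguousarray(grad, dtype=float),
            float(step), int(n_steps), np.ascontiguousarray(inv_mass, dtype=float),
            self.X, self.y, self.subjects, self.hier_idx, self.offset, self.S,
            self.mu_scale, self.sigma_scale, self.centered,
        )
        return q, p, float(lp), grad

    def _logp_grad_numpy(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        mu, log_sigma, z = self.unpack(theta)
        # clip keeps absurd step-size-search proposals from overflowing sigma**2
        sigma = np.exp(np.clip(log_sigma, -30.0, 30.0))
        eta = self.linear_predictor(theta)
        if not np.isfinite(eta).all():
            return -np.inf, np.zeros(self.dim)
        ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        lp = (
            ll
            - 0.5 * float(np.sum(mu**2)) / self.mu_scale**2
            - 0.5 * float(np.sum(sigma**2)) / self.sigma_scale**2
            + float(np.sum(log_sigma))          # half-normal Jacobian
        )
        r = self.y - expit(eta)                  # (n,) residuals
        grad = np.empty(self.dim)
        # d/d mu_p : sum_n r_n X_np
        grad[: self.P] = self.X.T @ r - mu / self.mu_scale**2
        if self.H:
            # per-subject accumulations G[i, p] = sum_{n in subject i} r_n X_np
            G = np.empty((self.S, self.H))
            for j, p in enumerate(self.hier_idx):
                G[:, j] = np.bincount(
                    self.subjects, weights=r * self.X[:, p], minlength=self.S
                )
        if self.H and self.centered:
            # z holds the subject coefficients; Normal(mu, sigma) prior on them
            dev = z - mu[self.hier_idx]
            lp += float(-self.S * np.sum(log_sigma)
                        - 0.5 * np.sum((dev / sigma) ** 2))
            grad[self.hier_idx] = (dev / sigma**2).sum(axis=0) \
                - mu[self.hier_idx] / self.mu_scale**2
            grad[self.P : self.P + self.H] = (
                -self.S + np.sum(dev**2, axis=0) / sigma**2
                - sigma**2 / self.sigma_scale**2 + 1.0
            )
            grad[self.P + self.H :] = (G - dev / sigma**2).ravel()
        elif self.H:
            lp += -0.5 * float(np.sum(z**2))
            grad[self.P : self.P + self.H] = (
                sigma * np.sum(z * G, axis=0) - sigma**2 / self.sigma_scale**2 + 1.0
            )
            grad[self.P + self.H :] = (sigma * G - z).ravel()
        return lp, grad


@dataclass
class FitResult:
    """Posterior draws and diagnostics for one model on one dataset.

    Population draws are exposed by name (``mu_<param>``, ``sigma_<param>``)
    with shape (chains, draws); ``subject_draws`` has shape
    (chains, draws, S, P). ``log_lik`` is the per-draw per-event matrix
    (chains, draws, n) in event order.
    """

    spec: ModelSpec
    population_draws: dict[str, np.ndarray]
    subject_draws: np.ndarray
    subject_ids: list[str]
    log_lik: np.ndarray
    diagnostics: dict
    fingerprint: str
    seed: int
    events: pd.DataFrame

    @property
    def failed(self) -> bool:
        return bool(self.diagnostics.get("failed", False))

    @property
    def n_events(self) -> int:
        return self.log_lik.shape[-1]

    def posterior_mean_params(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.population_draws.items()}


def preprocess(events: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove decisions made after the deadline, where time pressure is undefined.

    Drops rows with ``time_available <= 0`` or non-finite time pressures and
    reports counts and fractions removed per decision type.

    Raises
    ------
    ValueError
        If nothing survives the filter.
    """
    validate_events(events)
    tp = events[["tp_interrupter", "tp_interruptee"]].to_numpy(float)
    bad = (events["time_available"].to_numpy(float) <= 0) | ~np.isfinite(tp).all(axis=1)
    kept = events.loc[~bad].reset_index(drop=True)
    report: dict = {"n_input": int(len(events)), "n_removed": int(bad.sum()),
                    "n_kept": int(len(kept)), "by_decision_type": {}}
    for dt, grp in events.groupby("decision_type"):
        removed = int(bad[grp.index.to_numpy()].sum()) if len(grp) else 0
        report["by_decision_type"][dt] = {
            "n": int(len(grp)),
            "n_removed": removed,
            "fraction_removed": removed / len(grp) if len(grp) else 0.0,
        }
    if kept.empty:
        raise ValueError("no events remain after post-deadline filtering")
    return kept, report


def _build_model(events: pd.DataFrame, spec: ModelSpec):
    sub = events.loc[events["decision_type"] == spec.decision_type]
    if sub.empty:
        raise ValueError(f"no events of decision_type {spec.decision_type!r}")
    subject_ids = sorted(sub["subject_id"].astype(str).unique())
    codes = sub["subject_id"].astype(str).map({s: i for i, s in enumerate(subject_ids)})
    X = dm.design_matrix(sub, spec.model_kind)
    names = list(spec.param_names)
    offset = np.zeros(len(sub))
    keep = []
    for j, name in enumerate(names):
        if name in spec.fixed_params:
            offset += spec.fixed_params[name] * X[:, j]
        else:
            keep.append(j)
    free_names = [names[j] for j in keep]
    model = HierarchicalLogistic(
        X[:, keep], sub["outcome"].to_numpy(float), codes.to_numpy(int),
        offset=offset, prior_mu_scale=spec.prior_mu_scale,
        prior_sigma_scale=spec.prior_sigma_scale,
    )
    return model, sub.reset_index(drop=True), subject_ids, free_names


def fit(events: pd.DataFrame, spec: ModelSpec, seed: int) -> FitResult:
    """Fit one hierarchical choice model by HMC.

    ``events`` should already be preprocessed (no post-deadline rows). Returns
    a :class:`FitResult`; convergence problems are recorded in
    ``result.diagnostics`` (``failed`` when split-Rhat of any population
    parameter exceeds 1.05) rather than raised, so that callers can report
    them.
    """
    model, sub, subject_ids, free_names = _build_model(events, spec)
    if len(subject_ids) < 2:
        warnings.warn("fewer than 2 subjects: population SDs are prior-driven")
    st = spec.sampler
    res = sample_hmc(
        model.logp_grad, np.zeros(model.dim), chains=st.chains, warmup=st.warmup,
        draws=st.draws, target_accept=st.target_accept,
        max_leapfrog=st.max_leapfrog, seed=seed, leapfrog=model.leapfrog,
    )
    return _package_fit(model, res, sub, subject_ids, free_names, spec, seed)


def _package_fit(model: HierarchicalLogistic, res: HMCResult, sub: pd.DataFrame,
                 subject_ids: list[str], free_names: list[str], spec: ModelSpec,
                 seed: int) -> FitResult:
    chains, ndraws, _ = res.draws.shape
    pop: dict[str, np.ndarray] = {}
    for j, name in enumerate(free_names):
        pop[f"mu_{name}"] = res.draws[:, :, j]
    for h, j in enumerate(model.hier_idx):
        pop[f"sigma_{free_names[j]}"] = np.exp(res.draws[:, :, model.P + h])

    subj = np.empty((chains, ndraws, model.S, model.P))
    log_lik = np.empty((chains, ndraws, model.n))
    for c in range(chains):
        for d in range(ndraws):
            theta = res.draws[c, d]
            subj[c, d] = model.subject_coefficients(theta)
            log_lik[c, d] = model.loglik(theta)

    idata = az.from_dict(posterior=pop)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rhats = {k: float(rhat[k].values) for k in pop}
    esss = {k: float(ess[k].values) for k in pop}
    max_rhat = max(rhats.values())
    diagnostics = {
        "rhat": rhats,
        "ess_bulk": esss,
        "max_rhat": max_rhat,
        "min_ess_bulk": min(esss.values()),
        "divergences": int(res.divergences.sum()),
        "accept_rate": res.accept_rate.tolist(),
        "failed": bool(max_rhat > 1.05),
        "warnings": [],
    }
    if max_rhat > 1.01:
        diagnostics["warnings"].append(f"max split-Rhat {max_rhat:.3f} > 1.01")
    if diagnostics["divergences"]:
        diagnostics["warnings"].append(f"{diagnostics['divergences']} divergent transitions")

    return FitResult(
        spec=spec, population_draws=pop, subject_draws=subj,
        subject_ids=subject_ids, log_lik=log_lik, diagnostics=diagnostics,
        fingerprint=data_fingerprint(sub), seed=int(seed), events=sub,
    )


def summarize(fit_result: FitResult, force: bool = False) -> pd.DataFrame:
    """Posterior summary table for population-level parameters.

    One row per parameter: posterior mean, SD, 2.5%/97.5% quantiles and a
    ``credible`` flag (true when the 95% interval excludes zero). Refuses to
    summarize a failed fit unless ``force`` is set.
    """
    if fit_result.failed and not force:
        raise RuntimeError(
            "fit did not converge: " + str(fit_result.diagnostics["rhat"])
        )
    rows = []
    for name, draws in fit_result.population_draws.items():
        flat = draws.ravel()
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "q2.5": float(lo),
            "q97.5": float(hi),
            "credible": bool(lo > 0 or hi < 0),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Surface:
    """Choice-probability surface over a time-pressure grid.

    ``prob[i, j]`` is the probability at ``tp_interrupter = tp_interrupter[i]``,
    ``tp_interruptee = tp_interruptee[j]``. ``method`` records how subject
    effects were handled.
    """

    tp_interrupter: np.ndarray
    tp_interruptee: np.ndarray
    prob: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(
            np.arange(len(self.tp_interrupter)), np.arange(len(self.tp_interruptee)),
            indexing="ij",
        )
        return pd.DataFrame({
            "tp_interrupter": self.tp_interrupter[ii.ravel()],
            "tp_interruptee": self.tp_interruptee[jj.ravel()],
            "probability": self.prob.ravel(),
        })


def _eta_grid(spec: ModelSpec, bias, lin, quad, tp_er, tp_ee):
    d1 = tp_er[:, None] - tp_ee[None, :]
    if spec.model_kind == "monotonic":
        return bias + lin * d1
    d2 = tp_er[:, None] ** 2 - tp_ee[None, :] ** 2
    return bias + lin * d1 + quad * d2


def predict_surface(
    fit_result: FitResult,
    tp_interrupter: Sequence[float],
    tp_interruptee: Sequence[float],
    method: str = "population-mean-draws",
) -> Surface:
    """Posterior choice-probability surface over a (tp_interrupter, tp_interruptee) grid.

    ``population-mean-draws`` (default) averages the probability over the
    posterior draws of the population means — the predicted surface for a
    typical subject. ``plug-in`` evaluates once at the posterior-mean
    parameters.
    """
    if fit_result.failed:
        raise RuntimeError("cannot predict from a non-converged fit")
    tp_er = np.asarray(tp_interrupter, dtype=float)
    tp_ee = np.asarray(tp_interruptee, dtype=float)
    if (tp_er < 0).any() or (tp_ee < 0).any():
        raise ValueError("time-pressure grid must be non-negative")
    spec = fit_result.spec
    names = spec.param_names
    mus = [fit_result.population_draws[f"mu_{n}"].ravel()
           for n in names if f"mu_{n}" in fit_result.population_draws]
    while len(mus) < 3:
        mus.append(np.zeros_like(mus[0]))
    bias_d, lin_d, quad_d = mus[0], mus[1], mus[2]
    if method == "plug-in":
        prob = expit(_eta_grid(spec, bias_d.mean(), lin_d.mean(), quad_d.mean(),
                               tp_er, tp_ee))
    elif method == "population-mean-draws":
        prob = np.zeros((len(tp_er), len(tp_ee)))
        for b, l, q in zip(bias_d, lin_d, quad_d):
            prob += expit(_eta_grid(spec, b, l, q, tp_er, tp_ee))
        prob /= len(bias_d)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Surface(tp_er, tp_ee, prob, method)


def posterior_predictive_bins(
    fit_result: FitResult, events: pd.DataFrame | None = None, n_bins: int = 4
) -> pd.DataFrame:
    """Observed vs predicted choice rates, binned for calibration plots.

    Panels split events at the quartiles of the empirical interruptee time
    pressure; within each panel events are grouped into ``n_bins`` equal-count
    bins of interrupter time pressure. For each panel/bin the table reports the
    observed mean outcome with its standard error and the model-predicted mean
    rate with a 95% posterior band (subject-level parameters, so the band
    reflects both population and subject uncertainty). Empty bins are absent
    from the table.
    """
    if events is None:
        events = fit_result.events
    sub = events.loc[events["decision_type"] == fit_result.spec.decision_type]
    sub = sub.reset_index(drop=True)
    if not len(sub):
        raise ValueError("no events of the fitted decision type")

    tp_ee = sub["tp_interruptee"].to_numpy(float)
    tp_er = sub["tp_interrupter"].to_numpy(float)
    y = sub["outcome"].to_numpy(float)

    panel_edges = np.quantile(tp_ee, [0.25, 0.5, 0.75])
    panel = np.searchsorted(panel_edges, tp_ee)

    # per-draw per-event probabilities from the fitted subject parameters
    code = {s: i for i, s in enumerate(fit_result.subject_ids)}
    subj_idx = sub["subject_id"].astype(str).map(code).to_numpy(int)
    X = dm.design_matrix(sub, fit_result.spec.model_kind)
    coef = fit_result.subject_draws.reshape(-1, *fit_result.subject_draws.shape[2:])
    eta = np.einsum("np,dnp->dn", X, coef[:, subj_idx, :])
    p = expit(eta)  # (draws, n)

    rows = []
    for pan in range(4):
        mask = panel == pan
        if not mask.any():
            continue
        k = min(n_bins, max(1, int(mask.sum())))
        edges = np.quantile(tp_er[mask], np.linspace(0, 1, k + 1)[1:-1])
        bins = np.searchsorted(edges, tp_er[mask])
        for b in range(k):
            in_bin = mask.copy()
            in_bin[mask] = bins == b
            m = int(in_bin.sum())
            if m == 0:
                continue
            obs = float(y[in_bin].mean())
            pred = p[:, in_bin].mean(axis=1)
            lo, hi = np.quantile(pred, [0.025, 0.975])
            rows.append({
                "panel": pan,
                "panel_tp_interruptee_mean": float(tp_ee[in_bin].mean()),
                "bin": b,
                "bin_tp_interrupter_mean": float(tp_er[in_bin].mean()),
                "n": m,
                "observed_rate": obs,
                "observed_se": float(np.sqrt(max(obs * (1 - obs), 1e-12) / m)),
                "predicted_mean": float(pred.mean()),
                "predicted_lo": float(lo),
                "predicted_hi": float(hi),
            })
    return pd.DataFrame(rows)
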