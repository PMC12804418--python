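"""Descriptive Bayesian logistic regressions of interruption/acceptance rates.

Separate from the process models, these regressions ask how the participant's
progress, the coworker's progress, and the time remaining (all standardized)
relate to the probability of interrupting or of accepting an interruption,
including all pairwise interactions. Subjects get random intercepts by default
(repeated measures). Fitting reuses the package's hierarchical logistic
machinery; predictions are rendered as probability heat maps over a
standardized [-2, 2] x [-2, 2] grid with the third predictor held at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import HierarchicalLogistic, SamplerSettings
from .mcmc import sample_hmc

import arviz as az

PREDICTORS = ("time_remaining", "participant_progress", "coworker_progress")


@dataclass(frozen=True)
class RegressionDesign:
    """Configuration of one descriptive regression."""

    outcome: str  # "interrupt" or "accept"
    predictors: tuple[str, ...] = PREDICTORS
    random_intercept: bool = True
    prior_scale: float = 2.0
    intercept_sd_prior_scale: float = 1.0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)

    def __post_init__(self) -> None:
        if self.outcome not in ("interrupt", "accept"):
            raise ValueError("outcome must be 'interrupt' or 'accept'")

    @property
    def terms(self) -> tuple[str, ...]:
        inter = tuple(f"{a}:{b}" for a, b in combinations(self.predictors, 2))
        return ("intercept",) + self.predictors + inter


def standardize(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Z-score a covariate; returns (z, location, scale).

    Uses the population-SD convention (ddof=0). The stored location/scale let
    prediction grids on the standardized [-2, 2] range be mapped back to the
    original units.

    Raises
    ------
    ValueError
        For constant input, where the scale is undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("standardization undefined for constant input")
    loc = float(x.mean())
    scale = float(x.std(ddof=0))
    return (x - loc) / scale, loc, scale


@dataclass
class RegressionFit:
    """Posterior of one descriptive regression.

    ``coef_draws`` maps term name to draws of shape (chains, draws); the
    summary table carries posterior means, 95% intervals and credible flags.
    """

    design: RegressionDesign
    coef_draws: dict[str, np.ndarray]
    scaling: dict[str, tuple[float, float]]
    diagnostics: dict
    seed: int

    @property
    def failed(self) -> bool:
        return bool(self.diagnostics.get("failed", False))

    def summary(self, force: bool = False) -> pd.DataFrame:
        if self.failed and not force:
            raise RuntimeError(f"regression did not converge: {self.diagnostics['rhat']}")
        rows = []
        for name, draws in self.coef_draws.items():
            flat = draws.ravel()
            lo, hi = np.quantile(flat, [0.025, 0.975])
            rows.append({
                "term": name, "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(lo), "q97.5": float(hi),
                "credible": bool(lo > 0 or hi < 0),
            })
        return pd.DataFrame(rows)

    def posterior_mean_coefs(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.coef_draws.items()
                if not k.startswith("sigma_")}


def _build_design_matrix(df: pd.DataFrame, design: RegressionDesign,
                         prestandardized: bool):
    cols = {"intercept": np.ones(len(df))}
    scaling: dict[str, tuple[float, float]] = {}
    for p in design.predictors:
        if prestandardized:
            z = df[p].to_numpy(float)
            scaling[p] = (0.0, 1.0)
        else:
            z, loc, scale = standardize(df[p])
            scaling[p] = (loc, scale)
        cols[p] = z
    for a, b in combinations(design.predictors, 2):
        cols[f"{a}:{b}"] = cols[a] * cols[b]
    X = np.column_stack([cols[t] for t in design.terms])
    return X, scaling


def fit_logistic_regression(
    df: pd.DataFrame,
    design: RegressionDesign,
    seed: int,
    prestandardized: bool = False,
) -> RegressionFit:
    """Fit the progress/time-remaining logistic regression by HMC.

    ``df`` needs columns ``subject_id``, ``outcome`` (binary) and the design's
    predictors. Predictors are standardized on the analysis set unless
    ``prestandardized`` is set. With ``random_intercept`` the intercept varies
    by subject around its population mean.
    """
    if not np.isfinite(df[list(design.predictors)].to_numpy(float)).all():
        raise ValueError("predictors must be finite")
    X, scaling = _build_design_matrix(df, design, prestandardized)
    subjects, _ = pd.factorize(df["subject_id"], sort=True)
    hier = np.zeros(X.shape[1], bool)
    hier[0] = design.random_intercept
    # centered subject intercepts: each subject contributes many events here,
    # so the data-dominated geometry mixes far better than non-centered
    model = HierarchicalLogistic(
        X, df["outcome"].to_numpy(float), subjects, hier=hier,
        prior_mu_scale=design.prior_scale,
        prior_sigma_scale=design.intercept_sd_prior_scale,
        centered=True,
    )
    st = design.sampler
    res = sample_hmc(model.logp_grad, np.zeros(model.dim), chains=st.chains,
                     warmup=st.warmup, draws=st.draws,
                     target_accept=st.target_accept,
                     max_leapfrog=st.max_leapfrog, seed=seed,
                     leapfrog=model.leapfrog)

    coef_draws = {t: res.draws[:, :, j] for j, t in enumerate(design.terms)}
    if design.random_intercept:
        coef_draws["sigma_intercept"] = np.exp(res.draws[:, :, model.P])

    idata = az.from_dict(posterior=coef_draws)
    rhat = az.rhat(idata)
    rhats = {k: float(rhat[k].values) for k in coef_draws}
    max_rhat = max(rhats.values())
    diagnostics = {
        "rhat": rhats,
        "max_rhat": max_rhat,
        "divergences": int(res.divergences.sum()),
        "failed": bool(max_rhat > 1.05),
    }
    return RegressionFit(design=design, coef_draws=coef_draws, scaling=scaling,
                         diagnostics=diagnostics, seed=int(seed))


def prediction_heatmap(
    fit: RegressionFit,
    pair: tuple[str, str],
    grid: np.ndarray | None = None,
    method: str = "posterior-mean-draws",
) -> pd.DataFrame:
    """Predicted probability surface over a standardized predictor pair.

    The two named predictors vary over ``grid`` (default 41 points on
    [-2, 2]); the remaining predictor is held at 0 (its mean). Returns a tidy
    frame with columns ``x``, ``y``, ``probability``; deterministic given the
    fit. ``method='plug-in'`` evaluates at posterior-mean coefficients,
    the default averages the probability over posterior draws.
    """
    if fit.failed:
        raise RuntimeError("cannot predict from a non-converged regression fit")
    a, b = pair
    design = fit.design
    if a not in design.predictors or b not in design.predictors:
        raise ValueError(f"unknown predictor pair {pair}")
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 41)
    grid = np.asarray(grid, dtype=float)
    if np.abs(grid).max() > 3.0:
        import warnings

        warnings.warn("grid extends beyond 3 SDs: extrapolating far outside the data")

    xx, yy = np.meshgrid(grid, grid, indexing="ij")
    values = {p: np.zeros_like(xx) for p in design.predictors}
    values[a], values[b] = xx, yy

    def eta_at(coefs: dict[str, float]) -> np.ndarray:
        eta = np.full_like(xx, coefs["intercept"])
        for p in design.predictors:
            eta = eta + coefs[p] * values[p]
        for u, v in combinations(design.predictors, 2):
            eta = eta + coefs[f"{u}:{v}"] * values[u] * values[v]
        return eta

    if method == "plug-in":
        prob = expit(eta_at(fit.posterior_mean_coefs()))
    elif method == "posterior-mean-draws":
        names = [t for t in design.terms]
        flat = {t: fit.coef_draws[t].ravel() for t in names}
        ndraws = len(flat["intercept"])
        prob = np.zeros_like(xx)
        for d in range(ndraws):
            prob += expit(eta_at({t: flat[t][d] for t in names}))
        prob /= ndraws
    else:
        raise ValueError(f"unknown method {method!r}")

    return pd.DataFrame({
        "x": xx.ravel(), "y": yy.ravel(), "probability": prob.ravel(),
        "x_name": a, "y_name": b,
    })


def save_heatmap_png(surface: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a prediction surface to a PNG (lighter = higher probability)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.sort(surface["x"].unique())
    y = np.sort(surface["y"].unique())
    z = surface.pivot_table(index="x", columns="y", values="probability").to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(z.T, origin="lower", extent=[x[0], x[-1], y[0], y[-1]],
                   aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel(str(surface["x_name"].iloc[0]))
    ax.set_ylabel(str(surface["y_name"].iloc[0]))
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="probability")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
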