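"""Synthetic decision datasets with known ground truth.

The original behavioral data are not distributed with this package, so every
inference and model-comparison routine is validated on data generated from the
models themselves: subject-level parameters are drawn from Normal population
distributions (the hierarchical generative assumption), decision contexts
(time-pressure pairs) come either from a stated sampling law or from the task
simulator, and outcomes are Bernoulli draws from the chosen model family.

The default direct-context law is independent uniform time pressure on
[0.2, 2.0] for each role — spanning comfortably under-loaded (TP well below 1)
to clearly over-loaded (TP = 2) while keeping time pressure defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import decision_models as dm
from .io import validate_events

#: condition labels cycled through in direct mode so the schema is complete
_DEADLINES = (960, 1320, 1680)
_ERROR_IMPACTS = (3, 6)
#: inert but schema-required time_available (s) attached to direct-mode rows
_DIRECT_TIME_AVAILABLE = 600.0


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level description of a synthetic cohort.

    ``means``/``sds`` map subject-parameter names (e.g. ``gamma``, ``delta``
    for the monotonic respond model) to the Normal population moments they are
    drawn from. ``context_source`` selects uniform direct sampling of
    time-pressure pairs or the full task simulator.
    """

    model_kind: str
    decision_type: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    n_subjects: int
    decisions_per_subject: int
    context_source: str = "direct"
    tp_low: float = 0.2
    tp_high: float = 2.0

    def __post_init__(self) -> None:
        if self.model_kind not in dm.MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {dm.MODEL_KINDS}")
        if self.decision_type not in dm.DECISION_TYPES:
            raise ValueError(f"decision_type must be one of {dm.DECISION_TYPES}")
        if self.context_source not in ("direct", "simulator"):
            raise ValueError("context_source must be 'direct' or 'simulator'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        expected = set(dm.PARAM_NAMES[(self.model_kind, self.decision_type)])
        for m in (self.means, self.sds):
            if set(m) != expected:
                raise ValueError(f"parameter names must be exactly {sorted(expected)}")
        if any(v < 0 for v in self.sds.values()):
            raise ValueError("population SDs must be >= 0")
        if self.tp_low < 0 or self.tp_high <= self.tp_low:
            raise ValueError("tp support must satisfy 0 <= tp_low < tp_high")

    @property
    def param_names(self) -> tuple[str, ...]:
        return dm.PARAM_NAMES[(self.model_kind, self.decision_type)]


@dataclass(frozen=True)
class GroundTruth:
    """Record of what generated a synthetic dataset, for recovery bookkeeping."""

    spec: PopulationSpec
    subject_params: pd.DataFrame  # one row per subject, columns = param names
    seed: int

    def to_dict(self) -> dict:
        return {
            "spec": {**asdict(self.spec),
                     "means": dict(self.spec.means), "sds": dict(self.spec.sds)},
            "subject_params": self.subject_params.to_dict(orient="list"),
            "seed": self.seed,
        }


def sample_subjects(spec: PopulationSpec, rng: np.random.Generator,
                    seed: int = 0) -> GroundTruth:
    """Draw each subject's parameters independently from Normal(mean, SD)."""
    names = spec.param_names
    draws = {
        name: spec.means[name] + spec.sds[name] * rng.standard_normal(spec.n_subjects)
        for name in names
    }
    df = pd.DataFrame(draws)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(spec.n_subjects)])
    return GroundTruth(spec=spec, subject_params=df, seed=int(seed))


def _role_tps(spec: PopulationSpec, rng: np.random.Generator, n: int):
    """Sample (tp_interrupter, tp_interruptee) pairs from the direct law."""
    tp = rng.uniform(spec.tp_low, spec.tp_high, size=(n, 2))
    return tp[:, 0], tp[:, 1]


def generate_dataset(
    spec: PopulationSpec, seed: int, sim_config=None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a schema-conforming decision-event table plus its ground truth.

    Direct mode draws time-pressure pairs from the spec's uniform law and
    outcomes as Bernoulli with the model's choice probability. Simulator mode
    runs a full task block per subject with that subject's parameters as the
    participant policy and keeps the events of the spec's decision type.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    truth = sample_subjects(spec, rng, seed=seed)

    if spec.context_source == "simulator":
        from . import simulator as sim

        frames = []
        base = sim.SimConfig() if sim_config is None else sim_config
        for i, row in truth.subject_params.iterrows():
            params = _row_params(spec, row)
            policy = sim.ParticipantPolicy(model_kind=spec.model_kind, params=params)
            block_seed = int(rng.integers(2**31))
            log = sim.run_block(base, policy, seed=block_seed)
            ev = sim.extract_decision_events(log, base)
            ev = ev.loc[ev["decision_type"] == spec.decision_type].copy()
            ev["subject_id"] = row["subject_id"]
            frames.append(ev)
        df = pd.concat(frames, ignore_index=True)
        return validate_events(df), truth

    n_per = spec.decisions_per_subject
    names = spec.param_names
    values = truth.subject_params[list(names)].to_numpy(float)
    rows = []
    for i in range(spec.n_subjects):
        tp_er, tp_ee = _role_tps(spec, rng, n_per)
        bias = values[i, 0]
        lin = values[i, 1]
        quad = values[i, 2] if len(names) == 3 else 0.0
        eta = bias + lin * (tp_er - tp_ee) + quad * (tp_er**2 - tp_ee**2)
        y = (rng.random(n_per) < expit(eta)).astype(int)
        sid = truth.subject_params.loc[i, "subject_id"]
        for j in range(n_per):
            rows.append({
                "subject_id": sid,
                "block": 1 + (j % 2),
                "decision_type": spec.decision_type,
                "tp_interrupter": tp_er[j],
                "tp_interruptee": tp_ee[j],
                "outcome": int(y[j]),
                "time_available": _DIRECT_TIME_AVAILABLE,
                "deadline_condition": _DEADLINES[i % 3],
                "error_impact_condition": _ERROR_IMPACTS[j % 2],
            })
    df = pd.DataFrame(rows)
    return validate_events(df), truth


def _row_params(spec: PopulationSpec, row: pd.Series) -> dm.Params:
    """Build a params object for one subject, zero-filling the unused decision side."""
    if spec.model_kind == "monotonic":
        if spec.decision_type == "interrupt":
            return dm.MonotonicParams(alpha=row["alpha"], beta=row["beta"])
        return dm.MonotonicParams(gamma=row["gamma"], delta=row["delta"])
    if spec.decision_type == "interrupt":
        return dm.NonMonotonicParams(alpha=row["alpha"], tau=row["tau"],
                                     omega=row["omega"])
    return dm.NonMonotonicParams(gamma=row["gamma"], kappa=row["kappa"],
                                 lambda_=row["lambda"])


def generate_regression_dataset(
    n_events: int,
    n_subjects: int,
    coefficients: Mapping[str, float],
    seed: int,
    subject_intercept_sd: float = 0.5,
) -> pd.DataFrame:
    """Synthetic data for the descriptive progress/time-remaining regressions.

    Standardized predictors ``time_remaining``, ``participant_progress`` and
    ``coworker_progress`` are drawn i.i.d. standard Normal; the binary outcome
    follows a logistic model with the given coefficients (keys: ``intercept``,
    predictor names, and interaction names like
    ``participant_progress:time_remaining``). Subjects get Normal random
    intercepts with SD ``subject_intercept_sd``.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    preds = ["time_remaining", "participant_progress", "coworker_progress"]
    X = {p: rng.standard_normal(n_events) for p in preds}
    eta = np.full(n_events, float(coefficients.get("intercept", 0.0)))
    for p in preds:
        eta += float(coefficients.get(p, 0.0)) * X[p]
    for i, a in enumerate(preds):
        for b in preds[i + 1:]:
            key = f"{a}:{b}"
            key_rev = f"{b}:{a}"
            coef = float(coefficients.get(key, coefficients.get(key_rev, 0.0)))
            eta += coef * X[a] * X[b]
    subj = rng.integers(n_subjects, size=n_events)
    intercepts = subject_intercept_sd * rng.standard_normal(n_subjects)
    eta += intercepts[subj]
    y = (rng.random(n_events) < expit(eta)).astype(int)
    df = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in subj],
        "outcome": y,
        **X,
    })
    return df
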