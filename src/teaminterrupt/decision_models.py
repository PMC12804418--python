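"""Choice models for interruption and response decisions driven by time pressure.

Two team members (in the motivating setting, nurses discharging ICU patients)
decide whether to interrupt one another and whether to accept an interruption.
Both decisions are modelled as Bernoulli choices whose log-odds compare the
benefit of the interruption to the interrupter against its cost to the
interruptee. With task importance held constant, benefit and cost are driven
entirely by each member's *time pressure*: the ratio of the time required to
finish all outstanding tasks to the time available before the deadline.

Two model families are implemented:

* **monotonic** — log-odds are ``bias + sensitivity * (b - c)`` where the
  benefit ``b`` is the interrupter's time pressure and the cost ``c`` the
  interruptee's; the choice probability increases monotonically in the
  benefit-cost difference.
* **non-monotonic** — benefit and cost are quadratic in each side's time
  pressure, ``b = tau*tp + omega*tp**2`` (linear and quadratic sensitivities),
  and enter the log-odds with a unit coefficient: ``bias + (b - c)``. With a
  negative quadratic term the influence of time pressure is an inverted U.

Interrupt decisions use bias/sensitivity parameters (alpha, beta) or
(alpha, tau, omega); response (accept) decisions use (gamma, delta) or
(gamma, kappa, lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

ModelKind = Literal["monotonic", "nonmonotonic"]
DecisionType = Literal["interrupt", "respond"]

MODEL_KINDS: tuple[str, ...] = ("monotonic", "nonmonotonic")
DECISION_TYPES: tuple[str, ...] = ("interrupt", "respond")

#: seconds a single task question is assumed to take (coworker service time
#: and the unit of "time required" in the time-pressure ratio)
DEFAULT_TIME_PER_TASK = 11.0


class UndefinedTimePressureError(ValueError):
    """Raised when time pressure is requested with no time left before the deadline."""


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class TimePressureContext:
    """Workload snapshot from which a team member's time pressure is computed.

    Parameters
    ----------
    tasks_remaining
        Uncompleted questions across both of the member's patients.
    time_available
        Seconds until the deadline (deadline minus time used). Time pressure
        is undefined once this reaches zero.
    time_per_task
        Seconds each remaining question is expected to take (default 11 s).
    """

    tasks_remaining: int
    time_available: float
    time_per_task: float = DEFAULT_TIME_PER_TASK

    def __post_init__(self) -> None:
        if self.tasks_remaining < 0:
            raise ValueError("tasks_remaining must be >= 0")
        if self.time_per_task <= 0:
            raise ValueError("time_per_task must be > 0")


@dataclass(frozen=True)
class BenefitCost:
    """Interrupter benefit ``b`` and interruptee cost ``c`` of an interruption."""

    b: float
    c: float

    def __post_init__(self) -> None:
        _require_finite(b=self.b, c=self.c)


@dataclass(frozen=True)
class MonotonicParams:
    """Bias/sensitivity parameters of the monotonic family for one subject.

    ``alpha``/``beta`` govern interrupt decisions, ``gamma``/``delta`` response
    decisions. A bias above zero indicates a tendency to interrupt (or accept);
    sensitivity weights the benefit-cost difference.
    """

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(**{f.name: getattr(self, f.name) for f in fields(self)})


@dataclass(frozen=True)
class NonMonotonicParams:
    """Parameters of the non-monotonic (quadratic benefit/cost) family.

    ``tau``/``omega`` are the interrupter's linear and quadratic sensitivities
    to time pressure, ``kappa``/``lambda_`` the interruptee's. An inverted-U
    effect of time pressure requires the quadratic term to be negative.
    """

    alpha: float = 0.0
    tau: float = 0.0
    omega: float = 0.0
    gamma: float = 0.0
    kappa: float = 0.0
    lambda_: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(**{f.name: getattr(self, f.name) for f in fields(self)})


Params = Union[MonotonicParams, NonMonotonicParams]


@dataclass(frozen=True)
class DecisionEvent:
    """One binary interruption or response decision with its context.

    ``tp_interrupter``/``tp_interruptee`` are stored by *role*: for an
    interrupt decision the deciding participant is the interrupter; for a
    respond decision the coworker is the interrupter and the participant the
    interruptee. ``outcome`` is 1 if the interruption was made / accepted.
    """

    subject_id: str
    block: int
    decision_type: str
    tp_interrupter: float
    tp_interruptee: float
    outcome: int
    time_available: float
    deadline_condition: int
    error_impact_condition: int

    def __post_init__(self) -> None:
        if self.decision_type not in DECISION_TYPES:
            raise ValueError(f"decision_type must be one of {DECISION_TYPES}")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")


def compute_time_pressure(ctx: TimePressureContext) -> float:
    """Time pressure: time required for outstanding tasks over time available.

    Returns ``tasks_remaining * time_per_task / time_available``. A value
    above one means the member cannot finish before the deadline at the
    assumed pace.

    Raises
    ------
    UndefinedTimePressureError
        If ``time_available <= 0`` — past the deadline the ratio is undefined
        and callers must filter such instances.
    """
    if ctx.time_available <= 0:
        raise UndefinedTimePressureError(
            f"time pressure undefined for time_available={ctx.time_available}"
        )
    return ctx.tasks_remaining * ctx.time_per_task / ctx.time_available


def logistic(x):
    """Standard logistic function 1 / (1 + exp(-x)), stable for large |x|."""
    return expit(x)


def p_choice_monotonic(bias: float, sensitivity: float, bc: BenefitCost) -> float:
    """Choice probability under the monotonic model: logistic(bias + sens*(b-c))."""
    _require_finite(bias=bias, sensitivity=sensitivity)
    return float(expit(bias + sensitivity * (bc.b - bc.c)))


def p_choice_nonmonotonic(bias: float, bc: BenefitCost) -> float:
    """Choice probability under the non-monotonic model: logistic(bias + (b-c)).

    The sensitivities live inside ``b`` and ``c`` (see
    :func:`benefit_cost_nonmono_interrupt`), so the benefit-cost difference
    enters with a unit coefficient.
    """
    _require_finite(bias=bias)
    return float(expit(bias + (bc.b - bc.c)))


def benefit_cost_nonmono_interrupt(
    tau: float, omega: float, tp_p: float, tp_c: float
) -> BenefitCost:
    """Quadratic benefit/cost for an interrupt decision.

    The participant is the interrupter: ``b = tau*tp_p + omega*tp_p**2`` from
    their own time pressure, ``c`` the same form in the coworker's.
    """
    _require_finite(tau=tau, omega=omega, tp_p=tp_p, tp_c=tp_c)
    return BenefitCost(
        b=tau * tp_p + omega * tp_p**2,
        c=tau * tp_c + omega * tp_c**2,
    )


def benefit_cost_nonmono_respond(
    kappa: float, lambda_: float, tp_c: float, tp_p: float
) -> BenefitCost:
    """Quadratic benefit/cost for a response decision.

    The coworker is the interrupter, so benefit is quadratic in the coworker's
    time pressure ``tp_c`` and cost quadratic in the participant's own ``tp_p``.
    """
    _require_finite(kappa=kappa, lambda_=lambda_, tp_c=tp_c, tp_p=tp_p)
    return BenefitCost(
        b=kappa * tp_c + lambda_ * tp_c**2,
        c=kappa * tp_p + lambda_ * tp_p**2,
    )


def _params_for(params: Params, model_kind: str, decision_type: str) -> tuple[float, ...]:
    """Extract (bias, linear, [quadratic]) for a decision type, validating kinds."""
    if model_kind == "monotonic":
        if not isinstance(params, MonotonicParams):
            raise TypeError("monotonic model requires MonotonicParams")
        if decision_type == "interrupt":
            return params.alpha, params.beta
        return params.gamma, params.delta
    if model_kind == "nonmonotonic":
        if not isinstance(params, NonMonotonicParams):
            raise TypeError("nonmonotonic model requires NonMonotonicParams")
        if decision_type == "interrupt":
            return params.alpha, params.tau, params.omega
        return params.gamma, params.kappa, params.lambda_
    raise ValueError(f"unknown model_kind {model_kind!r}")


def linear_predictor(event: DecisionEvent, params: Params, model_kind: str) -> float:
    """Log-odds of the recorded actor interrupting / accepting for one event.

    Because the event stores time pressures by role, both decision types share
    the same form: the interrupter-side pressure drives benefit and the
    interruptee-side pressure drives cost.
    """
    coefs = _params_for(params, model_kind, event.decision_type)
    d1 = event.tp_interrupter - event.tp_interruptee
    if model_kind == "monotonic":
        bias, sens = coefs
        return bias + sens * d1
    bias, lin, quad = coefs
    d2 = event.tp_interrupter**2 - event.tp_interruptee**2
    return bias + lin * d1 + quad * d2


def event_probability(event: DecisionEvent, params: Params, model_kind: str) -> float:
    """Probability that the recorded actor interrupts (or accepts)."""
    return float(expit(linear_predictor(event, params, model_kind)))


def bernoulli_loglik(eta, outcome):
    """log Bernoulli(outcome | logistic(eta)), numerically stable for any |eta|."""
    eta = np.asarray(eta, dtype=float)
    sign = 2.0 * np.asarray(outcome, dtype=float) - 1.0
    return -np.logaddexp(0.0, -sign * eta)


def pointwise_loglik(
    events: Sequence[DecisionEvent],
    subject_params: Mapping[str, Params],
    model_kind: str,
) -> np.ndarray:
    """Per-event log-likelihoods, in input order.

    Element ``n`` is ``log Bernoulli(outcome_n | p_n)`` with ``p_n`` from each
    subject's own parameters; the total log-likelihood is the sum.

    Raises
    ------
    KeyError
        If an event's subject has no entry in ``subject_params``.
    """
    out = np.empty(len(events))
    for n, ev in enumerate(events):
        if ev.subject_id not in subject_params:
            raise KeyError(f"no parameters for subject {ev.subject_id!r}")
        eta = linear_predictor(ev, subject_params[ev.subject_id], model_kind)
        out[n] = bernoulli_loglik(eta, ev.outcome)
    return out


# ---------------------------------------------------------------------------
# vectorized design-matrix view used by the fitting machinery
# ---------------------------------------------------------------------------

PARAM_NAMES: dict[tuple[str, str], tuple[str, ...]] = {
    ("monotonic", "interrupt"): ("alpha", "beta"),
    ("monotonic", "respond"): ("gamma", "delta"),
    ("nonmonotonic", "interrupt"): ("alpha", "tau", "omega"),
    ("nonmonotonic", "respond"): ("gamma", "kappa", "lambda"),
}


def design_matrix(events: pd.DataFrame, model_kind: str) -> np.ndarray:
    """Design matrix mapping subject parameters to log-odds.

    Columns: intercept (bias), tp difference (linear sensitivity) and, for the
    non-monotonic family, squared-tp difference (quadratic sensitivity). The
    role-based storage of the tp columns makes this valid for both decision
    types.
    """
    d1 = (events["tp_interrupter"] - events["tp_interruptee"]).to_numpy(float)
    cols = [np.ones_like(d1), d1]
    if model_kind == "nonmonotonic":
        d2 = (
            events["tp_interrupter"].to_numpy(float) ** 2
            - events["tp_interruptee"].to_numpy(float) ** 2
        )
        cols.append(d2)
    elif model_kind != "monotonic":
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return np.column_stack(cols)


def events_from_frame(df: pd.DataFrame) -> list[DecisionEvent]:
    """Materialize :class:`DecisionEvent` objects from a schema-conforming frame."""
    evs = []
    for row in df.itertuples(index=False):
        evs.append(
            DecisionEvent(
                subject_id=str(row.subject_id),
                block=int(row.block),
                decision_type=str(row.decision_type),
                tp_interrupter=float(row.tp_interrupter),
                tp_interruptee=float(row.tp_interruptee),
                outcome=int(row.outcome),
                time_available=float(row.time_available),
                deadline_condition=int(row.deadline_condition),
                error_impact_condition=int(row.error_impact_condition),
            )
        )
    return evs
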