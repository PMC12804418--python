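"""Agent-based simulation of the two-nurse ICU-discharge task paradigm.

Two nurses (the *participant*, driven by a configurable choice policy, and a
simulated *coworker*) each discharge two patients by completing three tasks per
patient — vitals (13 questions), medications (16) and documentation (24) — under
a shared deadline. At scheduled question indices an agent must decide whether
to interrupt the other nurse before progressing; the other nurse then decides
whether to accept. An accepted interruption pauses the interruptee for one
service time and raises their error risk for the next eight questions; a
rejected interruption forces the interrupter to change patients or retry every
11 s. Detected errors cost 3 or 6 s (the error-impact manipulation) and a
question is abandoned after three failed attempts.

Each agent keeps its own ``time_used`` clock (the experiment displayed both);
decisions are evaluated at the deciding agent's clock and the event log is
ordered by clock with a fixed participant-before-coworker tie-break. Decision
probabilities follow the package's choice models; the coworker's response
policy is the monotonic accept rule with bias 0 and sensitivity 1, exactly the
policy the human participants faced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import decision_models as dm

PARTICIPANT = "participant"
COWORKER = "coworker"


@dataclass(frozen=True)
class SimConfig:
    """Fixed design of one experimental block."""

    deadline_s: int = 1320
    error_impact_s: int = 3
    questions_per_task: tuple[int, int, int] = (13, 16, 24)
    patients_per_nurse: int = 2
    time_per_question_s: float = 11.0
    coworker_error_rate: float = 0.05
    post_interruption_window: int = 8
    post_interruption_error_multiplier: float = 2.0
    reinterrupt_interval_s: float = 11.0
    max_attempts: int = 3
    importance_level: int = 5
    prompts_per_task: int = 2
    #: explicit {task_index: [question indices]} overriding prompts_per_task
    prompt_schedule: Optional[dict[int, tuple[int, ...]]] = None
    hard_cap_s: float = 10000.0
    block: int = 1

    def __post_init__(self) -> None:
        if self.deadline_s <= 0 or self.time_per_question_s <= 0:
            raise ValueError("deadline and service time must be positive")
        if not 0 <= self.coworker_error_rate <= 1:
            raise ValueError("error rate must be in [0, 1]")
        if any(q < 0 for q in self.questions_per_task):
            raise ValueError("question counts must be non-negative")

    @property
    def total_questions(self) -> int:
        return self.patients_per_nurse * sum(self.questions_per_task)

    def schedule(self) -> dict[int, tuple[int, ...]]:
        """Prompt positions per task: evenly spaced question indices by default."""
        if self.prompt_schedule is not None:
            return {int(t): tuple(qs) for t, qs in self.prompt_schedule.items()}
        out = {}
        for t, nq in enumerate(self.questions_per_task):
            k = min(self.prompts_per_task, nq)
            out[t] = tuple(
                int(round((j + 1) * nq / (k + 1))) for j in range(k)
            ) if k else ()
        return out


@dataclass
class ParticipantPolicy:
    """Decision policy and task behavior of the synthetic participant.

    In the original experiment this role is a human; here the interrupt and
    respond probabilities come from one of the two model families with the
    given subject parameters. ``force_interrupt`` / ``force_accept`` override
    the stochastic policy for diagnostic runs.
    """

    model_kind: str = "monotonic"
    params: dm.Params = field(default_factory=lambda: dm.MonotonicParams(
        alpha=0.0, beta=1.0, gamma=0.0, delta=1.0))
    error_rate: float = 0.05
    service_time_s: Optional[float] = None  # default: config.time_per_question_s
    #: if set, per-question service times are lognormal with this sigma and the
    #: same mean as the constant dialect
    service_lognormal_sigma: Optional[float] = None
    force_interrupt: Optional[bool] = None
    force_accept: Optional[bool] = None


@dataclass
class CoworkerPolicy:
    """Simulated nurse's decision parameters.

    The response rule (bias 0, sensitivity 1) matches the experiment; the
    interrupt-side parameters are not reported there and default to the same
    neutral values. ``force_accept`` / ``force_interrupt`` support tests.
    """

    interrupt_bias: float = 0.0
    interrupt_sensitivity: float = 1.0
    respond_bias: float = 0.0
    respond_sensitivity: float = 1.0
    force_interrupt: Optional[bool] = None
    force_accept: Optional[bool] = None


@dataclass
class AgentState:
    """Evolving per-agent task state within a block."""

    agent_id: str
    n_patients: int
    tasks: tuple[int, ...]
    time_used: float = 0.0
    active_patient: int = 0
    attempts: int = 0
    elevated_error_remaining: int = 0
    done_counts: list[list[int]] = field(default_factory=list)
    prompts_resolved: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.done_counts:
            self.done_counts = [[0] * len(self.tasks) for _ in range(self.n_patients)]

    def questions_completed(self) -> int:
        return sum(sum(p) for p in self.done_counts)

    def tasks_remaining(self) -> int:
        return self.n_patients * sum(self.tasks) - self.questions_completed()

    def patient_done(self, p: int) -> bool:
        return all(self.done_counts[p][t] >= self.tasks[t] for t in range(len(self.tasks)))

    @property
    def done(self) -> bool:
        return all(self.patient_done(p) for p in range(self.n_patients))

    def position(self, p: int) -> Optional[tuple[int, int]]:
        """Next (task, question) for patient ``p``, or None if finished."""
        for t in range(len(self.tasks)):
            if self.done_counts[p][t] < self.tasks[t]:
                return t, self.done_counts[p][t]
        return None


@dataclass
class EventLog:
    """Ordered block record: one row per simulated event."""

    frame: pd.DataFrame
    truncated: bool
    config: SimConfig


def time_pressure_at(agent: AgentState, config: SimConfig) -> tuple[float, float]:
    """(time pressure, time_available) at the agent's current clock.

    Past the deadline time pressure is undefined; for policy evaluation it is
    computed with the time available clamped to one second (extreme pressure)
    and the true non-positive ``time_available`` is returned so downstream
    filtering can remove the decision, mirroring the exclusion applied to the
    behavioral data.
    """
    ta = config.deadline_s - agent.time_used
    eff = max(ta, 1.0)
    tp = dm.compute_time_pressure(dm.TimePressureContext(
        tasks_remaining=agent.tasks_remaining(),
        time_available=eff,
        time_per_task=config.time_per_question_s,
    ))
    return tp, ta


def coworker_respond(tp_coworker: float, tp_participant: float,
                     rng: np.random.Generator,
                     policy: CoworkerPolicy | None = None) -> bool:
    """Simulated nurse's accept/reject decision for a participant interruption.

    Accept probability is logistic(bias + sensitivity * (b - c)) with benefit b
    the participant's (interrupter's) time pressure and cost c the coworker's
    own; the experiment used bias 0 and sensitivity 1. Consumes exactly one
    uniform variate.
    """
    policy = policy or CoworkerPolicy()
    if policy.force_accept is not None:
        rng.random()  # keep the stream aligned with the stochastic path
        return policy.force_accept
    p = expit(policy.respond_bias
              + policy.respond_sensitivity * (tp_participant - tp_coworker))
    return bool(rng.random() < p)


def coworker_interrupt_decision(tp_coworker: float, tp_participant: float,
                                policy: CoworkerPolicy,
                                rng: np.random.Generator) -> bool:
    """Simulated nurse's decision to interrupt the participant at a prompt."""
    if policy.force_interrupt is not None:
        rng.random()
        return policy.force_interrupt
    p = expit(policy.interrupt_bias
              + policy.interrupt_sensitivity * (tp_coworker - tp_participant))
    return bool(rng.random() < p)


def apply_outcome(interrupter: AgentState, interruptee: AgentState,
                  interrupted: bool, accepted: bool, config: SimConfig,
                  prompt_key=None) -> None:
    """State transition after a resolved interrupt/response decision pair.

    Accept: the interruptee pauses for one service time and enters the
    elevated-error window while the interrupter's pending prompt is cleared so
    they can progress. Reject or no interruption: states are unchanged here
    (the interrupter's switch-or-retry handling happens in the block loop).
    """
    if interrupted and accepted:
        if prompt_key is not None:
            interrupter.prompts_resolved.add(prompt_key)
        interruptee.time_used += config.time_per_question_s
        interruptee.elevated_error_remaining = config.post_interruption_window


class _BlockRunner:
    def __init__(self, config: SimConfig, participant: ParticipantPolicy,
                 coworker: CoworkerPolicy, seed: int):
        self.config = config
        self.pp = participant
        self.cp = coworker
        self.rng = np.random.default_rng(int(seed) % (2**31))
        self.part = AgentState(PARTICIPANT, config.patients_per_nurse,
                               config.questions_per_task)
        self.cow = AgentState(COWORKER, config.patients_per_nurse,
                              config.questions_per_task)
        self.schedule = config.schedule()
        self.records: list[dict] = []
        self.truncated = False

    # -- logging ----------------------------------------------------------
    def log(self, kind: str, agent: AgentState, **payload) -> None:
        self.records.append({
            "seq": len(self.records),
            "clock": agent.time_used,
            "kind": kind,
            "agent": agent.agent_id,
            "participant_progress": self.part.questions_completed(),
            "coworker_progress": self.cow.questions_completed(),
            **payload,
        })

    def other(self, agent: AgentState) -> AgentState:
        return self.cow if agent is self.part else self.part

    # -- behaviour --------------------------------------------------------
    def interrupt_probability(self, agent: AgentState, tp_self, tp_other) -> float:
        if agent is self.part:
            ev_bias_lin = dm._params_for(self.pp.params, self.pp.model_kind, "interrupt")
            if self.pp.model_kind == "monotonic":
                bias, sens = ev_bias_lin
                return float(expit(bias + sens * (tp_self - tp_other)))
            bias, lin, quad = ev_bias_lin
            return float(expit(bias + lin * (tp_self - tp_other)
                               + quad * (tp_self**2 - tp_other**2)))
        return float(expit(self.cp.interrupt_bias
                           + self.cp.interrupt_sensitivity * (tp_self - tp_other)))

    def respond_probability(self, agent: AgentState, tp_interrupter, tp_self) -> float:
        if agent is self.part:
            coefs = dm._params_for(self.pp.params, self.pp.model_kind, "respond")
            if self.pp.model_kind == "monotonic":
                bias, sens = coefs
                return float(expit(bias + sens * (tp_interrupter - tp_self)))
            bias, lin, quad = coefs
            return float(expit(bias + lin * (tp_interrupter - tp_self)
                               + quad * (tp_interrupter**2 - tp_self**2)))
        return float(expit(self.cp.respond_bias
                           + self.cp.respond_sensitivity * (tp_interrupter - tp_self)))

    def _force_flag(self, agent: AgentState, which: str) -> Optional[bool]:
        pol = self.pp if agent is self.part else self.cp
        return getattr(pol, f"force_{which}")

    def working_patient(self, agent: AgentState) -> int:
        if agent.patient_done(agent.active_patient):
            agent.active_patient = next(
                p for p in range(agent.n_patients) if not agent.patient_done(p)
            )
        return agent.active_patient

    def patient_blocked(self, agent: AgentState, p: int) -> bool:
        """True if patient p's next question sits at an unresolved prompt."""
        pos = agent.position(p)
        if pos is None:
            return True
        t, q = pos
        return q in self.schedule.get(t, ()) and (p, t, q) not in agent.prompts_resolved

    def switch_or_wait(self, agent: AgentState) -> None:
        p = agent.active_patient
        alt = [o for o in range(agent.n_patients)
               if o != p and not agent.patient_done(o) and not self.patient_blocked(agent, o)]
        if alt:
            agent.active_patient = alt[0]
            self.log("patient_switch", agent, patient=alt[0])
        else:
            agent.time_used += self.config.reinterrupt_interval_s

    def make_interrupt_decision(self, agent: AgentState, key) -> None:
        other = self.other(agent)
        tp_self, ta_self = time_pressure_at(agent, self.config)
        tp_other, ta_other = time_pressure_at(other, self.config)

        forced = self._force_flag(agent, "interrupt")
        p_int = self.interrupt_probability(agent, tp_self, tp_other)
        u = self.rng.random()
        interrupt = forced if forced is not None else bool(u < p_int)
        self.log("interrupt_decision", agent, outcome=int(interrupt),
                 tp_interrupter=tp_self, tp_interruptee=tp_other,
                 time_available=ta_self)
        accepted = False
        if interrupt:
            forced_acc = self._force_flag(other, "accept")
            p_acc = self.respond_probability(other, tp_self, tp_other)
            u2 = self.rng.random()
            accepted = forced_acc if forced_acc is not None else bool(u2 < p_acc)
            self.log("response_decision", other, outcome=int(accepted),
                     tp_interrupter=tp_self, tp_interruptee=tp_other,
                     time_available=ta_other)
            apply_outcome(agent, other, True, accepted, self.config, key)
            self.log("interruption_accepted" if accepted else "interruption_rejected",
                     agent)
        if not (interrupt and accepted):
            self.switch_or_wait(agent)

    def answer_question(self, agent: AgentState) -> None:
        cfg = self.config
        p = agent.active_patient
        t, q = agent.position(p)
        if agent is self.part:
            service = self.pp.service_time_s or cfg.time_per_question_s
            if self.pp.service_lognormal_sigma:
                sig = self.pp.service_lognormal_sigma
                service *= float(np.exp(self.rng.normal(-0.5 * sig**2, sig)))
            base_rate = self.pp.error_rate
        else:
            service = cfg.time_per_question_s
            base_rate = cfg.coworker_error_rate
        rate = min(base_rate * (cfg.post_interruption_error_multiplier
                                if agent.elevated_error_remaining > 0 else 1.0), 1.0)
        err = bool(self.rng.random() < rate)
        if err:
            agent.attempts += 1
            agent.time_used += service + cfg.error_impact_s
            self.log("error", agent, patient=p, task=t, question=q)
            if agent.attempts < cfg.max_attempts:
                return  # retry same question
        else:
            agent.time_used += service
        # question consumed (answered, or abandoned after max_attempts failures)
        agent.attempts = 0
        agent.done_counts[p][t] += 1
        if agent.elevated_error_remaining > 0:
            agent.elevated_error_remaining -= 1
        self.log("question_answered", agent, patient=p, task=t, question=q,
                 outcome=int(not err))

    def step(self, agent: AgentState) -> None:
        p = self.working_patient(agent)
        t, q = agent.position(p)
        key = (p, t, q)
        if q in self.schedule.get(t, ()) and key not in agent.prompts_resolved:
            self.make_interrupt_decision(agent, key)
        else:
            self.answer_question(agent)

    def run(self) -> EventLog:
        order = {PARTICIPANT: 0, COWORKER: 1}
        while True:
            active = [a for a in (self.part, self.cow) if not a.done]
            if not active:
                break
            agent = min(active, key=lambda a: (a.time_used, order[a.agent_id]))
            if agent.time_used > self.config.hard_cap_s:
                self.truncated = True
                break
            self.step(agent)
        self.log("block_end", self.part, outcome=int(not self.truncated))
        frame = pd.DataFrame(self.records)
        frame = frame.sort_values(["clock", "seq"], kind="stable").reset_index(drop=True)
        return EventLog(frame=frame, truncated=self.truncated, config=self.config)


def run_block(config: SimConfig, participant: ParticipantPolicy,
              coworker_policy: CoworkerPolicy | None = None,
              seed: int = 0) -> EventLog:
    """Simulate one experimental block; deterministic given the seed.

    Runs until both nurses have completed all questions for both patients, or
    until an agent's clock passes ``config.hard_cap_s``, in which case the log
    is flagged as truncated.
    """
    runner = _BlockRunner(config, participant, coworker_policy or CoworkerPolicy(),
                          seed)
    return runner.run()


def extract_decision_events(log: EventLog, config: SimConfig | None = None,
                            subject_id: str = "P0") -> pd.DataFrame:
    """Participant decision events from a block log, in the fitting schema.

    One row per participant interrupt decision and per participant response
    decision, with both agents' time pressures at the decision clock and the
    progress/time-remaining covariates used by the descriptive regressions.
    Post-deadline decisions are emitted with their true ``time_available <= 0``
    so the preprocessing filter can remove them.
    """
    config = config or log.config
    if log.truncated:
        warnings.warn("truncated block: events after the cap are not present")
    f = log.frame
    rows = []
    for rec in f.itertuples(index=False):
        if rec.kind == "interrupt_decision" and rec.agent == PARTICIPANT:
            dt, tp_er, tp_ee = "interrupt", rec.tp_interrupter, rec.tp_interruptee
        elif rec.kind == "response_decision" and rec.agent == PARTICIPANT:
            # coworker interrupted: interrupter-side tp is the coworker's
            dt, tp_er, tp_ee = "respond", rec.tp_interrupter, rec.tp_interruptee
        else:
            continue
        rows.append({
            "subject_id": subject_id,
            "block": config.block,
            "decision_type": dt,
            "tp_interrupter": tp_er,
            "tp_interruptee": tp_ee,
            "outcome": int(rec.outcome),
            "time_available": rec.time_available,
            "deadline_condition": config.deadline_s,
            "error_impact_condition": config.error_impact_s,
            "participant_progress": rec.participant_progress,
            "coworker_progress": rec.coworker_progress,
            "time_remaining": rec.time_available,
        })
    cols = ["subject_id", "block", "decision_type", "tp_interrupter",
            "tp_interruptee", "outcome", "time_available", "deadline_condition",
            "error_impact_condition", "participant_progress",
            "coworker_progress", "time_remaining"]
    return pd.DataFrame(rows, columns=cols)
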