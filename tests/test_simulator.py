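"""Behavioral contracts of the two-nurse task simulator."""

import numpy as np
import pytest
from scipy.special import expit

from teaminterrupt import simulator as sim
from teaminterrupt.inference import preprocess


def forced_policy(interrupt=True, accept=True):
    return sim.ParticipantPolicy(error_rate=0.0, force_interrupt=interrupt,
                                 force_accept=accept)


class TestBlockDynamics:
    def test_question_conservation(self):
        cfg = sim.SimConfig()
        assert cfg.total_questions == 106
        log = sim.run_block(cfg, sim.ParticipantPolicy(), seed=3)
        qa = log.frame[log.frame.kind == "question_answered"]
        counts = qa.groupby("agent").size()
        assert counts["participant"] == 106
        assert counts["coworker"] == 106

    def test_clock_monotone_and_tiebreak(self):
        log = sim.run_block(sim.SimConfig(), sim.ParticipantPolicy(), seed=5)
        clocks = log.frame["clock"].to_numpy()
        assert (np.diff(clocks) >= 0).all()

    def test_determinism_byte_identical(self):
        cfg = sim.SimConfig(error_impact_s=6)
        a = sim.run_block(cfg, sim.ParticipantPolicy(), seed=11)
        b = sim.run_block(cfg, sim.ParticipantPolicy(), seed=11)
        assert a.frame.to_csv(index=False) == b.frame.to_csv(index=False)
        c = sim.run_block(cfg, sim.ParticipantPolicy(), seed=12)
        assert a.frame.to_csv(index=False) != c.frame.to_csv(index=False)

    def test_zero_questions_immediate_end(self):
        cfg = sim.SimConfig(questions_per_task=(0, 0, 0))
        log = sim.run_block(cfg, sim.ParticipantPolicy(), seed=1)
        assert not log.truncated
        assert set(log.frame.kind) == {"block_end"}
        assert sim.extract_decision_events(log).empty

    def test_forced_policies_counting_oracle(self):
        """Interrupt-always/accept-always: decisions = prompts + coworker interrupts."""
        cfg = sim.SimConfig()
        n_prompts = sum(len(v) for v in cfg.schedule().values()) * cfg.patients_per_nurse
        log = sim.run_block(cfg, forced_policy(),
                            sim.CoworkerPolicy(force_interrupt=True,
                                               force_accept=True), seed=7)
        ev = sim.extract_decision_events(log)
        assert (ev.decision_type == "interrupt").sum() == n_prompts
        # coworker has the same schedule and always interrupts once per prompt
        assert (ev.decision_type == "respond").sum() == n_prompts
        qa = log.frame[(log.frame.kind == "question_answered")
                       & (log.frame.agent == "coworker")]
        assert len(qa) == 106

    def test_completion_time_accounting_identity(self):
        """No errors: completion = 106 questions x 11 s + accepted-interruption pauses."""
        cfg = sim.SimConfig(deadline_s=100000, coworker_error_rate=0.0,
                            hard_cap_s=1e9)
        log = sim.run_block(cfg, forced_policy(),
                            sim.CoworkerPolicy(force_interrupt=True,
                                               force_accept=True), seed=2)
        assert not log.truncated
        n_prompts = sum(len(v) for v in cfg.schedule().values()) * cfg.patients_per_nurse
        f = log.frame
        for agent in ("participant", "coworker"):
            last = f[(f.agent == agent) & (f.kind == "question_answered")].clock.max()
            expected = 106 * 11.0 + n_prompts * 11.0  # own work + pauses
            assert last == pytest.approx(expected, abs=1e-9)

    def test_accept_never_blocks_interrupter_progress(self):
        """With an accept-never coworker, interrupting never advances the participant."""
        cfg = sim.SimConfig(hard_cap_s=3000.0)
        log = sim.run_block(cfg, forced_policy(accept=True),
                            sim.CoworkerPolicy(force_accept=False), seed=9)
        f = log.frame
        # participant progress can never exceed the questions before the first
        # prompt on each patient (task 0 prompt at index 4)
        first_prompt = cfg.schedule()[0][0]
        assert f.participant_progress.max() <= first_prompt * cfg.patients_per_nurse
        assert log.truncated

    def test_accept_always_interruption_precedes_progress(self):
        cfg = sim.SimConfig()
        log = sim.run_block(cfg, forced_policy(),
                            sim.CoworkerPolicy(force_accept=True), seed=4)
        f = log.frame.reset_index(drop=True)
        accepted = f[(f.kind == "interruption_accepted") & (f.agent == "participant")]
        for idx in accepted.index:
            before = f.loc[idx, "participant_progress"]
            after = f[(f.index > idx) & (f.agent == "participant")
                      & (f.kind == "question_answered")]
            assert len(after) > 0 and after.iloc[0].participant_progress >= before

    def test_reinterrupt_spacing_11s(self):
        """Blocked on both patients, rejected attempts retry exactly 11 s apart."""
        cfg = sim.SimConfig(hard_cap_s=2000.0)
        log = sim.run_block(cfg, forced_policy(),
                            sim.CoworkerPolicy(force_accept=False,
                                               force_interrupt=False), seed=13)
        f = log.frame
        dec = f[(f.kind == "interrupt_decision") & (f.agent == "participant")]
        # after the participant has switched once, both patients are blocked
        tail = dec.clock.to_numpy()[3:]
        gaps = np.diff(tail)
        assert np.allclose(gaps, cfg.reinterrupt_interval_s)


class TestQuestionAnswering:
    def test_three_attempt_rule_and_error_impact(self):
        """error_rate=1: each question consumed after exactly 3 failed attempts."""
        cfg = sim.SimConfig(questions_per_task=(2, 0, 0), patients_per_nurse=1,
                            error_impact_s=6, prompts_per_task=0,
                            coworker_error_rate=1.0, deadline_s=100000,
                            hard_cap_s=1e9)
        pol = sim.ParticipantPolicy(error_rate=1.0)
        log = sim.run_block(cfg, pol, seed=21)
        f = log.frame
        for agent in ("participant", "coworker"):
            errors = f[(f.agent == agent) & (f.kind == "error")]
            answered = f[(f.agent == agent) & (f.kind == "question_answered")]
            assert len(answered) == 2
            assert len(errors) == 2 * cfg.max_attempts
            assert (answered.outcome == 0).all()  # completed-with-failure
            # each attempt costs service + error impact
            assert answered.clock.max() == pytest.approx(
                2 * cfg.max_attempts * (11.0 + 6.0), abs=1e-9)

    def test_error_free_time_is_service_time(self):
        cfg = sim.SimConfig(questions_per_task=(5, 0, 0), patients_per_nurse=1,
                            prompts_per_task=0, coworker_error_rate=0.0,
                            deadline_s=100000)
        log = sim.run_block(cfg, sim.ParticipantPolicy(error_rate=0.0), seed=1)
        qa = log.frame[(log.frame.kind == "question_answered")
                       & (log.frame.agent == "participant")]
        assert qa.clock.max() == pytest.approx(5 * 11.0, abs=1e-9)

    def test_elevated_window_bookkeeping(self):
        """elevated_error_remaining starts at 8 after an accept and hits 0 after 8 questions."""
        cfg = sim.SimConfig(coworker_error_rate=0.0)
        runner = sim._BlockRunner(cfg, sim.ParticipantPolicy(error_rate=0.0),
                                  sim.CoworkerPolicy(), seed=0)
        sim.apply_outcome(runner.part, runner.cow, True, True, cfg,
                          prompt_key=(0, 0, 4))
        assert runner.cow.elevated_error_remaining == 8
        assert (0, 0, 4) in runner.part.prompts_resolved
        seen = []
        for _ in range(10):
            seen.append(runner.cow.elevated_error_remaining)
            runner.answer_question(runner.cow)
        assert seen == [8, 7, 6, 5, 4, 3, 2, 1, 0, 0]
        assert runner.cow.elevated_error_remaining == 0

    def test_reject_leaves_states_unchanged(self):
        cfg = sim.SimConfig()
        runner = sim._BlockRunner(cfg, sim.ParticipantPolicy(),
                                  sim.CoworkerPolicy(), seed=0)
        before = (runner.part.questions_completed(), runner.cow.time_used)
        sim.apply_outcome(runner.part, runner.cow, True, False, cfg)
        assert (runner.part.questions_completed(), runner.cow.time_used) == before


class TestCoworkerPolicy:
    def test_accept_rate_at_equal_pressure(self, rng):
        draws = [sim.coworker_respond(1.0, 1.0, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("gap,expected", [(5.0, expit(5.0)), (-5.0, expit(-5.0))])
    def test_accept_rate_large_gaps(self, rng, gap, expected):
        draws = [sim.coworker_respond(1.0, 1.0 + gap, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(expected, abs=0.01)

    def test_interrupt_decision_uses_own_minus_other(self, rng):
        draws = [sim.coworker_interrupt_decision(6.0, 1.0, sim.CoworkerPolicy(), rng)
                 for _ in range(5000)]
        assert np.mean(draws) == pytest.approx(expit(5.0), abs=0.01)


class TestExtraction:
    def test_counts_match_bruteforce_log_scan(self):
        log = sim.run_block(sim.SimConfig(), sim.ParticipantPolicy(), seed=17)
        ev = sim.extract_decision_events(log)
        f = log.frame
        n_int = ((f.kind == "interrupt_decision") & (f.agent == "participant")).sum()
        n_resp = ((f.kind == "response_decision") & (f.agent == "participant")).sum()
        assert (ev.decision_type == "interrupt").sum() == n_int
        assert (ev.decision_type == "respond").sum() == n_resp

    def test_post_deadline_events_flagged_for_filtering(self):
        cfg = sim.SimConfig(deadline_s=960)  # short deadline forces overruns
        log = sim.run_block(cfg, sim.ParticipantPolicy(), seed=23)
        ev = sim.extract_decision_events(log)
        late = ev[ev.time_available <= 0]
        assert len(late) > 0
        kept, report = preprocess(ev)
        assert (kept.time_available > 0).all()
        assert report["n_removed"] == len(late)

    def test_truncated_log_warns(self):
        cfg = sim.SimConfig(hard_cap_s=500.0)
        log = sim.run_block(cfg, forced_policy(),
                            sim.CoworkerPolicy(force_accept=False), seed=3)
        assert log.truncated
        with pytest.warns(UserWarning, match="truncated"):
            sim.extract_decision_events(log)
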