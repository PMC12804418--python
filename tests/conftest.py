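import numpy as np
import pytest

from teaminterrupt import decision_models as dm


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_event(decision_type="interrupt", tp_er=1.0, tp_ee=0.5, outcome=1,
               subject="S0", time_available=500.0):
    return dm.DecisionEvent(
        subject_id=subject, block=1, decision_type=decision_type,
        tp_interrupter=tp_er, tp_interruptee=tp_ee, outcome=outcome,
        time_available=time_available, deadline_condition=1320,
        error_impact_condition=3,
    )


@pytest.fixture
def event_factory():
    return make_event


@pytest.fixture
def random_events(rng):
    """A mixed batch of decision events across subjects and decision types."""
    def build(n=10, n_subjects=3):
        events = []
        for i in range(n):
            events.append(make_event(
                decision_type="interrupt" if i % 2 == 0 else "respond",
                tp_er=float(rng.uniform(0.2, 2.0)),
                tp_ee=float(rng.uniform(0.2, 2.0)),
                outcome=int(rng.integers(2)),
                subject=f"S{i % n_subjects}",
            ))
        return events
    return build
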