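import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(catch_correct, test_correct=(), cop_mads=None, start_index=1):
    """Build a small SessionRecord: catch trials first, then test trials."""
    from lapsewatch.session import SessionRecord, TrialRecord

    trials = []
    i = start_index
    for ok in catch_correct:
        trials.append(
            TrialRecord(index=i, kind="catch", stimulus_magnitude=30.0,
                        response_correct=bool(ok))
        )
        i += 1
    for ok in test_correct:
        trials.append(
            TrialRecord(index=i, kind="test", stimulus_magnitude=5.0,
                        response_correct=bool(ok))
        )
        i += 1
    if cop_mads is not None:
        for t, v in zip(trials, cop_mads):
            t.cop_mad = v
    return SessionRecord(trials=trials)


@pytest.fixture
def session_factory():
    return make_session
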