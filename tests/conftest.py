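import numpy as np
import pytest

from ratplay.events import AttackEvent, CountMatrix, build_count_matrix

LABELS = tuple("ABCDEF")


def make_event(initiator="A", recipient="B", group_id=1, day=1, time_s=10.0,
               response="pin", role_reversal=False, n_partners_available=5,
               **kw) -> AttackEvent:
    return AttackEvent(group_id=group_id, day=day, time_s=time_s,
                       initiator=initiator, recipient=recipient,
                       response=response, role_reversal=role_reversal,
                       n_partners_available=n_partners_available,
                       **kw).validated()


def random_count_matrix(rng: np.random.Generator, k: int = 6,
                        max_count: int = 30, group_id: int = 1,
                        day: int = 1) -> CountMatrix:
    counts = rng.integers(0, max_count, size=(k, k))
    np.fill_diagonal(counts, 0)
    return CountMatrix(group_id, day, LABELS[:k], counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_events():
    return [
        make_event("A", "B", time_s=5.0, response="pin"),
        make_event("A", "B", time_s=15.0, response="evasion",
                   role_reversal=True),
        make_event("B", "A", time_s=30.0, response="no_response",
                   n_partners_available=3),
    ]


@pytest.fixture
def small_counts(small_events):
    return build_count_matrix(small_events, 1, 1, LABELS)
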