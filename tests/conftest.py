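import pytest

from gusome.simulate import generate_cohort, make_representatives

CORE_LENGTH = 240
FMN_TAIL = 120


@pytest.fixture(scope="session")
def reps():
    """Compact synthetic representative set (fast alignments)."""
    return make_representatives(core_length=CORE_LENGTH, fmn_tail=FMN_TAIL)


@pytest.fixture(scope="session")
def cohort(reps):
    """One fully generated labeled cohort shared across tests."""
    return generate_cohort(seed=11, representatives=reps)
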