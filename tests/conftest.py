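import pytest

from accrualpred import AccrualObservation, StudyDesign


@pytest.fixture
def planning_design() -> StudyDesign:
    """A 158-subject, 24-month trial planned with strong prior confidence."""
    return StudyDesign(n=158, T=24, P=0.5)


@pytest.fixture
def no_data() -> AccrualObservation:
    return AccrualObservation.empty()
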