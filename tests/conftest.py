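import pytest

from flextrial import pilot_fixture, reference_design


@pytest.fixture(scope="session")
def design():
    return reference_design()


@pytest.fixture(scope="session")
def pilot(design):
    """The reconstructed 77-participant pilot cohort and its flow summary."""
    return pilot_fixture(design, seed=1)


@pytest.fixture(scope="session")
def pilot_participants(pilot):
    return pilot[0]
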