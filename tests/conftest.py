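import pytest

from segconcord import load_fixture_cohort
from segconcord.karyo import ClassificationThresholds


@pytest.fixture(scope="session")
def cohort():
    """The packaged 36-embryo segmental-aneuploidy TE/ICM cohort."""
    result = load_fixture_cohort()
    assert not result.errors
    return result.records


@pytest.fixture(scope="session")
def thresholds():
    return ClassificationThresholds()
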