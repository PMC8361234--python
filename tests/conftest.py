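import pytest

from echonom.consensus import NomenclatureConfig
from echonom.fixtures import CohortSpec, generate_cohort


@pytest.fixture
def config():
    return NomenclatureConfig()


@pytest.fixture(scope="session")
def cohort():
    """A small two-species cohort exercising every naming branch."""
    return generate_cohort(11, CohortSpec(second_species="spub"))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, cohort):
    d = tmp_path_factory.mktemp("cohort")
    cohort.write(d)
    return d
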