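import pytest

from picoscreen.criteria_prompt import default_criteria
from picoscreen.llm_backend import BackendParams, MockBackend
from picoscreen.screening import default_task_suite


@pytest.fixture(scope="session")
def rsv():
    """(criteria, taxonomy) for the bundled default scenario."""
    return default_criteria()


@pytest.fixture(scope="session")
def criteria(rsv):
    return rsv[0]


@pytest.fixture(scope="session")
def taxonomy(rsv):
    return rsv[1]


@pytest.fixture(scope="session")
def ta_tasks(criteria, taxonomy):
    return default_task_suite(criteria, taxonomy, "title_abstract")


@pytest.fixture(scope="session")
def ft_tasks(criteria, taxonomy):
    return default_task_suite(criteria, taxonomy, "full_text")


@pytest.fixture
def mock_backend():
    return MockBackend()


@pytest.fixture
def params():
    return BackendParams()
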