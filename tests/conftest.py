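import pytest

from admetriage import RunConfig, load_table1_fixture, run_workflow


@pytest.fixture(scope="session")
def fixture_set():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_report(fixture_set):
    """Default-config triage of the packaged case study."""
    return run_workflow(fixture_set.all_records, RunConfig())
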