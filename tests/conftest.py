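import pytest

from tdmcost import default_schedule, load_fixture, load_reference_results


@pytest.fixture(scope="session")
def base_configs():
    return {a: load_fixture(a) for a in (1, 2, 3)}


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def reference():
    return load_reference_results()
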