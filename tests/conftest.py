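import pytest

from audit_savings import default_parameters, load_default_study_table


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def study_series():
    return load_default_study_table()
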