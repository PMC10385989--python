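import pytest

from pampa_lfer import load_reference_dprime, load_reference_systems


@pytest.fixture(scope="session")
def reference_systems():
    return load_reference_systems()


@pytest.fixture(scope="session")
def systems_by_id(reference_systems):
    return {s.system_id: s for s in reference_systems}


@pytest.fixture(scope="session")
def pampa_systems(reference_systems):
    return [s for s in reference_systems if s.category == "pampa"]


@pytest.fixture(scope="session")
def biological_systems(reference_systems):
    return [s for s in reference_systems if s.category == "biological"]


@pytest.fixture(scope="session")
def dprime_reference():
    return load_reference_dprime()
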