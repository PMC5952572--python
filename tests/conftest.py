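import pytest
from hypothesis import settings

from srnaclean import ReferenceConfig, load_assays, make_references

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SMALL_REF_CONFIG = ReferenceConfig(
    host_length=20_000, n_host_srnas=20, nonhost_genome_length=4_000
)


@pytest.fixture(scope="session")
def refs():
    """Small synthetic reference universe shared across tests."""
    return make_references(SMALL_REF_CONFIG, seed=7)


@pytest.fixture(scope="session")
def assays():
    return load_assays()
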