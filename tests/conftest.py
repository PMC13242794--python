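import pytest
from hypothesis import HealthCheck, settings

from readtrim.simdata import SimConfig, write_adapter_fasta

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def adapter_fasta(tmp_path_factory) -> str:
    """Palindrome pair + simple 3'-adapter records matching the generator."""
    path = tmp_path_factory.mktemp("adapters") / "pe_adapters.fa"
    return write_adapter_fasta(str(path))


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    """The shared short-insert read-through scenario."""
    return SimConfig(n_pairs=500, seed=42)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """Error-free variant, for exact-construction assertions."""
    return SimConfig(n_pairs=200, seed=43, error_rate=0.0)
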