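import numpy as np
import pytest

from onfhost.sequence_io import SequenceRecord
from onfhost.synthetic_data import SimulationConfig, simulate_benchmark


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_record(rng, length, record_id="rec", with_n=False, n_contigs=1):
    alphabet = list("ACGTN" if with_n else "ACGT")
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    contigs = [
        "".join(rng.choice(alphabet, size=length, p=probs))
        for _ in range(n_contigs)
    ]
    return SequenceRecord(id=record_id, contigs=contigs)


@pytest.fixture(scope="session")
def small_benchmark():
    """12 hosts / 12 viruses, 3-level-deep balanced taxonomy, strong signal."""
    config = SimulationConfig(
        n_hosts=12,
        hosts_per_genus=2,
        genera_per_family=2,
        host_length=30_000,
        virus_length=10_000,
        markov_order=4,
        alpha=1.0,
        seed=101,
    )
    return config, simulate_benchmark(config)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_benchmark):
    from onfhost.synthetic_data import build_benchmark

    config, _ = small_benchmark
    out = tmp_path_factory.mktemp("fixture")
    paths = build_benchmark(config, out)
    return paths
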