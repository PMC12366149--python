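import pytest

from svmeta.sim import (
    SimulationConfig,
    simulate_caller_outputs,
    simulate_truth_set,
    write_simulation,
)
from svmeta.types import SequencingStats, SVType


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded simulation shared by read-only tests: 300 truth SVs
    per type on two 5 Mb contigs, seven caller profiles."""
    config = SimulationConfig(
        seed=7,
        n_truth={SVType.DEL: 300, SVType.INS: 300},
        contigs=(("1", 5_000_000), ("2", 5_000_000)),
        stats=SequencingStats(mean_coverage=35.0, read_length=250.0),
    )
    truth = simulate_truth_set(config)
    ledger, calls = simulate_caller_outputs(truth, config)
    return config, truth, ledger, calls


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    """The same simulation written to VCF files."""
    config, truth, ledger, _ = small_sim
    out = tmp_path_factory.mktemp("sim")
    paths = write_simulation(ledger, config, out)
    return config, ledger, paths


def make_call(**kwargs):
    """SVCall factory with sensible defaults for fixture construction."""
    from svmeta.types import SVCall, SVType

    defaults = dict(
        id="c1",
        caller="manta",
        chrom="1",
        pos=1000,
        end=1999,
        svtype=SVType.DEL,
        svlen=1000,
    )
    defaults.update(kwargs)
    return SVCall(**defaults)
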