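import numpy as np
import pytest

from coiphylo.io import Alignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


def aln_from_strings(seqs, ids=None, metadata=None):
    """Build an Alignment from raw sequence strings (terminal N/- → missing)."""
    from coiphylo.io import encode_sequence

    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    rows = [encode_sequence(s, record_id=i) for s, i in zip(seqs, ids)]
    return Alignment(ids, np.vstack(rows), metadata)


@pytest.fixture
def make_alignment():
    return aln_from_strings


@pytest.fixture(scope="session")
def small_two_clade():
    """A 50-sequence two-clade simulated dataset shared across tests."""
    from coiphylo.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        seed=11,
        sample_sizes={"NEA": 15, "MED": 10, "AFR": 10, "SA": 5, "AUS": 5, "ASI": 5},
    )
    return simulate_dataset(cfg)
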