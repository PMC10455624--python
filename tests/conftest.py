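import numpy as np
import pytest

from barcodegap.alignment_io import AlignedSequenceSet, SpeciesPartition
from barcodegap.simulate import SimulationConfig, simulate_dataset

ALPHABET = "ACGT-N"


@pytest.fixture
def tiny_alignment() -> AlignedSequenceSet:
    """Four sequences, two clear species, 20 columns."""
    return AlignedSequenceSet.from_records(
        [
            ("s1_a", "ACGTACGTACGTACGTACGT"),
            ("s1_b", "ACGTACGTACGTACGTACGA"),
            ("s2_a", "TGCATGCATGCAACGTACGT"),
            ("s2_b", "TGCATGCATGCAACGTACGA"),
        ],
        dataset_name="tiny",
    )


@pytest.fixture
def tiny_partition() -> SpeciesPartition:
    return SpeciesPartition(
        "default",
        {"s1_a": "sp1", "s1_b": "sp1", "s2_a": "sp2", "s2_b": "sp2"},
    )


def random_alignment(rng: np.random.Generator, n_seqs=None, n_cols=None,
                     gap_prob=0.1) -> AlignedSequenceSet:
    """A random aligned matrix over {A,C,G,T,-,N} for oracle comparisons."""
    n_seqs = n_seqs or int(rng.integers(2, 11))
    n_cols = n_cols or int(rng.integers(5, 61))
    probs = np.array([1, 1, 1, 1, gap_prob * 2, gap_prob * 2])
    probs = probs / probs.sum()
    chars = rng.choice(list(ALPHABET), size=(n_seqs, n_cols), p=probs)
    return AlignedSequenceSet.from_records(
        [(f"t{i}", "".join(row)) for i, row in enumerate(chars)],
        dataset_name="random",
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at generator defaults, shared across tests."""
    return simulate_dataset(SimulationConfig(seed=2023))
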