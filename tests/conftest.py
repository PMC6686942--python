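import numpy as np
import pytest

from karyoscope import (
    default_fusion_map,
    default_scaffold_specs,
    simulate_genome,
    simulate_reads,
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@pytest.fixture(scope="session")
def toy_specs():
    return default_scaffold_specs()


@pytest.fixture(scope="session")
def toy_fusion(toy_specs):
    return default_fusion_map(toy_specs)


@pytest.fixture(scope="session")
def toy_genome(toy_specs):
    """Default five-scaffold genome with planted X, arms and tandem clusters."""
    return simulate_genome(toy_specs, seed=101)


@pytest.fixture(scope="session")
def toy_reads(toy_genome):
    """Female (XX) and male (XO) read sets at 20x on the toy genome."""
    female = simulate_reads(toy_genome, "female", mean_depth=20, read_length=100, seed=7)
    male = simulate_reads(toy_genome, "male", mean_depth=20, read_length=100, seed=8)
    return female, male
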