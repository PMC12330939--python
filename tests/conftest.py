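import numpy as np
import pytest

from circrbp.io import CircRecord, GenomeStore
from circrbp.synthetic import SynthParams


@pytest.fixture
def toy_genome() -> GenomeStore:
    """Deterministic 12 kb single-chromosome genome for coordinate tests."""
    rng = np.random.default_rng(12345)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytes(lut[rng.integers(0, 4, 12_000)]).decode()
    return GenomeStore({"chr1": seq})


@pytest.fixture
def plus_circ() -> CircRecord:
    return CircRecord("circP", "chr1", 5000, 6000, "+")


@pytest.fixture
def minus_circ() -> CircRecord:
    return CircRecord("circM", "chr1", 5000, 6000, "-")


@pytest.fixture
def small_params() -> SynthParams:
    """Desk-scale generator parameters for fast recovery tests."""
    return SynthParams(
        chrom_len=600_000,
        n_circ=100,
        circ_len_min=200,
        circ_len_max=1000,
        n_samples=10,
        n_rbp=30,
        n_driver_rbps=8,
        seed=7,
    )
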