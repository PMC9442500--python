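import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from kmercomp import DNA, PROTEIN, KmerSpec, SequenceRecord


@pytest.fixture
def dna_spec_k2():
    return KmerSpec(alphabet=DNA, k=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length, with_n=0.0):
    symbols = np.array(list("ACGTN"))
    probs = np.array([0.25, 0.25, 0.25, 0.25, 0.0])
    if with_n > 0:
        probs = np.array([(1 - with_n) / 4] * 4 + [with_n])
    return "".join(rng.choice(symbols, size=length, p=probs))


def dna_record(rng, length, name="s", with_n=0.0):
    return SequenceRecord(id=name, residues=random_dna(rng, length, with_n), alphabet=DNA)


def random_protein(rng, length, name="p"):
    return SequenceRecord(
        id=name, residues="".join(rng.choice(list(PROTEIN.symbols), size=length)),
        alphabet=PROTEIN,
    )
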