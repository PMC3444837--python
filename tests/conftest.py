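import numpy as np
import pytest

from lwords.io import SequenceRecord, SequenceSet


def make_set(*residues: str, ids=None) -> SequenceSet:
    """Build a SequenceSet from bare residue strings with auto ids a, b, c..."""
    if ids is None:
        ids = [chr(ord("a") + i) for i in range(len(residues))]
    return SequenceSet(
        tuple(SequenceRecord(id=i, description="", residues=r)
              for i, r in zip(ids, residues))
    )


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
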