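import numpy as np
import pytest

from spidrokit.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20170314)


@pytest.fixture
def protein():
    def make(seq, id="p"):
        return SequenceRecord(id=id, alphabet="protein", residues=seq)

    return make


@pytest.fixture
def nucleotide():
    def make(seq, id="n"):
        return SequenceRecord(id=id, alphabet="nucleotide", residues=seq)

    return make
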