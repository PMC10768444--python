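import numpy as np
import pytest

from tcrdiv import clonocall, simkit


@pytest.fixture(scope="session")
def trb_segments():
    return simkit.make_germline_reference(8, 2, 4, "TRB", seed=7)


@pytest.fixture(scope="session")
def trg_segments():
    return simkit.make_germline_reference(4, 0, 3, "TRG", seed=11)


@pytest.fixture(scope="session")
def trb_tags(trb_segments):
    return clonocall.build_tag_library(trb_segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_simple_pair(seq1, seq2, qual=40, read_id="r1"):
    """Read pair with constant quality, for unit tests."""
    return clonocall.ReadPair(read_id=read_id, seq1=seq1,
                              qual1=[qual] * len(seq1), seq2=seq2,
                              qual2=[qual] * len(seq2))
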