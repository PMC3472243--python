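import logging

import numpy as np
import pytest

from venomxtend import NucleotideRead

# replicate-reduction and duplicate-seed warnings are routine in simulations
logging.getLogger("venomxtend").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def perfect_pair(fragment: str, read_length: int = 100, adaptor: str = "") -> tuple:
    """Error-free mate pair from a fragment (adaptor fills short fragments)."""
    from venomxtend import reverse_complement

    r1_seq = (fragment + adaptor)[:read_length]
    r2_seq = (reverse_complement(fragment) + adaptor)[:read_length]
    r1 = NucleotideRead("p/1", r1_seq, [40] * len(r1_seq))
    r2 = NucleotideRead("p/2", r2_seq, [40] * len(r2_seq))
    return r1, r2
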