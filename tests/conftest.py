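import numpy as np
import pytest

from idrkit.datasets import musashi1_idr
from idrkit.records import CANONICAL, ProteinRecord


@pytest.fixture(scope="session")
def musashi():
    """The packaged Musashi-1 IDR construct (residues 194-362)."""
    return musashi1_idr()


@pytest.fixture()
def random_records():
    """Factory: n seeded random canonical sequences as ProteinRecords."""

    def make(n, length=300, seed=0, offset=1):
        rng = np.random.default_rng(seed)
        letters = np.array(list(CANONICAL))
        return [
            ProteinRecord(f"R{i}", "".join(rng.choice(letters, size=length)),
                          numbering_offset=offset)
            for i in range(n)
        ]

    return make
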