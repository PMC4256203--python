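import numpy as np
import pytest

from sialoseq.io_formats import CdsRecord, ReadRecord
from sialoseq.synthetic_data import SENSE_CODONS, STOP_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cds(rng, n_codons: int, cds_id: str = "cds1") -> CdsRecord:
    """A valid ORF: ATG + random sense codons + one stop."""
    body = "".join(
        SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 2)
    )
    return CdsRecord(
        id=cds_id, sequence="ATG" + body + STOP_CODONS[int(rng.integers(3))]
    )


def make_read(seq: str, q: int = 40, read_id: str = "r1") -> ReadRecord:
    return ReadRecord(id=read_id, sequence=seq, qualities=np.full(len(seq), q))


@pytest.fixture
def small_cds_set(rng):
    return {
        f"cds{i}": random_cds(rng, n_codons=40, cds_id=f"cds{i}") for i in range(1, 6)
    }
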