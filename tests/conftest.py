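import numpy as np
import pytest

from hysemafi.io_formats import Role, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_read(rid: str, seq: str) -> SequenceRecord:
    return SequenceRecord(id=rid, seq=seq, role=Role.LONG_READ)


def make_contig(cid: str, seq: str) -> SequenceRecord:
    return SequenceRecord(id=cid, seq=seq, role=Role.CONTIG)


@pytest.fixture(scope="session")
def small_genes():
    """Five small genes shared by several module tests."""
    from hysemafi import simulate

    return simulate.make_genes(
        5, exon_count_range=(4, 5), exon_len_range=(60, 140), seed=3,
        isoform_counts=[1, 2, 2, 1, 3],
    )
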