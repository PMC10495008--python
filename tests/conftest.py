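import numpy as np
import pytest

from pirnakit.io import SmallRNARecord
from pirnakit.te import TECopy, TEFamily


_SEQ_RNG = np.random.default_rng(0)


def make_record(
    pos,
    strand="+",
    contig="c",
    length=26,
    first="T",
    tenth="A",
    n_hits=1,
    read_id=None,
    sequence=None,
):
    if sequence is None:
        # distinct middle per record so reads are not one dominant sequence
        middle = "".join(_SEQ_RNG.choice(list("ACGT"), length - 10))
        sequence = first + middle[:8] + tenth + middle[8:]
    return SmallRNARecord(
        read_id=read_id or f"r{pos}_{strand}_{np.random.default_rng().integers(1e9)}",
        length=length,
        contig=contig,
        five_prime_pos=pos,
        strand=strand,
        first_nt=first,
        tenth_nt=tenth,
        n_hits=n_hits,
        sequence=sequence,
    )


def make_copy(family, strand="+", start=0, end=None, category="full_length",
              contig="c", completeness=1.0, divergence=5.0):
    return TECopy(
        family=family,
        contig=contig,
        start=start,
        end=end if end is not None else start + 100,
        strand=strand,
        fragments=[],
        cons_intervals=[],
        completeness=completeness,
        category=category,
        mean_divergence_pct=divergence,
    )


@pytest.fixture(scope="session")
def small_library():
    return [
        TEFamily("GYP1", "LTR", 5000, ltr_len=400),
        TEFamily("GYP2", "LTR", 4000, ltr_len=300),
        TEFamily("LIN1", "LINE", 5429),
        TEFamily("DNA1", "DNA", 3000),
    ]
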