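import numpy as np
import pytest

from ratecmp.alignio import CodonAlignment


def make_aln(seqs: dict[str, str], locus_id: str = "locus") -> CodonAlignment:
    """Build an alignment from {record_id: sequence}; species = id prefix
    before '.' (so 'At.1', 'At.2' are paralogs of species 'At')."""
    records = [(rid, rid.split(".")[0], seq) for rid, seq in seqs.items()]
    return CodonAlignment(locus_id, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20101109)


@pytest.fixture
def triple_aln():
    # 5 codons, A and B differ at one synonymous third position, O further
    return make_aln(
        {
            "A": "TTTGGAACCAAAGTT",
            "B": "TTCGGAACCAAAGTT",
            "O": "TTCGGGACCAAGGTA",
        }
    )
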