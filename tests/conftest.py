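import numpy as np
import pytest

from afpcompare.seqio import ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20130)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(content: str, name: str = "seqs.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write


@pytest.fixture
def hplc6_like():
    """A canonical short circulating-isoform-like 37-mer: Asp/Thr start,
    Thr at positions 2, 13, 24, 35 (11-aa repeat), Ala-dominated."""
    seq = list("A" * 37)
    seq[0] = "D"
    for pos in (2, 13, 24, 35):
        seq[pos] = "T"
    return ProteinRecord(id="hplc6_like", seq="".join(seq), provenance="direct")


def random_dna(rng, length: int, p=None) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
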