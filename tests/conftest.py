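import pytest

from dehydrin.motif_scan import default_motifs
from dehydrin.seqio import SequenceRecord


@pytest.fixture
def motifs():
    return default_motifs()


@pytest.fixture
def protein():
    def _make(residues: str, id: str = "p1") -> SequenceRecord:
        return SequenceRecord(id=id, residues=residues, moltype="protein")

    return _make
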