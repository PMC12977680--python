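import pytest

from codonbias import CodingSequence, TranscriptCatalog


def make_catalog(records):
    """Build a catalog from (transcript_id, gene_id, seq) triples."""
    return TranscriptCatalog(tuple(CodingSequence(t, g, s) for t, g, s in records))


@pytest.fixture
def toy_catalog():
    """Three genes, clean CDS, heterogeneous lengths and codon content."""
    return make_catalog(
        [
            ("tr1", "g1", "ATG" + "ACT" * 4 + "TAA"),
            ("tr2", "g2", "ATG" + "GGT" * 2 + "ACC" * 2 + "TAA"),
            ("tr3", "g3", "ATG" + "GAA" * 10 + "TGA"),
        ]
    )
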