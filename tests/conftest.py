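import numpy as np
import pytest

from cubkit.composition import CodonCountTable
from cubkit.sequence_io import CdsSet, CodingSequence
from cubkit.synthetic import regime_battery


def make_counts(scope="gene", **codons) -> CodonCountTable:
    return CodonCountTable(
        counts=dict(codons), total_codons=sum(codons.values()), scope=scope
    )


def make_gene(seq, gene_id="g1", species="toy") -> CodingSequence:
    return CodingSequence(id=gene_id, species=species, seq=seq)


@pytest.fixture(scope="session")
def battery():
    """The fixed-seed scenario grid shared by the slower end-to-end tests."""
    return regime_battery(seed=0)


@pytest.fixture
def toy_set():
    genes = [
        make_gene("ATG" + "AAA" * 99 + "TAA", "ga"),
        make_gene("ATG" + "GCG" * 99 + "TGA", "gb"),
        make_gene("ATG" + "AAATTTGGG" * 33 + "TAG", "gc"),
    ]
    return CdsSet(species="toy", members=genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
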