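import numpy as np
import pytest

from breakscan.models import CensusGene, GeneModel, ProbeTrack


@pytest.fixture
def plus_gene():
    """5 exons of 100 nt on the plus strand, CDS inset 30 nt on both ends."""
    exons = tuple((1000 + 200 * k, 1100 + 200 * k) for k in range(5))
    cds = ((1030, 1100),) + exons[1:4] + ((1800, 1870),)
    return GeneModel(gene_id="GP", chrom="chr1", strand="+", exons=exons, cds=cds)


@pytest.fixture
def minus_gene():
    """4 exons on the minus strand; transcript order is descending genomic."""
    exons = tuple((5000 - 200 * k, 5100 - 200 * k) for k in range(4))
    return GeneModel(gene_id="GM", chrom="chr1", strand="-", exons=exons)


@pytest.fixture
def census():
    return [
        CensusGene("ABL1", "three_prime"),
        CensusGene("BCR", "five_prime"),
        CensusGene("EWSR1", "either"),
    ]


def make_track(ratios, sample="S00", chrom="chr1", spacing=1000):
    ratios = np.asarray(ratios, dtype=float)
    return ProbeTrack(
        sample_id=sample,
        chrom=chrom,
        positions=spacing * (1 + np.arange(ratios.size, dtype=np.int64)),
        ratios=ratios,
    )
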