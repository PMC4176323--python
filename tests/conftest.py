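import numpy as np
import pytest

from endmate.io_models import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240918)


def random_gene(rng, gene_id="G", chrom="chr1", strand=None, offset=0,
                n_exons=None, mrna_len=None):
    """A random but valid multi-exon gene model."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = n_exons or int(rng.integers(1, 6))
    mrna_len = mrna_len or int(rng.integers(300, 3000))
    min_ex = 50
    n_exons = max(1, min(n_exons, mrna_len // min_ex))
    extra = rng.multinomial(mrna_len - min_ex * n_exons, [1 / n_exons] * n_exons)
    pos = offset + int(rng.integers(0, 1000))
    exons = []
    for i, el in enumerate(min_ex + extra):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(rng.integers(100, 1500))
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tx_start=exons[0][0], tx_end=exons[-1][1], exons=tuple(exons),
    )


@pytest.fixture
def gene_plus():
    """Fixed 3-exon '+' gene: exons [1000,1200) [2000,2300) [5000,5500)."""
    return GeneModel(
        gene_id="NM_plus", chrom="chr1", strand="+", tx_start=1000, tx_end=5500,
        exons=((1000, 1200), (2000, 2300), (5000, 5500)),
    )


@pytest.fixture
def gene_minus():
    """Fixed 3-exon '-' gene: exons [10000,10400) [12000,12250) [13000,13350)."""
    return GeneModel(
        gene_id="NM_minus", chrom="chr1", strand="-", tx_start=10000, tx_end=13350,
        exons=((10000, 10400), (12000, 12250), (13000, 13350)),
    )
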