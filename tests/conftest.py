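import numpy as np
import pytest

from drecistrome.dre_scanner import EXAMPLE_TRAINING_SEQS, build_pwm
from drecistrome.genome_model import GeneAnnotation, GeneRegion


@pytest.fixture(scope="session")
def example_pwm():
    return build_pwm(EXAMPLE_TRAINING_SEQS)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_gene(
    transcript_id="NM_000001",
    chrom="chr1",
    strand="+",
    tx_start=50_000,
    tx_end=60_000,
    cds=None,
    exons=None,
    symbol=None,
):
    """Compact GeneAnnotation builder for toy cases."""
    if exons is None:
        exons = [(tx_start, tx_end)]
    if cds is None:
        cds = (tx_start + 100, tx_end - 100)
    return GeneAnnotation(
        transcript_id=transcript_id,
        gene_symbol=symbol or transcript_id.replace("NM_", "G"),
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds[0],
        cds_end=cds[1],
        exons=exons,
    )


def make_region_stub(chrom, start, end, tss=None, strand="+", symbol="G1"):
    """Bare GeneRegion with a given full span and no segments."""
    return GeneRegion(
        transcript_id=symbol,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        tss=tss if tss is not None else start,
        segments={"upstream10k": [], "utr5": [], "cds": [], "utr3": []},
        full_span=(start, end),
    )
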