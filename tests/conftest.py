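import numpy as np
import pytest

from cagekit.core import GenomicInterval
from cagekit.expression import CagePeak
from cagekit.segmentation import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_transcript():
    """Two-exon coding transcript on +: exons 1000-1200 and 1500-1800."""
    return TranscriptModel(
        transcript_id="T1",
        gene_id="G1",
        gene_symbol="ALPHA",
        strand="+",
        exons=[
            GenomicInterval("chr1", 1000, 1200, "+"),
            GenomicInterval("chr1", 1500, 1800, "+"),
        ],
        cds_span=GenomicInterval("chr1", 1100, 1700, "+"),
    )


@pytest.fixture
def minus_transcript():
    """Two-exon non-coding transcript on -: exons 3000-3200 and 3500-3700."""
    return TranscriptModel(
        transcript_id="T2",
        gene_id="G2",
        gene_symbol="BETA",
        strand="-",
        exons=[
            GenomicInterval("chr1", 3000, 3200, "-"),
            GenomicInterval("chr1", 3500, 3700, "-"),
        ],
    )


def make_peak(start, end, strand="+", peak_id="p1", chrom="chr1", rep=None):
    return CagePeak(
        GenomicInterval(chrom, start, end, strand), id=peak_id,
        representative_position=rep,
    )
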