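"""Transcript-derived genome segments, hierarchical peak annotation, naming.

Each transcript model contributes: a 1-bp TSS segment; a proximal promoter
(500 bp upstream through 500 bp downstream of the TSS, truncated at the 3'
end of the first exon); exon segments classified by position within the
transcript (first / inner / last) and, secondarily, by coding status
(5' UTR / coding / 3' UTR / non-coding); intron segments by position; and
an antisense mirror of every segment on the opposite strand.

A CAGE peak overlapping several segments receives the highest-precedence
category: TSS, then proximal promoter, then first/inner/last exon, then
the antisense TSS, promoter and exons, and finally introns (sense before
antisense).  Peaks are named ``p{rank}@{gene}`` by descending pooled CTSS
count among the peaks associated with each gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .core import GenomicInterval

# Precedence (lower rank wins). Position refines the lumped antisense-exon
# and intron classes into a deterministic total order.
CATEGORY_RANK: Dict[str, int] = {
    "tss": 0,
    "proximal_promoter": 1,
    "exon_first": 2,
    "exon_inner": 3,
    "exon_last": 4,
    "antisense_tss": 5,
    "antisense_proximal_promoter": 6,
    "antisense_exon_first": 7,
    "antisense_exon_inner": 8,
    "antisense_exon_last": 9,
    "intron_first": 10,
    "intron_inner": 11,
    "intron_last": 12,
    "antisense_intron_first": 13,
    "antisense_intron_inner": 14,
    "antisense_intron_last": 15,
}

INTERGENIC = "intergenic"


@dataclass
class TranscriptModel:
    """A transcript: ordered exons (5' to 3') and an optional CDS span."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    strand: str
    exons: List[GenomicInterval]
    cds_span: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.transcript_id}: strand must be +/-")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        # store 5'->3'
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        if self.cds_span is not None:
            if not (self.span.start <= self.cds_span.start < self.cds_span.end <= self.span.end):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS outside transcript span"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def tss(self) -> int:
        """Genomic position of the transcript 5' end base."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    def introns(self) -> List[GenomicInterval]:
        """Introns in 5'->3' order."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.chrom, up.end, down.start, "+"))
            else:
                out.append(GenomicInterval(self.chrom, down.end, up.start, "-"))
        return out


@dataclass(frozen=True)
class GenomeSegment:
    interval: GenomicInterval
    category: str
    source_transcript: str
    coding: Optional[str] = None  # utr5 / coding / utr3 / noncoding for exons


@dataclass(frozen=True)
class SegmentationParams:
    promoter_up: int = 500
    promoter_down: int = 500
    gene_assoc_up: int = 500
    gene_assoc_down: int = 500
    proximity_margin: int = 300

    def __post_init__(self) -> None:
        for name in ("promoter_up", "promoter_down", "gene_assoc_up",
                     "gene_assoc_down", "proximity_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AnnotationResult:
    peak_id: str
    primary_category: str
    all_overlapping_categories: List[str]
    source_transcripts: List[str]
    coding_status: List[str] = field(default_factory=list)


def _positional_label(index: int, n: int) -> str:
    """first/inner/last label; a lone element is 'first', two give first+last."""
    if index == 0:
        return "first"
    if index == n - 1:
        return "last"
    return "inner"


def _promoter_interval(
    chrom: str, tss: int, first_exon: GenomicInterval, strand: str, params: SegmentationParams
) -> GenomicInterval:
    """Promoter window around the TSS, downstream-truncated at the first exon 3' end."""
    if strand == "+":
        start = max(0, tss - params.promoter_up)
        end = min(tss + params.promoter_down, first_exon.end)
    else:
        start = max(tss + 1 - params.promoter_down, first_exon.start)
        end = tss + 1 + params.promoter_up
    return GenomicInterval(chrom, start, end, strand)


def _exon_coding_pieces(
    exon: GenomicInterval, cds: Optional[GenomicInterval], strand: str
) -> List[Tuple[GenomicInterval, str]]:
    """Split one exon at CDS boundaries into (interval, coding-status) pieces."""
    if cds is None:
        return [(exon, "noncoding")]
    cuts = sorted({exon.start, exon.end, min(max(cds.start, exon.start), exon.end),
                   min(max(cds.end, exon.start), exon.end)})
    pieces = []
    for a, b in zip(cuts, cuts[1:]):
        if a >= b:
            continue
        if b <= cds.start:
            status = "utr5" if strand == "+" else "utr3"
        elif a >= cds.end:
            status = "utr3" if strand == "+" else "utr5"
        else:
            status = "coding"
        pieces.append((GenomicInterval(exon.chrom, a, b, strand), status))
    return pieces


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def build_segments(
    transcripts: Iterable[TranscriptModel],
    params: SegmentationParams = SegmentationParams(),
) -> List[GenomeSegment]:
    """Emit every sense segment plus its antisense mirror per transcript."""
    segments: List[GenomeSegment] = []

    def emit(interval: GenomicInterval, category: str, tid: str, coding=None):
        segments.append(GenomeSegment(interval, category, tid, coding))
        anti = GenomicInterval(interval.chrom, interval.start, interval.end,
                               _flip(interval.strand))
        segments.append(GenomeSegment(anti, "antisense_" + category, tid, coding))

    for tx in transcripts:
        tss = tx.tss
        emit(GenomicInterval(tx.chrom, tss, tss + 1, tx.strand), "tss", tx.transcript_id)
        emit(_promoter_interval(tx.chrom, tss, tx.exons[0], tx.strand, params),
             "proximal_promoter", tx.transcript_id)
        n_ex = len(tx.exons)
        for i, exon in enumerate(tx.exons):
            label = "exon_" + _positional_label(i, n_ex)
            for piece, status in _exon_coding_pieces(exon, tx.cds_span, tx.strand):
                emit(piece, label, tx.transcript_id, status)
        introns = tx.introns()
        for i, intron in enumerate(introns):
            emit(intron, "intron_" + _positional_label(i, len(introns)),
                 tx.transcript_id)
    return segments


class SegmentIndex:
    """Interval index over segments, keyed by (chrom, strand)."""

    def __init__(self, segments: Iterable[GenomeSegment]):
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for seg in segments:
            key = (seg.interval.chrom, seg.interval.strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                seg.interval.start, seg.interval.end, seg
            )

    def query(self, interval: GenomicInterval) -> List[GenomeSegment]:
        tree = self._trees.get((interval.chrom, interval.strand))
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(interval.start, interval.end)]


def annotate_peak(peak, index: SegmentIndex) -> AnnotationResult:
    """Assign a peak its highest-precedence overlapping category.

    Overlap requires strand equality; antisense segments already carry the
    strand opposite their source transcript, so one stranded overlap rule
    covers both sense and antisense semantics.
    """
    overlapping = index.query(peak.interval)
    if not overlapping:
        return AnnotationResult(peak.id, INTERGENIC, [], [])
    cats = sorted({s.category for s in overlapping}, key=CATEGORY_RANK.__getitem__)
    primary = cats[0]
    primary_segs = [s for s in overlapping if s.category == primary]
    sources = sorted({s.source_transcript for s in primary_segs})
    coding = sorted({s.coding for s in primary_segs if s.coding is not None})
    return AnnotationResult(peak.id, primary, cats, sources, coding)


def annotate_proximity(
    peaks: Sequence,
    features: Dict[str, Sequence[GenomicInterval]],
    margin: int = 300,
) -> Dict[str, Dict[str, bool]]:
    """Per-peak boolean flags: does the peak overlap a feature +- margin?

    Features (CpG islands, TATA boxes, repeats, TFBS clusters) are treated
    as unstranded; overlap is half-open after extending each feature by
    ``margin`` on both sides.
    """
    flags: Dict[str, Dict[str, bool]] = {}
    for peak in peaks:
        row = {}
        for label, intervals in features.items():
            hit = any(
                iv.chrom == peak.interval.chrom
                and peak.interval.start < iv.end + margin
                and iv.start - margin < peak.interval.end
                for iv in intervals
            )
            row[label] = hit
        flags[peak.id] = row
    return flags


# ---------------------------------------------------------------------------
# Peak naming: pN@GENE


@dataclass
class GeneAnchor:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    five_prime: int
    window: GenomicInterval


def gene_anchors(
    transcripts: Iterable[TranscriptModel],
    params: SegmentationParams = SegmentationParams(),
) -> List[GeneAnchor]:
    """One association anchor per gene.

    The gene 5' end is the 5'-most TSS over the gene's transcripts; the
    association window runs from 500 bp upstream of it through 500 bp
    downstream, truncated at the 3' end of the first exon of the
    transcript providing that TSS.
    """
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    anchors = []
    for gene_id, txs in sorted(by_gene.items()):
        strands = {t.strand for t in txs}
        if len(strands) > 1:
            raise ValueError(f"gene {gene_id}: transcripts on both strands")
        strand = strands.pop()
        # 5'-most TSS; deterministic tie-break on transcript_id
        key = (lambda t: (t.tss, t.transcript_id)) if strand == "+" else (
            lambda t: (-t.tss, t.transcript_id))
        provider = min(txs, key=key)
        g5 = provider.tss
        window = _promoter_interval(
            provider.chrom, g5, provider.exons[0], strand,
            SegmentationParams(
                promoter_up=params.gene_assoc_up,
                promoter_down=params.gene_assoc_down,
                proximity_margin=params.proximity_margin,
            ),
        )
        symbol = txs[0].gene_symbol or gene_id
        anchors.append(GeneAnchor(gene_id, symbol, provider.chrom, strand, g5, window))
    return anchors


def name_peaks(
    peaks: Sequence,
    pooled_counts: Dict[str, float],
    transcripts: Iterable[TranscriptModel],
    params: SegmentationParams = SegmentationParams(),
) -> Dict[str, str]:
    """Assign pN@GENE names; returns {peak_id: name}.

    A peak associates with a gene when its interval overlaps the gene's
    association window on the gene's strand; among several genes the one
    whose 5' end is nearest the peak's representative position wins (ties
    by lexicographic symbol).  Ranks within a gene follow descending
    pooled CTSS count, ties broken by genomic start then peak id.
    Unassociated peaks are named positionally.
    """
    missing = [p.id for p in peaks if p.id not in pooled_counts]
    if missing:
        raise ValueError(f"missing pooled counts for peaks: {missing[:3]}")
    anchors = gene_anchors(transcripts, params)

    assigned: Dict[str, List] = {}
    names: Dict[str, str] = {}
    for peak in peaks:
        candidates = [a for a in anchors if peak.interval.overlaps(a.window)]
        if not candidates:
            iv = peak.interval
            names[peak.id] = f"p@{iv.chrom}:{iv.start}..{iv.end},{iv.strand}"
            continue
        anchor_pos = (
            peak.representative_position
            if peak.representative_position is not None
            else peak.interval.five_prime()
        )
        best = min(candidates, key=lambda a: (abs(anchor_pos - a.five_prime), a.symbol))
        assigned.setdefault(best.gene_id, []).append((peak, best.symbol))

    for gene_id, members in assigned.items():
        members.sort(key=lambda pk: (-pooled_counts[pk[0].id],
                                     pk[0].interval.start, pk[0].id))
        for rank, (peak, symbol) in enumerate(members, 1):
            names[peak.id] = f"p{rank}@{symbol}"

    seen: Dict[str, str] = {}
    for pid, name in names.items():
        if name in seen:
            raise ValueError(f"duplicate peak name {name!r} for {seen[name]} and {pid}")
        seen[name] = pid
    return names
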