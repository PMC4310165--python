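"""CTSS construction: aligned CAGE reads -> single-base TSS profiles.

A CAGE tag start site (CTSS) is the genomic base under the 5' end of an
aligned CAGE read; per-base, per-strand counts of these 5' ends quantify
transcription initiation at single-base resolution. Alignments are first
filtered on mapping quality and sequence identity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

from .core import FormatError, GenomicInterval

CtssKey = Tuple[str, str, int]  # (chrom, strand, position)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read reduced to the fields the CTSS pipeline needs.

    ``identity`` is the fraction of aligned read bases matching the
    reference, in [0, 1]; for BAM input it is derived from the NM tag.
    """

    interval: GenomicInterval
    mapq: int
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.mapq < 0:
            raise ValueError(f"negative mapq {self.mapq}")


@dataclass(frozen=True)
class FilterParams:
    """Alignment quality thresholds (both inclusive).

    Defaults are the standard CAGE processing thresholds: mapping quality
    >= 20 and sequence identity >= 85%.
    """

    min_mapq: int = 20
    min_identity: float = 0.85


@dataclass
class CtssProfile:
    """Per-base, per-strand counts of CAGE read 5' ends for one library."""

    library_id: str
    counts: Dict[CtssKey, int] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, position: int, count: int = 1) -> None:
        if count <= 0:
            raise ValueError("CTSS counts must be positive")
        key = (chrom, strand, position)
        self.counts[key] = self.counts.get(key, 0) + count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def items_sorted(self) -> List[Tuple[CtssKey, int]]:
        """(key, count) pairs sorted by chrom, position, strand."""
        return sorted(self.counts.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1]))

    @classmethod
    def pooled(cls, profiles: Iterable["CtssProfile"], library_id: str = "pooled") -> "CtssProfile":
        out = cls(library_id=library_id)
        for prof in profiles:
            for (chrom, strand, pos), c in prof.counts.items():
                out.add(chrom, strand, pos, c)
        return out


def filter_alignments(
    records: Iterable[AlignmentRecord], params: FilterParams = FilterParams()
) -> Iterator[AlignmentRecord]:
    """Keep records with mapq >= min_mapq and identity >= min_identity.

    Both thresholds are inclusive; input order is preserved.
    """
    for rec in records:
        if rec.mapq >= params.min_mapq and rec.identity >= params.min_identity:
            yield rec


def count_ctss(
    records: Iterable[AlignmentRecord], library_id: str = "library"
) -> CtssProfile:
    """Count read 5' ends: interval.start on +, interval.end - 1 on -."""
    profile = CtssProfile(library_id=library_id)
    for rec in records:
        strand = rec.interval.strand
        if strand == ".":
            raise ValueError("unstranded alignment cannot yield a CTSS")
        profile.add(rec.interval.chrom, strand, rec.interval.five_prime())
    return profile


def read_alignments_tabular(path) -> Iterator[AlignmentRecord]:
    """Read a 6-column TSV of alignments: chrom, start, end, strand, mapq, identity."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, strand, mapq, identity = fields
            yield AlignmentRecord(
                interval=GenomicInterval(chrom, int(start), int(end), strand),
                mapq=int(mapq),
                identity=float(identity),
            )


def read_alignments_bam(path, mode: str = "rb") -> Iterator[AlignmentRecord]:
    """Read alignments from SAM/BAM via pysam.

    Secondary, supplementary and unmapped records are dropped (one 5' end
    per sequenced molecule). Identity is (aligned read bases - NM) /
    aligned read bases; a record without an NM tag is taken at identity 1.
    """
    import pysam

    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            aln_len = aln.query_alignment_length
            if aln_len == 0:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            identity = max(0.0, (aln_len - nm) / aln_len)
            strand = "-" if aln.is_reverse else "+"
            yield AlignmentRecord(
                interval=GenomicInterval(
                    aln.reference_name, aln.reference_start, aln.reference_end, strand
                ),
                mapq=aln.mapping_quality,
                identity=identity,
            )
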