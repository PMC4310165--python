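"""Readers and writers for every external format the toolkit touches.

BED6 for CTSS profiles and peaks, GTF2.2 for transcript models, JASPAR
text for motif matrices, TSV for expression matrices, FASTA for genomes,
plus the RFC 3986 percent-encoding scheme used to turn curated sample
names into file-system-safe identifiers.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .core import FormatError, GenomicInterval
from .ctss import CtssProfile
from .expression import CagePeak, ExpressionMatrix
from .motif_stats import Pwm
from .segmentation import GenomeSegment, TranscriptModel

# --------------------------------------------------------------------------
# Sample names (RFC 3986 percent-encoding, lowercase hex, space -> %20)

_UNRESERVED = set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-._~"
)


@dataclass(frozen=True)
class SampleName:
    """A curated sample name with its tracking identifiers."""

    curated_name: str
    rna_id: str = ""
    library_id: str = ""

    @property
    def encoded(self) -> str:
        return encode_sample_name(self.curated_name)


def encode_sample_name(name: str) -> str:
    """Percent-encode every character outside the RFC 3986 unreserved set.

    Hex digits are emitted lowercase and space becomes %20, matching the
    promoter-atlas archive file-name style.
    """
    out = []
    for ch in name:
        if ch in _UNRESERVED:
            out.append(ch)
        else:
            out.extend(f"%{b:02x}" for b in ch.encode("utf-8"))
    return "".join(out)


def decode_sample_name(encoded: str) -> str:
    """Inverse of :func:`encode_sample_name`."""
    buf = bytearray()
    i = 0
    while i < len(encoded):
        ch = encoded[i]
        if ch == "%":
            try:
                buf.append(int(encoded[i + 1 : i + 3], 16))
            except ValueError as exc:
                raise FormatError(f"bad percent escape at offset {i}") from exc
            i += 3
        else:
            buf.extend(ch.encode("utf-8"))
            i += 1
    return buf.decode("utf-8")


# --------------------------------------------------------------------------
# CTSS BED (BED6, one 1-bp interval per line, score = count)


def read_ctss_bed(path, library_id: Optional[str] = None) -> CtssProfile:
    """Read a CTSS BED6 file into a profile; intervals must be 1 bp wide."""
    profile = CtssProfile(library_id=library_id or str(path))
    seen = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected BED6, got {len(fields)} columns")
            chrom, start, end, _name, score, strand = fields[:6]
            start, end = int(start), int(end)
            if end - start != 1:
                raise FormatError(f"line {lineno}: CTSS interval width != 1")
            count = int(score)
            if count < 0:
                raise FormatError(f"line {lineno}: negative count")
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: CTSS strand must be + or -")
            key = (chrom, strand, start)
            if key in seen:
                raise FormatError(f"line {lineno}: duplicate CTSS position {key}")
            seen.add(key)
            if count > 0:
                profile.add(chrom, strand, start, count)
    return profile


def write_ctss_bed(profile: CtssProfile, path, header: Optional[str] = None) -> None:
    """Write a profile as BED6; names are regenerated as chrom:pos,strand."""
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for (chrom, strand, pos), count in profile.items_sorted():
            name = f"{chrom}:{pos},{strand}"
            handle.write(f"{chrom}\t{pos}\t{pos + 1}\t{name}\t{count}\t{strand}\n")


# --------------------------------------------------------------------------
# Peak BED


def read_peaks_bed(path) -> List[CagePeak]:
    peaks = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected BED6 peak")
            chrom, start, end, name, score, strand = fields[:6]
            rep = None
            if len(fields) >= 7 and fields[6] not in ("", "."):
                rep = int(fields[6])
            peaks.append(
                CagePeak(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    id=name,
                    representative_position=rep,
                )
            )
    return peaks


def write_peaks_bed(peaks: Sequence[CagePeak], path, header: Optional[str] = None) -> None:
    """BED6 + optional 7th column with the representative position."""
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for p in peaks:
            iv = p.interval
            rep = "." if p.representative_position is None else str(p.representative_position)
            label = p.name or p.id
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\t{rep}\n"
            )


# --------------------------------------------------------------------------
# GTF transcript models

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcript_gtf(path) -> List[TranscriptModel]:
    """Parse transcript models from GTF exon (and optional CDS) features.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    cds: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, tuple] = {}
    declared: Dict[str, GenomicInterval] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "transcript"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                raise FormatError(f"line {lineno}: missing transcript_id")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if feature == "transcript":
                declared[tid] = iv
                meta.setdefault(tid, (attr.get("gene_id", tid), attr.get("gene_name", "")))
                continue
            meta.setdefault(tid, (attr.get("gene_id", tid), attr.get("gene_name", "")))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    for tid, span in declared.items():
        if tid not in exons:
            raise FormatError(f"transcript {tid} has zero exons")
        for e in exons[tid]:
            if not (span.start <= e.start and e.end <= span.end):
                raise FormatError(f"transcript {tid}: exon outside transcript span")

    transcripts = []
    for tid in sorted(exons):
        gene_id, gene_name = meta[tid]
        cds_span = None
        if tid in cds:
            pieces = cds[tid]
            cds_span = GenomicInterval(
                pieces[0].chrom,
                min(c.start for c in pieces),
                max(c.end for c in pieces),
                pieces[0].strand,
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_symbol=gene_name or gene_id,
                strand=exons[tid][0].strand,
                exons=exons[tid],
                cds_span=cds_span,
            )
        )
    return transcripts


def write_transcript_gtf(transcripts: Sequence[TranscriptModel], path,
                         header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for tx in sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id)):
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_symbol}";'
            )
            span = tx.span
            handle.write(
                f"{tx.chrom}\tcagekit\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )
            for exon in sorted(tx.exons, key=lambda e: e.start):
                handle.write(
                    f"{tx.chrom}\tcagekit\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds_span is not None:
                handle.write(
                    f"{tx.chrom}\tcagekit\tCDS\t{tx.cds_span.start + 1}\t{tx.cds_span.end}"
                    f"\t.\t{tx.strand}\t.\t{attrs}\n"
                )


# --------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path, pseudocount: float = 0.01) -> List[Pwm]:
    """Read JASPAR-format motifs into PWMs with a per-cell pseudocount."""
    with open(path) as handle:
        try:
            parsed = bio_motifs.parse(handle, "jaspar")
            records = list(parsed)
        except Exception as exc:
            raise FormatError(f"cannot parse JASPAR file: {exc}") from exc
    pwms = []
    for record in records:
        counts = np.array([record.counts[b] for b in "ACGT"], dtype=float).T
        if counts.size == 0:
            raise FormatError(f"motif {record.matrix_id}: empty matrix")
        if np.any(counts.sum(axis=1) == 0) and pseudocount == 0:
            raise FormatError(f"motif {record.matrix_id}: all-zero column")
        motif_id = record.matrix_id or record.name
        pwms.append(Pwm.from_counts(motif_id, counts, pseudocount))
    return pwms


def write_jaspar_pfm(pwms_counts: Mapping[str, np.ndarray], path) -> None:
    """Write count matrices (positions x 4, ACGT columns) in JASPAR format."""
    with open(path, "w") as handle:
        for motif_id, counts in pwms_counts.items():
            counts = np.asarray(counts)
            handle.write(f">{motif_id} {motif_id}\n")
            for col, base in enumerate("ACGT"):
                row = " ".join(f"{v:.0f}" for v in counts[:, col])
                handle.write(f"{base} [ {row} ]\n")


# --------------------------------------------------------------------------
# Expression matrix TSV


def read_expression_matrix(path, kind: str = "counts") -> ExpressionMatrix:
    with open(path) as handle:
        for line in handle:
            if line.strip() and not line.startswith("#"):
                raw_cols = line.rstrip("\n").split("\t")[1:]
                if len(set(raw_cols)) != len(raw_cols):
                    raise FormatError("duplicate sample id in header")
                break
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("expression matrix needs a peak column and >=1 sample")
    sample_ids = list(df.columns[1:])
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample id in header")
    peak_ids = df.iloc[:, 0].tolist()
    if len(set(peak_ids)) != len(peak_ids):
        raise FormatError("duplicate peak id")
    body = df.iloc[:, 1:]
    try:
        values = body.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    if np.isnan(values).any():
        raise FormatError("missing or non-numeric cell in expression matrix")
    return ExpressionMatrix(peak_ids, sample_ids, values, kind)


def write_expression_matrix(matrix: ExpressionMatrix, path,
                            header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        handle.write("peak_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.peak_ids, matrix.values):
            cells = "\t".join(repr(float(v)) for v in row)
            handle.write(f"{pid}\t{cells}\n")


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    """Load a (small) FASTA genome fully into memory via pyfaidx."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# Segments BED and cluster TSV


def write_segments_bed(segments: Sequence[GenomeSegment], path,
                       header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for seg in segments:
            iv = seg.interval
            label = seg.category if seg.coding is None else f"{seg.category}|{seg.coding}"
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}:{seg.source_transcript}"
                f"\t0\t{iv.strand}\n"
            )


def read_clusters_tsv(path) -> Dict[str, List[str]]:
    """Read cluster membership: two columns, cluster_id <tab> promoter_id."""
    clusters: Dict[str, List[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            clusters.setdefault(fields[0], []).append(fields[1])
    return clusters


def write_clusters_tsv(clusters: Mapping[str, Sequence[str]], path,
                       header: Optional[str] = None) -> None:
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        for cid in clusters:
            for member in clusters[cid]:
                handle.write(f"{cid}\t{member}\n")
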