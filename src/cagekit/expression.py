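"""CAGE peak expression: counting, RLE normalization, tags per million.

Peak-level counts are sums of CTSS counts within each peak on the peak's
strand.  Library sizes are adjusted by the relative log expression (RLE)
method: the size factor of a library is the median, over peaks expressed
in every library, of the ratio of its count to the per-peak geometric
mean (median-of-ratios), rescaled so the factors have geometric mean 1.
Expression is reported as tags per million over the RLE-adjusted
effective library size.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .core import GenomicInterval, geometric_mean
from .ctss import CtssProfile


@dataclass
class CagePeak:
    """A named genomic interval carrying peak-level attributes."""

    interval: GenomicInterval
    id: str
    name: Optional[str] = None
    representative_position: Optional[int] = None
    rep_fallback: bool = False

    def __post_init__(self) -> None:
        if self.representative_position is not None and not (
            self.interval.start <= self.representative_position < self.interval.end
        ):
            raise ValueError(
                f"peak {self.id}: representative position outside interval"
            )


@dataclass
class ExpressionMatrix:
    """Peaks x samples matrix of raw counts or normalized TPM."""

    peak_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    kind: str = "counts"  # or "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peak_ids), len(self.sample_ids)):
            raise ValueError("matrix dimensions inconsistent with id lists")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.kind not in ("counts", "tpm"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def row(self, peak_id: str) -> np.ndarray:
        return self.values[self.peak_ids.index(peak_id)]


@dataclass
class NormalizationFactors:
    """Per-sample RLE size factors (geometric mean 1) and library sizes."""

    sample_ids: List[str]
    size_factors: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be positive")

    @property
    def effective_sizes(self) -> np.ndarray:
        """RLE-adjusted library sizes: s_j times the geometric-mean library size."""
        return self.size_factors * geometric_mean(self.library_sizes)


def _check_no_same_strand_overlap(peaks: Sequence[CagePeak]) -> None:
    by_key: Dict[tuple, List[CagePeak]] = {}
    for p in peaks:
        by_key.setdefault((p.interval.chrom, p.interval.strand), []).append(p)
    for group in by_key.values():
        group.sort(key=lambda p: p.interval.start)
        for a, b in zip(group, group[1:]):
            if a.interval.end > b.interval.start:
                raise ValueError(
                    f"overlapping same-strand peaks: {a.id} and {b.id}"
                )


def quantify_peaks(
    profiles: Sequence[CtssProfile], peaks: Sequence[CagePeak]
) -> ExpressionMatrix:
    """Count CTSS tags within each peak (strand-matched) per library."""
    _check_no_same_strand_overlap(peaks)
    peak_ids = [p.id for p in peaks]
    values = np.zeros((len(peaks), len(profiles)))
    # map every base of every peak once; profiles are sparse dicts
    base_to_row: Dict[tuple, int] = {}
    for i, p in enumerate(peaks):
        for pos in range(p.interval.start, p.interval.end):
            base_to_row[(p.interval.chrom, p.interval.strand, pos)] = i
    for j, prof in enumerate(profiles):
        for key, count in prof.counts.items():
            row = base_to_row.get(key)
            if row is not None:
                values[row, j] += count
    return ExpressionMatrix(peak_ids, [p.library_id for p in profiles], values, "counts")


def rle_scale_factors(
    counts: ExpressionMatrix,
    library_sizes: Optional[Sequence[float]] = None,
    subset: Optional[Sequence[str]] = None,
) -> NormalizationFactors:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    Only peaks with positive counts in every sample contribute to the
    medians; ``subset`` optionally restricts them further to the given
    peak ids (e.g. a robust-peak set).  ``library_sizes`` defaults to the
    column sums of the count matrix; pass the libraries' total CTSS counts
    when peaks do not tile every expressed base.
    """
    if counts.kind != "counts":
        raise ValueError("RLE factors are computed from raw counts")
    v = counts.values
    if subset is not None:
        wanted = set(subset)
        missing = wanted - set(counts.peak_ids)
        if missing:
            raise ValueError(f"subset peaks not in matrix: {sorted(missing)[:3]}")
        v = v[[pid in wanted for pid in counts.peak_ids]]
    if v.shape[1] < 2:
        raise ValueError("RLE needs at least 2 samples")
    positive = np.all(v > 0, axis=1)
    if not positive.any():
        raise ValueError("RLE undefined: no peak with all-positive counts")
    sub = v[positive]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    s = np.median(ratios, axis=0)
    s = s / geometric_mean(s)
    if library_sizes is None:
        library_sizes = v.sum(axis=0)
    return NormalizationFactors(list(counts.sample_ids), s, np.asarray(library_sizes))


def normalize_tpm(
    counts: ExpressionMatrix, factors: NormalizationFactors
) -> ExpressionMatrix:
    """Tags per million over the RLE-adjusted effective library size.

    tpm_ij = counts_ij / (s_j * geomean_k(N_k)) * 1e6.  Using the common
    geometric-mean library size makes the result exactly invariant to
    rescaling any single library's counts.
    """
    if counts.sample_ids != factors.sample_ids:
        raise ValueError("factors computed from different samples")
    eff = factors.effective_sizes
    if np.any(eff == 0):
        raise ValueError("zero effective library size")
    tpm = counts.values / eff[None, :] * 1e6
    return ExpressionMatrix(list(counts.peak_ids), list(counts.sample_ids), tpm, "tpm")


def representative_positions(
    peaks: Sequence[CagePeak], pooled: CtssProfile
) -> List[CagePeak]:
    """Set each peak's representative position to its most expressed base.

    Ties break to the 5'-most position on the peak's strand; a peak with
    zero pooled signal falls back to its 5' end and is flagged.
    """
    out = []
    for peak in peaks:
        iv = peak.interval
        positions = range(iv.start, iv.end)
        counts = [pooled.counts.get((iv.chrom, iv.strand, pos), 0) for pos in positions]
        best = max(counts)
        if best == 0:
            rep, fallback = iv.five_prime(), True
        else:
            fallback = False
            at_max = [pos for pos, c in zip(positions, counts) if c == best]
            rep = min(at_max) if iv.strand != "-" else max(at_max)
        out.append(
            CagePeak(iv, peak.id, peak.name, representative_position=rep,
                     rep_fallback=fallback)
        )
    return out
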