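"""Core genomic primitives shared by every module.

All coordinates in cagekit are 0-based, half-open ``[start, end)``; BED is
the native convention and GTF is converted on read/write.
"""
from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def five_prime(self) -> int:
        """Position of the 5' end base (start on +, end-1 on -)."""
        if self.strand == "-":
            return self.end - 1
        return self.start


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def geometric_mean(values) -> float:
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))
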