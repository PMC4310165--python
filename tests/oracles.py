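"""Independent reference implementations used only to check the package.

These deliberately avoid the package's vectorized scanning and interval
index: the scan oracle multiplies per-base probability ratios in pure
Python (reverse-complementing the window text for the minus strand), and
the annotation oracle tests every peak against every raw transcript
definition directly.
"""
from __future__ import annotations

from typing import List, Tuple

from cagekit.segmentation import CATEGORY_RANK, INTERGENIC

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_scan(matrix, bg_probs, seq: str, prior: float, threshold: float,
               both_strands: bool = True) -> List[Tuple[int, str, float, float]]:
    """All (offset, strand, lr, posterior) with posterior > threshold."""
    L = len(matrix)
    hits = []
    seq = seq.upper()
    strands = ["+", "-"] if both_strands else ["+"]
    for o in range(len(seq) - L + 1):
        window = seq[o : o + L]
        if any(ch not in _IDX for ch in window):
            continue
        for strand in strands:
            w = window if strand == "+" else "".join(
                _COMP[c] for c in reversed(window))
            lr = 1.0
            for i, ch in enumerate(w):
                lr *= matrix[i][_IDX[ch]] / bg_probs[_IDX[ch]]
            post = prior * lr / (prior * lr + 1.0 - prior)
            if post > threshold:
                hits.append((o, strand, lr, post))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _positional(i: int, n: int) -> str:
    if i == 0:
        return "first"
    if i == n - 1:
        return "last"
    return "inner"


def brute_force_annotate(peak, transcripts, promoter_up=500, promoter_down=500) -> str:
    """Primary annotation of a peak from raw transcript definitions.

    No segment list, no interval index: every region of every transcript
    is derived inline and tested against the peak with the half-open
    overlap rule; the minimum label under the precedence order wins.
    """
    iv = peak.interval
    labels = set()
    for tx in transcripts:
        if tx.chrom != iv.chrom:
            continue
        prefix = "" if iv.strand == tx.strand else "antisense_"
        regions = []
        tss = tx.tss
        regions.append(("tss", tss, tss + 1))
        if tx.strand == "+":
            regions.append(("proximal_promoter", max(0, tss - promoter_up),
                            min(tss + promoter_down, tx.exons[0].end)))
        else:
            regions.append(("proximal_promoter",
                            max(tx.exons[0].start, tss + 1 - promoter_down),
                            tss + 1 + promoter_up))
        n = len(tx.exons)
        for i, exon in enumerate(tx.exons):
            regions.append((f"exon_{_positional(i, n)}", exon.start, exon.end))
        genomic = sorted(tx.exons, key=lambda e: e.start)
        gaps = [(a.end, b.start) for a, b in zip(genomic, genomic[1:])]
        if tx.strand == "-":
            gaps = gaps[::-1]
        for i, (s, e) in enumerate(gaps):
            regions.append((f"intron_{_positional(i, len(gaps))}", s, e))
        for label, s, e in regions:
            if s < e and s < iv.end and iv.start < e:
                labels.add(prefix + label)
    if not labels:
        return INTERGENIC
    return min(labels, key=CATEGORY_RANK.__getitem__)
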