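"""Deterministic synthetic data: toy genomes, transcripts, peaks, CTSS,
expression, and motif-planted promoter sets.

Everything is driven by a single integer seed through
``numpy.random.default_rng``, so the full fixture set is bit-identical
across runs.  The generator emulates the statistical structure the
toolkit's tests need — GC-controlled i.i.d. genome sequence, negative
binomially overdispersed peak counts with per-library size factors, and
promoters carrying planted motif copies whose number drives one sample's
expression — not sequencing error, mappability, or real promoter
architecture.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, revcomp
from .ctss import CtssProfile
from .expression import CagePeak, ExpressionMatrix
from .motif_stats import BASES, Pwm
from .segmentation import TranscriptModel


@dataclass
class SimConfig:
    """Conditions for one synthetic data set."""

    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.409
    n_transcripts: int = 12
    n_peaks: int = 40
    n_samples: int = 6
    n_promoters: int = 300
    nb_dispersion: float = 0.1
    expression_noise_sd: float = 0.25
    size_factors: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        for name in ("genome_length", "n_transcripts", "n_peaks", "n_samples",
                     "n_promoters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0 or self.expression_noise_sd < 0:
            raise ValueError("invalid noise parameters")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    at = (1.0 - gc) / 2.0
    cg = gc / 2.0
    codes = rng.choice(4, size=length, p=[at, cg, cg, at])
    return "".join(BASES[c] for c in codes)


def synth_genome(config: SimConfig, rng: Optional[np.random.Generator] = None
                 ) -> Dict[str, str]:
    """One-chromosome genome of i.i.d. bases with P(G or C) = gc."""
    rng = rng or config.rng()
    return {"chr1": _random_seq(config.genome_length, config.gc, rng)}


def synth_transcripts(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> List[TranscriptModel]:
    """Random non-overlapping genes: 1-5 exons, both strands, ~half coding.

    Genes are laid out in equal slots with a 700 bp edge margin so that
    promoter windows never run off the chromosome.
    """
    rng = rng or config.rng()
    margin = 700
    usable = config.genome_length - 2 * margin
    slot = usable // config.n_transcripts
    if slot < 400:
        raise ValueError("genome too short to place the requested transcripts")
    transcripts = []
    for i in range(config.n_transcripts):
        slot_start = margin + i * slot
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 6))
        gene_len = int(rng.integers(200, max(201, slot - 100)))
        start = slot_start + int(rng.integers(0, slot - gene_len))
        # cut the gene span into alternating exon/intron blocks
        n_cuts = 2 * n_exons - 2
        if n_cuts:
            cuts = np.sort(rng.choice(np.arange(1, gene_len), size=n_cuts, replace=False))
        else:
            cuts = np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [gene_len]]) + start
        exons = [
            GenomicInterval("chr1", int(bounds[2 * k]), int(bounds[2 * k + 1]), strand)
            for k in range(n_exons)
        ]
        cds_span = None
        exonic = sum(len(e) for e in exons)
        if rng.random() < 0.5 and exonic >= 30:
            lo = exons[0].start + int(rng.integers(1, max(2, len(exons[0]))))
            hi = exons[-1].end - int(rng.integers(1, max(2, len(exons[-1]))))
            if lo < hi:
                cds_span = GenomicInterval("chr1", lo, hi, strand)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"T{i:03d}",
                gene_id=f"G{i:03d}",
                gene_symbol=f"GENE{i}",
                strand=strand,
                exons=exons,
                cds_span=cds_span,
            )
        )
    return transcripts


def synth_peaks(
    config: SimConfig,
    transcripts: Sequence[TranscriptModel],
    rng: Optional[np.random.Generator] = None,
) -> List[CagePeak]:
    """Random CAGE peaks: most near transcript TSSs, some intergenic.

    Peaks are 5-30 bp wide and never overlap on the same strand.
    """
    rng = rng or config.rng()
    taken: Dict[str, List[Tuple[int, int]]] = {"+": [], "-": []}

    def free(strand: str, start: int, end: int) -> bool:
        return all(end <= s or e <= start for s, e in taken[strand])

    peaks: List[CagePeak] = []
    i = 0
    attempts = 0
    while len(peaks) < config.n_peaks and attempts < config.n_peaks * 200:
        attempts += 1
        width = int(rng.integers(5, 31))
        if transcripts and rng.random() < 0.7:
            tx = transcripts[int(rng.integers(0, len(transcripts)))]
            center = tx.tss + int(rng.integers(-400, 401))
            strand = tx.strand
        else:
            center = int(rng.integers(700, config.genome_length - 700))
            strand = "+" if rng.random() < 0.5 else "-"
        start = max(1, center - width // 2)
        end = start + width
        if end >= config.genome_length - 1 or not free(strand, start, end):
            continue
        taken[strand].append((start, end))
        peaks.append(CagePeak(GenomicInterval("chr1", start, end, strand), id=f"peak{i:04d}"))
        i += 1
    peaks.sort(key=lambda p: (p.interval.start, p.interval.strand))
    return peaks


def synth_ctss_and_expression(
    config: SimConfig,
    peaks: Sequence[CagePeak],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[CtssProfile], ExpressionMatrix]:
    """Per-library CTSS profiles and the matching peak count matrix.

    Per-peak means are log-normal; counts are negative binomial with the
    configured dispersion, scaled by per-sample size factors; each peak's
    tags are spread over its bases with a geometric decay away from a
    peak-specific mode, so representative positions are well defined.
    """
    rng = rng or config.rng()
    n_peaks, n_samples = len(peaks), config.n_samples
    sf = np.asarray(
        config.size_factors if config.size_factors is not None else np.ones(n_samples),
        dtype=float,
    )
    if len(sf) != n_samples:
        raise ValueError("size_factors length != n_samples")
    base_mean = np.exp(rng.normal(np.log(50.0), 1.0, size=n_peaks))
    disp = config.nb_dispersion
    mu = base_mean[:, None] * sf[None, :]
    n_param = 1.0 / disp
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu)).astype(float)

    # per-peak positional profile: geometric decay from a mode base
    profiles = [CtssProfile(library_id=f"S{j:02d}") for j in range(n_samples)]
    for i, peak in enumerate(peaks):
        width = len(peak.interval)
        mode = int(rng.integers(0, width))
        weights = 0.5 ** np.abs(np.arange(width) - mode)
        weights /= weights.sum()
        for j in range(n_samples):
            c = int(counts[i, j])
            if c == 0:
                continue
            alloc = rng.multinomial(c, weights)
            for k, a in enumerate(alloc):
                if a > 0:
                    profiles[j].add(
                        peak.interval.chrom, peak.interval.strand,
                        peak.interval.start + k, int(a),
                    )
    matrix = ExpressionMatrix(
        [p.id for p in peaks], [p.library_id for p in profiles], counts, "counts"
    )
    return profiles, matrix


# ---------------------------------------------------------------------------
# Motif-planted promoter sets


def random_pwm(length: int, rng: np.random.Generator, motif_id: str = "random",
               alpha: float = 0.5) -> Pwm:
    """A random motif with Dirichlet(alpha) position distributions."""
    mat = rng.dirichlet([alpha] * 4, size=length)
    mat = np.clip(mat, 1e-6, None)
    mat /= mat.sum(axis=1, keepdims=True)
    return Pwm(motif_id, mat)


def consensus_pwm(consensus: str, motif_id: str = "consensus",
                  match_prob: float = 0.97) -> Pwm:
    """A near-deterministic motif for a given consensus sequence."""
    off = (1.0 - match_prob) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus.upper()):
        mat[i, BASES.index(base)] = match_prob
    return Pwm(motif_id, mat)


def random_consensus_pwm(length: int, rng: np.random.Generator,
                         motif_id: str = "decoy", match_prob: float = 0.97) -> Pwm:
    return consensus_pwm(_random_seq(length, 0.5, rng), motif_id, match_prob)


def synth_promoter_sequences(
    n: int, length: int = 400, gc: float = 0.409,
    rng: Optional[np.random.Generator] = None,
) -> List[str]:
    rng = rng if rng is not None else np.random.default_rng(0)
    return [_random_seq(length, gc, rng) for _ in range(n)]


def plant_motif(
    sequences: Sequence[str],
    pwm: Pwm,
    fraction: float,
    max_copies: int,
    rng: np.random.Generator,
    mutation_prob: float = 0.05,
) -> Tuple[List[str], np.ndarray]:
    """Write motif consensus copies into a random subset of promoters.

    A ``fraction`` of promoters receives 1..max_copies consensus copies at
    uniform random non-overlapping offsets, with per-base mutation
    probability ``mutation_prob``.  Returns the modified sequences and the
    per-promoter copy numbers.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    consensus = pwm.consensus
    L = len(consensus)
    n = len(sequences)
    copies = np.zeros(n, dtype=int)
    planted_idx = rng.choice(n, size=max(1, int(round(fraction * n))), replace=False)
    out = list(sequences)
    for idx in planted_idx:
        seq = list(out[idx])
        k = int(rng.integers(1, max_copies + 1))
        used: List[Tuple[int, int]] = []
        placed = 0
        for _ in range(50):
            if placed == k:
                break
            off = int(rng.integers(0, len(seq) - L + 1))
            if any(off < e and s < off + L for s, e in used):
                continue
            inserted = [
                ch if rng.random() >= mutation_prob
                else BASES[int(rng.integers(0, 4))]
                for ch in consensus
            ]
            seq[off : off + L] = inserted
            used.append((off, off + L))
            placed += 1
        copies[idx] = placed
        out[idx] = "".join(seq)
    return out, copies


def plant_homogeneous(
    sequences: Sequence[str],
    pwm: Pwm,
    mean_copies: float,
    rng: np.random.Generator,
    mutation_prob: float = 0.05,
) -> Tuple[List[str], np.ndarray]:
    """Plant a homogeneous site process: Poisson(mean_copies) per promoter.

    Site offsets are uniform (overlaps allowed); per-base mutation
    probability as in :func:`plant_motif`.  Returns sequences and the
    planted copy numbers.
    """
    consensus = pwm.consensus
    L = len(consensus)
    out = []
    copies = np.zeros(len(sequences), dtype=int)
    for i, seq in enumerate(sequences):
        k = int(rng.poisson(mean_copies))
        chars = list(seq)
        for _ in range(k):
            off = int(rng.integers(0, len(chars) - L + 1))
            chars[off : off + L] = [
                ch if rng.random() >= mutation_prob else BASES[int(rng.integers(0, 4))]
                for ch in consensus
            ]
        copies[i] = k
        out.append("".join(chars))
    return out, copies


def expression_from_copies(
    copies: np.ndarray,
    target_r: float,
    rng: np.random.Generator,
    baseline: float = 5.0,
    slope: float = 2.0,
) -> np.ndarray:
    """Expression linear in planted copy number with calibrated noise.

    The Gaussian noise SD is set from the copy-number variance so the
    population correlation with ``copies`` equals ``target_r``.
    """
    if not 0.0 < target_r <= 1.0:
        raise ValueError("target_r must be in (0, 1]")
    copies = np.asarray(copies, dtype=float)
    sd_c = copies.std()
    if sd_c == 0:
        raise ValueError("copy numbers are constant; correlation undefined")
    noise_sd = slope * sd_c * np.sqrt(1.0 / target_r**2 - 1.0)
    return baseline + slope * copies + rng.normal(0.0, noise_sd, size=len(copies))


def synth_clusters(
    promoter_ids: Sequence[str],
    n_clusters: int,
    cluster_size: int,
    rng: np.random.Generator,
) -> Dict[str, List[str]]:
    """Clusters drawn uniformly at random (with reuse across clusters)."""
    ids = list(promoter_ids)
    return {
        f"cluster{k:03d}": [ids[i] for i in rng.choice(len(ids), cluster_size, replace=False)]
        for k in range(n_clusters)
    }


def mirror_interval(iv: GenomicInterval, length: int) -> GenomicInterval:
    """Reverse-complement coordinate transform: [s, e) -> [L-e, L-s), strand flipped."""
    strand = {"+": "-", "-": "+", ".": "."}[iv.strand]
    return GenomicInterval(iv.chrom, length - iv.end, length - iv.start, strand)


def mirror_transcript(tx: TranscriptModel, length: int) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tx.transcript_id,
        gene_id=tx.gene_id,
        gene_symbol=tx.gene_symbol,
        strand={"+": "-", "-": "+"}[tx.strand],
        exons=[mirror_interval(e, length) for e in tx.exons],
        cds_span=None if tx.cds_span is None else mirror_interval(tx.cds_span, length),
    )


def mirror_peak(peak: CagePeak, length: int) -> CagePeak:
    rep = peak.representative_position
    return CagePeak(
        mirror_interval(peak.interval, length),
        id=peak.id,
        name=peak.name,
        representative_position=None if rep is None else length - 1 - rep,
    )
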