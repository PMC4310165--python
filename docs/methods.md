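# Methods

## CTSS construction

An aligned CAGE read is reduced to the genomic base under its 5′ end:
`interval.start` on the plus strand, `interval.end − 1` on the minus
strand. Records are filtered beforehand at mapping quality ≥ 20 and
sequence identity ≥ 85%, both inclusive. "Sequence identity" is not a
uniquely defined quantity for gapped alignments; for SAM/BAM input we use
the standard NM-based surrogate `(aligned read bases − NM) / aligned read
bases`, where the aligned read length is the CIGAR query-consuming aligned
span. A record without an NM tag is taken at identity 1. Secondary and
supplementary alignments are dropped before filtering so each sequenced
molecule contributes one 5′ end. Tabular input carries a precomputed
identity so the identity definition can be supplied by the caller.

## Expression and RLE normalization

Peak counts are sums of CTSS counts over the peak's bases on the peak's
strand; same-strand overlapping peaks are rejected because they would
double-count tags. Size factors follow the median-of-ratios definition:
for peaks with positive counts in every library, `s_j = median_i
(c_ij / geomean_k(c_ik))`, rescaled so `geomean_j(s_j) = 1`. TPM divides
each library's counts by its **effective library size** `s_j ·
geomean_k(N_k)` (N_k = total CTSS count of library k) and multiplies by
10⁶.

Using the common geometric-mean library size rather than each library's
own N_j is deliberate: the median-of-ratios factor already absorbs
sequencing depth, so dividing by `N_j · s_j` would correct depth twice.
With the effective-size form, multiplying any library's counts by a
constant leaves the TPM matrix exactly unchanged (the factor and the
geometric mean shift cancel), and exact replicate libraries at different
depths normalize to identical TPM columns. When every library has the
same total, the formula reduces to the familiar `counts / (N · s_j) ·
10⁶`.

The representative position of a peak is the base with the highest pooled
CTSS count; ties resolve to the 5′-most base on the peak's strand, and a
peak with no pooled signal falls back to its 5′ end with a flag.

## Genome segmentation and annotation hierarchy

Each transcript emits: a 1-bp TSS segment; a proximal promoter from
500 bp upstream of the TSS through 500 bp downstream, truncated at the 3′
end of the first exon; exon segments labeled first/inner/last along the
transcript; intron segments labeled the same way; and an antisense mirror
of every segment on the opposite strand. Exons are additionally split at
CDS boundaries into 5′ UTR / coding / 3′ UTR pieces (non-coding
transcripts are `noncoding`); this coding status is reported as a
secondary attribute and does not participate in precedence, which only
orders positional classes. A single-exon transcript's exon is
`exon_first`; a two-exon transcript has first and last, no inner.

A peak's primary label is the highest-precedence category among the
segments it overlaps (half-open, strand-matched — antisense segments
already carry the flipped strand, so one overlap rule serves both
senses): TSS > proximal promoter > exon first > inner > last > antisense
TSS > antisense promoter > antisense exon > sense intron > antisense
intron; within the lumped antisense-exon and intron classes,
first < inner < last makes the order total. Peaks overlapping nothing are
`intergenic`.

Gene association for naming uses the window from 500 bp upstream of the
gene's 5′ end through 500 bp downstream truncated at the first-exon 3′
end, on the gene's strand; the gene 5′ end is the 5′-most TSS over its
transcripts, and the first exon is taken from the transcript providing
that TSS. A peak overlapping several genes' windows goes to the gene with
the nearest 5′ end (tie: lexicographic symbol). Within a gene, ranks
follow descending pooled CTSS count, ties broken by genomic start and
then peak id, giving names `p1@GENE, p2@GENE, …`; unassociated peaks are
named positionally (`p@chrom:start..end,strand`). All tie-breaks are
deterministic, so naming is bit-stable across reruns.

Proximity annotation (CpG islands, TATA boxes, repeats, TFBS clusters)
extends each feature by a margin (default 300 bp) on both sides and tests
half-open overlap, ignoring strand.

## Motif scanning and statistics

Background base probabilities come from a GC fraction (default 0.409):
b(C)=b(G)=gc/2, b(A)=b(T)=(1−gc)/2. PWMs hold per-position probabilities;
matrices read from JASPAR count files get a per-cell pseudocount (default
0.01; zero is allowed, yielding −∞ log-ratios that simply cannot score).
Every window of the −300..+100 bp promoter sequence (relative to the
representative position, strand-aware, truncated and flagged at
chromosome ends) is scored on both strands; the minus-strand score uses
the reverse-complemented matrix over the same forward window. Windows
containing N are skipped, not imputed. The likelihood ratio converts to a
posterior via `π·LR/(π·LR + 1 − π)` with prior π = 5×10⁻⁴, and hits
require posterior strictly greater than 0.1 (at the boundary
LR = (1−π)/(9π) the posterior equals 0.1 exactly). Per-promoter TFBS
counts default to the sum of hit posteriors; a hit-count mode exists.

The activity test computes the Pearson correlation between per-promoter
counts and one sample's expression (raw by default; a log1p option
exists), then standardizes it against correlations from matrices whose
rows (motif positions) are permuted uniformly at random — 1,000
permutations by default, sample (n−1) standard deviation, one-sided
upper-tail normal p. If either vector is constant or the null SD is zero
(e.g. all motif rows identical), the result is flagged degenerate with
z = 0, p = 1 rather than NaN. The whole procedure is driven by a single
integer seed and is bit-reproducible.

The cluster test sums counts over cluster members and compares to
`Poisson(λ)` with λ = universe mean × cluster size. Posterior sums are
real-valued, so the observed value is ceiled before taking
`P(X ≥ ⌈obs⌉)`; the ceiling makes the test slightly conservative, and a
continuous alternative via the regularized incomplete gamma is exposed.
λ = 0 with zero observation gives p = 1.

Bulk rescanning for the permutation null runs through a compiled kernel
over pre-encoded sequences, with an early exit for windows that cannot
reach the posterior threshold; the single-sequence scanner is plain
vectorized numpy, and tests pin both to a naive per-offset product oracle
(agreement to better than 1e-12 relative) and to each other.

## Synthetic data

The generators emulate exactly the statistical structure the method
assumes: i.i.d. genome sequence at a target GC content; non-overlapping
genes with 1–5 exons on both strands, about half with a CDS; peaks mostly
within ±400 bp of TSSs; per-peak log-normal mean expression with negative
binomial counts (dispersion 0.1 — overdispersion stresses RLE) and
imposable per-library size factors, with tags spread over peak bases by a
geometric decay around a mode so representative positions are
informative. Motif planting writes a consensus (per-base mutation
probability 0.05) at uniform offsets into a chosen fraction of 400-bp
promoter sequences, either a fixed 1..k copies per planted promoter or as
a homogeneous Poisson site process; one sample's expression is linear in
copy number with Gaussian noise calibrated to a target correlation (0.8
in the verification runs).

What the generators do **not** emulate: sequencing error and mappability,
promoter shape classes, correlated co-expression structure, dinucleotide
composition, and real motif databases. Passing tests therefore
demonstrate the correctness and calibration of the computations, not
performance on real atlas data.

## Verification conditions and problem sizes

The end-to-end checks run at sizes chosen to be decisive yet quick on one
CPU: 100 random PWM/sequence pairs for scan–oracle agreement; 300
promoters, 30% planted, 1,000 permutations and 20 decoys for planted
recovery; 50 motifs at 200 permutations (expression independent of
sequence) for null calibration, judged by a Kolmogorov–Smirnov test at
α = 0.01; 500 promoters with a homogeneous planted site process
(mean 1 site/promoter) and 200 random clusters of 25 for the Poisson
test's type-I error; 1,000 random peaks against random transcript sets
for the annotation oracle and strand-mirror invariance; imposed factors (0.5, 1, 2)
over 600 reference peaks for RLE recovery, sized so the
median-of-ratios estimator's sampling error sits well inside the 5%
recovery tolerance. Under the row-permutation null the
standardized correlation is only approximately normal, and the Poisson
test is conservative by construction (ceiling, weight < 1 posteriors), so
its type-I fraction sits below the nominal 0.05; both behaviors are the
method's own, not artifacts.

## Known limitations

- The annotation hierarchy ranks the UTR/coding exon sub-split only as a
  secondary attribute; the positional order is declared, not derivable
  from first principles.
- Peak–gene association uses any overlap with the window, not
  containment.
- RLE is computed over all peaks positive in every library; a `subset`
  argument allows restricting to a robust subset, without asserting that
  choice as canonical.
- The scanner assumes an ACGTN alphabet and skips N-containing windows;
  IUPAC ambiguity codes are treated as N.
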