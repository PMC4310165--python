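"""PWM scanning with Bayesian posteriors and the two motif statistics.

Binding sites are predicted by scoring every window of a promoter sequence
(both strands) with a position-weight matrix against a GC-content
background.  The likelihood ratio

    LR(w) = prod_i f_i(b_i) / bg(b_i)

is converted to a posterior probability of a true site,

    posterior = prior * LR / (prior * LR + 1 - prior),

with a prior of 5e-4, and windows with posterior > 0.1 are retained as
predicted TFBSs.  Two statistics are built on the per-promoter TFBS counts
(sums of posteriors by default):

* **motif activity** — the Pearson correlation between per-promoter TFBS
  counts and one sample's expression, expressed as a Z-score against a
  null of matrices whose rows (motif positions) are randomly permuted;
* **Poisson overrepresentation** — the upper-tail probability of the TFBS
  count summed over a co-expression cluster, under a Poisson whose mean is
  the promoter-universe average times the cluster size.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, exp, log
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammainc

from .core import revcomp

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

DEFAULT_GC = 0.409
DEFAULT_PRIOR = 5e-4
DEFAULT_POSTERIOR_THRESHOLD = 0.1


@dataclass(frozen=True)
class BackgroundModel:
    """Single-nucleotide background defined by GC content.

    b(C) = b(G) = gc/2 and b(A) = b(T) = (1-gc)/2 (strand symmetric).
    """

    gc: float = DEFAULT_GC

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc {self.gc} outside (0, 1)")

    @property
    def probs(self) -> np.ndarray:
        """Base probabilities in A, C, G, T order."""
        at = (1.0 - self.gc) / 2.0
        cg = self.gc / 2.0
        return np.array([at, cg, cg, at])


def background_from_gc(gc: float) -> BackgroundModel:
    return BackgroundModel(gc=gc)


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix: rows are motif positions, columns A,C,G,T."""

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_counts(
        cls, motif_id: str, counts: np.ndarray, pseudocount: float = 0.01
    ) -> "Pwm":
        """Build from a position frequency matrix with a per-cell pseudocount."""
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(c.sum(axis=1) == 0) and pseudocount == 0:
            raise ValueError("all-zero PFM column with zero pseudocount")
        c = c + pseudocount
        return cls(motif_id, c / c.sum(axis=1, keepdims=True), pseudocount)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1], self.pseudocount)

    def log_ratio(self, bg: BackgroundModel) -> np.ndarray:
        """log(f_i(b)/bg(b)) table, shape (length, 4); -inf at zero cells."""
        with np.errstate(divide="ignore"):
            return np.log(self.matrix) - np.log(bg.probs)[None, :]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the TFBS prediction step."""

    prior: float = DEFAULT_PRIOR
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD
    window_up: int = 300
    window_down: int = 100
    count_mode: str = "posterior_sum"  # or "hit_count"
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must be in (0, 1)")
        if not 0.0 < self.posterior_threshold < 1.0:
            raise ValueError("posterior_threshold must be in (0, 1)")
        if self.count_mode not in ("posterior_sum", "hit_count"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass(frozen=True)
class TfbsHit:
    promoter_id: str
    motif_id: str
    offset: int
    strand: str
    lr: float
    posterior: float


def posterior_from_lr(lr: float, prior: float = DEFAULT_PRIOR) -> float:
    """Bayesian posterior of a true site given likelihood ratio ``lr``."""
    if lr < 0:
        raise ValueError("likelihood ratio must be non-negative")
    return prior * lr / (prior * lr + 1.0 - prior)


def lr_at_posterior(posterior: float, prior: float = DEFAULT_PRIOR) -> float:
    """Likelihood ratio at which the posterior equals ``posterior``."""
    return posterior * (1.0 - prior) / (prior * (1.0 - posterior))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; anything else (N) as 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)
        out[idx] = code
    return out


def _window_scores(codes: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """Log-LR of every window; windows containing N score -inf."""
    L = log_ratio.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (wins <= 3).all(axis=1)
    table = np.vstack([log_ratio.T, np.zeros((1, L))])  # row 4: placeholder for N
    scores = table[wins, np.arange(L)[None, :]].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan_promoter(
    pwm: Pwm,
    bg: BackgroundModel,
    sequence: str,
    params: ScanParams = ScanParams(),
    promoter_id: str = "",
) -> List[TfbsHit]:
    """Predict TFBSs in one sequence; hits have posterior strictly > threshold.

    Both strands are scanned unless ``params.both_strands`` is false; the
    minus-strand score at an offset is that of the reverse-complement
    matrix over the same forward-coordinate window. Windows containing N
    are skipped.
    """
    if len(sequence) < len(pwm):
        warnings.warn(
            f"sequence shorter than motif ({len(sequence)} < {len(pwm)}); no hits",
            stacklevel=2,
        )
        return []
    codes = encode_sequence(sequence)
    hits: List[TfbsHit] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if params.both_strands else [])
    for strand, mat in strands:
        scores = _window_scores(codes, mat.log_ratio(bg))
        with np.errstate(over="ignore"):
            lrs = np.exp(scores)
        posts = params.prior * lrs / (params.prior * lrs + 1.0 - params.prior)
        for offset in np.nonzero(posts > params.posterior_threshold)[0]:
            hits.append(
                TfbsHit(
                    promoter_id=promoter_id,
                    motif_id=pwm.motif_id,
                    offset=int(offset),
                    strand=strand,
                    lr=float(lrs[offset]),
                    posterior=float(posts[offset]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def tfbs_count(hits: Sequence[TfbsHit], mode: str = "posterior_sum") -> float:
    """Per-promoter TFBS count: sum of posteriors, or number of hits."""
    if mode == "posterior_sum":
        return float(sum(h.posterior for h in hits))
    if mode == "hit_count":
        return float(len(hits))
    raise ValueError(f"unknown count mode {mode!r}")


# ---------------------------------------------------------------------------
# Bulk scanning over a fixed promoter set (used by the permutation null).

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _bulk_kernel_py(codes, lengths, lr_fwd, lr_rev, log_cut, prior, thr, both):
    n, L = codes.shape[0], lr_fwd.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    n_tables = 2 if both else 1
    for p in range(n):
        seq_len = lengths[p]
        for o in range(seq_len - L + 1):
            window = codes[p, o : o + L]
            if (window > 3).any():
                continue
            for t in range(n_tables):
                table = lr_fwd if t == 0 else lr_rev
                s = float(table[np.arange(L), window].sum())
                if s > log_cut:
                    lr = exp(s)
                    post = prior * lr / (prior * lr + 1.0 - prior)
                    if post > thr:
                        sums[p] += post
                        counts[p] += 1
    return sums, counts


if _HAVE_NUMBA:

    @njit(cache=False)
    def _bulk_kernel(codes, lengths, lr_fwd, lr_rev, log_cut, prior, thr, both):  # pragma: no cover
        n = codes.shape[0]
        L = lr_fwd.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        n_tables = 2 if both else 1
        for p in range(n):
            seq_len = lengths[p]
            for o in range(seq_len - L + 1):
                ok = True
                for i in range(L):
                    if codes[p, o + i] > 3:
                        ok = False
                        break
                if not ok:
                    continue
                for t in range(n_tables):
                    s = 0.0
                    if t == 0:
                        for i in range(L):
                            s += lr_fwd[i, codes[p, o + i]]
                    else:
                        for i in range(L):
                            s += lr_rev[i, codes[p, o + i]]
                    if s > log_cut:
                        lr = exp(s)
                        post = prior * lr / (prior * lr + 1.0 - prior)
                        if post > thr:
                            sums[p] += post
                            counts[p] += 1.0
        return sums, counts

else:  # pragma: no cover
    _bulk_kernel = _bulk_kernel_py


class PromoterScanSet:
    """A fixed set of promoter sequences pre-encoded for repeated scanning.

    The permutation null rescans the same promoters thousands of times
    with row-permuted matrices; pre-encoding the sequences once makes
    that loop cheap.
    """

    def __init__(self, promoter_ids: Sequence[str], sequences: Sequence[str]):
        if len(promoter_ids) != len(sequences):
            raise ValueError("ids and sequences length mismatch")
        self.promoter_ids = list(promoter_ids)
        self.lengths = np.array([len(s) for s in sequences], dtype=np.int64)
        maxlen = int(self.lengths.max()) if len(sequences) else 0
        self.codes = np.full((len(sequences), maxlen), 4, dtype=np.int8)
        for i, seq in enumerate(sequences):
            self.codes[i, : len(seq)] = encode_sequence(seq)

    def __len__(self) -> int:
        return len(self.promoter_ids)

    def tfbs_counts(
        self, pwm: Pwm, bg: BackgroundModel, params: ScanParams = ScanParams()
    ) -> np.ndarray:
        """Per-promoter TFBS count (params.count_mode) for one matrix."""
        lr_fwd = np.ascontiguousarray(pwm.log_ratio(bg))
        lr_rev = np.ascontiguousarray(pwm.reverse_complement().log_ratio(bg))
        # Only windows that can clear the posterior threshold need exp().
        log_cut = log(lr_at_posterior(params.posterior_threshold, params.prior)) - 1e-9
        sums, counts = _bulk_kernel(
            self.codes,
            self.lengths,
            lr_fwd,
            lr_rev,
            log_cut,
            params.prior,
            params.posterior_threshold,
            params.both_strands,
        )
        return sums if params.count_mode == "posterior_sum" else counts


# ---------------------------------------------------------------------------
# Promoter windows around representative positions.


@dataclass(frozen=True)
class PromoterWindow:
    promoter_id: str
    sequence: str
    truncated: bool


def promoter_windows(
    peaks: Sequence,
    genome,
    params: ScanParams = ScanParams(),
) -> List[PromoterWindow]:
    """Extract the scanning window around each peak's representative position.

    On the + strand the window is [rep - window_up, rep + window_down);
    on the - strand the mirror image [rep - window_down + 1,
    rep + window_up + 1), reverse complemented, so that the returned
    sequence always reads 5'->3' relative to the promoter.  Windows are
    truncated at chromosome ends and flagged.
    """
    windows = []
    for peak in peaks:
        rep = peak.representative_position
        if rep is None:
            raise ValueError(f"peak {peak.id}: representative position not set")
        iv = peak.interval
        chrom_seq = genome[iv.chrom]
        chrom_len = len(chrom_seq)
        if iv.strand == "-":
            lo, hi = rep - params.window_down + 1, rep + params.window_up + 1
        else:
            lo, hi = rep - params.window_up, rep + params.window_down
        truncated = lo < 0 or hi > chrom_len
        lo, hi = max(0, lo), min(chrom_len, hi)
        seq = str(chrom_seq[lo:hi])
        if iv.strand == "-":
            seq = revcomp(seq)
        windows.append(PromoterWindow(peak.id, seq, truncated))
    return windows


# ---------------------------------------------------------------------------
# Motif activity: correlation vs a row-permutation null.


@dataclass
class MotifActivityResult:
    motif_id: str
    sample_id: str
    r_obs: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_randomizations: int
    degenerate: bool = False


def pearson_or_degenerate(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson r, with constant-vector inputs flagged and scored r=0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch between counts and expression")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def motif_activity(counts: np.ndarray, expression: np.ndarray) -> float:
    """Pearson correlation of per-promoter TFBS counts with expression."""
    if len(np.asarray(counts)) < 3:
        raise ValueError("need at least 3 promoters")
    r, _ = pearson_or_degenerate(counts, expression)
    return r


def permute_pwm_rows(pwm: Pwm, seed=None) -> Pwm:
    """Permute motif positions (matrix rows) uniformly at random."""
    if len(pwm) < 2:
        raise ValueError("permutation degenerate for motif length 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(pwm))
    return Pwm(pwm.motif_id, pwm.matrix[perm], pwm.pseudocount)


def activity_zscore(
    pwm: Pwm,
    bg: BackgroundModel,
    promoters: PromoterScanSet,
    expression: np.ndarray,
    params: ScanParams = ScanParams(),
    n_rand: int = 1000,
    seed: int = 0,
    sample_id: str = "",
    log_expression: bool = False,
) -> MotifActivityResult:
    """Motif activity Z-score for one motif in one sample.

    The observed correlation between per-promoter TFBS counts and
    expression is standardized by the mean and sample (n-1) standard
    deviation of the correlations obtained from ``n_rand`` row-permuted
    matrices; p is the upper-tail normal probability of the Z-score.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    expr = np.asarray(expression, dtype=float)
    if log_expression:
        expr = np.log1p(expr)
    counts_obs = promoters.tfbs_counts(pwm, bg, params)
    r_obs, degen_obs = pearson_or_degenerate(counts_obs, expr)

    rng = np.random.default_rng(seed)
    r_rand = np.empty(n_rand)
    for k in range(n_rand):
        permuted = permute_pwm_rows(pwm, rng)
        counts_k = promoters.tfbs_counts(permuted, bg, params)
        r_rand[k], _ = pearson_or_degenerate(counts_k, expr)

    null_mean = float(r_rand.mean())
    null_sd = float(r_rand.std(ddof=1))
    if null_sd == 0.0 or degen_obs:
        return MotifActivityResult(
            pwm.motif_id, sample_id, r_obs, null_mean, null_sd,
            z=0.0, p=1.0, n_randomizations=n_rand, degenerate=True,
        )
    z = (r_obs - null_mean) / null_sd
    p = float(stats.norm.sf(z))
    return MotifActivityResult(
        pwm.motif_id, sample_id, r_obs, null_mean, null_sd,
        z=float(z), p=p, n_randomizations=n_rand,
    )


# ---------------------------------------------------------------------------
# Poisson overrepresentation in co-expression clusters.


@dataclass(frozen=True)
class CoexpressionCluster:
    cluster_id: str
    members: tuple

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    cluster_id: str
    observed: float
    expected: float
    p: float


def poisson_enrichment(
    per_promoter_counts: Dict[str, float],
    cluster: CoexpressionCluster,
    motif_id: str = "",
    continuous: bool = False,
) -> MotifEnrichmentResult:
    """Poisson upper-tail test for motif overrepresentation in a cluster.

    The expected count lambda is the mean per-promoter TFBS count over the
    whole promoter universe times the cluster size; the observed count is
    the sum over cluster members.  p = P(X >= ceil(observed)) under
    Poisson(lambda); with ``continuous=True`` the regularized lower
    incomplete gamma P(observed, lambda) is used instead of the ceiling.
    """
    if not per_promoter_counts:
        raise ValueError("empty promoter universe")
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    missing = [m for m in cluster.members if m not in per_promoter_counts]
    if missing:
        raise ValueError(f"cluster members outside promoter universe: {missing[:3]}")
    lam = float(np.mean(list(per_promoter_counts.values()))) * len(cluster)
    observed = float(sum(per_promoter_counts[m] for m in cluster.members))
    if observed <= 0.0:
        p = 1.0
    elif continuous:
        # P(X >= x) for real x via the regularized incomplete gamma.
        p = float(gammainc(observed, lam)) if lam > 0 else 0.0
    else:
        k = ceil(observed)
        # P(X >= k) = gammainc(k, lam) = poisson.sf(k-1, lam)
        p = float(stats.poisson.sf(k - 1, lam)) if lam > 0 else 0.0
    p = min(max(p, 0.0), 1.0)
    if lam == 0.0 and observed == 0.0:
        p = 1.0
    return MotifEnrichmentResult(motif_id, cluster.cluster_id, observed, lam, p)
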