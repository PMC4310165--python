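import numpy as np
import pytest
from scipy import stats

from cagekit.expression import CagePeak
from cagekit.core import GenomicInterval
from cagekit.fixtures import consensus_pwm, random_pwm, synth_promoter_sequences
from cagekit.motif_stats import (
    BackgroundModel,
    CoexpressionCluster,
    PromoterScanSet,
    Pwm,
    ScanParams,
    activity_zscore,
    background_from_gc,
    lr_at_posterior,
    motif_activity,
    permute_pwm_rows,
    poisson_enrichment,
    posterior_from_lr,
    promoter_windows,
    scan_promoter,
    tfbs_count,
)
from .oracles import naive_scan


class TestBackground:
    def test_default_gc(self):
        bg = background_from_gc(0.409)
        np.testing.assert_allclose(bg.probs, [0.2955, 0.2045, 0.2045, 0.2955])
        assert bg.probs.sum() == pytest.approx(1.0)

    def test_uniform_at_half(self):
        np.testing.assert_allclose(background_from_gc(0.5).probs, 0.25)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_boundaries_rejected(self, gc):
        with pytest.raises(ValueError):
            background_from_gc(gc)


class TestPosterior:
    def test_lr_one_returns_prior(self):
        assert posterior_from_lr(1.0, 5e-4) == pytest.approx(5e-4, rel=1e-12)

    def test_boundary_lr_maps_to_threshold_exactly(self):
        prior = 5e-4
        lr = (1 - prior) / (9 * prior)
        assert posterior_from_lr(lr, prior) == pytest.approx(0.1, abs=1e-12)
        assert lr_at_posterior(0.1, prior) == pytest.approx(lr, rel=1e-12)

    def test_monotone_and_saturating(self):
        lrs = np.logspace(-3, 9, 50)
        posts = [posterior_from_lr(l) for l in lrs]
        assert all(a < b for a, b in zip(posts, posts[1:]))
        assert posterior_from_lr(1e18) == pytest.approx(1.0)


class TestScan:
    def test_uniform_pwm_never_hits(self):
        pwm = Pwm("u", np.full((8, 4), 0.25))
        hits = scan_promoter(pwm, background_from_gc(0.5), "ACGT" * 50)
        assert hits == []

    def test_consensus_found_once(self):
        rng = np.random.default_rng(7)
        pwm = consensus_pwm("ACGTACGA", "m")
        seq = synth_promoter_sequences(1, 400, 0.409, rng)[0]
        seq = seq[:100] + "ACGTACGA" + seq[108:]
        bg = BackgroundModel()
        hits = scan_promoter(pwm, bg, seq, ScanParams())
        exact = [h for h in hits if h.offset == 100 and h.strand == "+"]
        assert len(exact) == 1
        assert exact[0].posterior > 0.9

    def test_palindrome_hits_both_strands(self):
        pwm = consensus_pwm("ACGCGT", "pal")  # reverse complement of itself
        seq = "T" * 50 + "ACGCGT" + "T" * 50
        hits = scan_promoter(pwm, BackgroundModel(), seq)
        at = [(h.offset, h.strand) for h in hits]
        assert (50, "+") in at and (50, "-") in at

    def test_window_with_n_skipped(self):
        pwm = consensus_pwm("ACGTAC", "m")
        seq = "TTTTTACGNACTTTTT" + "ACGTAC" + "TTTT"
        hits = scan_promoter(pwm, BackgroundModel(), seq)
        assert all("N" not in seq[h.offset : h.offset + 6] for h in hits)

    def test_short_sequence_warns_and_returns_empty(self):
        pwm = consensus_pwm("ACGTACGT", "m")
        with pytest.warns(UserWarning, match="shorter than motif"):
            assert scan_promoter(pwm, BackgroundModel(), "ACGT") == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(5, 12))
        pwm = random_pwm(length, rng, alpha=0.2)
        seq = synth_promoter_sequences(1, 400, 0.409, rng)[0]
        if seed % 3 == 0:  # sprinkle Ns
            pos = rng.integers(0, 400, size=5)
            seq = "".join("N" if i in pos else c for i, c in enumerate(seq))
        params = ScanParams(posterior_threshold=0.001)  # catch more hits
        bg = BackgroundModel()
        ours = [(h.offset, h.strand, h.lr) for h in scan_promoter(pwm, bg, seq, params)]
        ref = naive_scan(pwm.matrix, bg.probs, seq, params.prior,
                         params.posterior_threshold)
        assert [(o, s) for o, s, *_ in ours] == [(o, s) for o, s, *_ in ref]
        for (_, _, lr_a), (_, _, lr_b, _) in zip(ours, ref):
            assert lr_a == pytest.approx(lr_b, rel=1e-12)

    def test_bulk_scanset_consistent_with_scan_promoter(self):
        rng = np.random.default_rng(3)
        seqs = synth_promoter_sequences(25, 400, 0.409, rng)
        pwm = random_pwm(8, rng, alpha=0.2)
        bg = BackgroundModel()
        params = ScanParams(posterior_threshold=0.01)
        ss = PromoterScanSet([f"p{i}" for i in range(25)], seqs)
        bulk_sums = ss.tfbs_counts(pwm, bg, params)
        for i, seq in enumerate(seqs):
            hits = scan_promoter(pwm, bg, seq, params)
            assert bulk_sums[i] == pytest.approx(tfbs_count(hits), rel=1e-9, abs=1e-12)


class TestPromoterWindows:
    def _peak(self, rep, strand="+"):
        return CagePeak(GenomicInterval("chr1", rep - 2, rep + 3, strand), id="pk",
                        representative_position=rep)

    def test_plus_window(self):
        genome = {"chr1": "A" * 700 + "C" * 300 + "G" * 1000}
        (win,) = promoter_windows([self._peak(1000)], genome)
        assert len(win.sequence) == 400
        assert win.sequence == "A" * 0 + "C" * 300 + "G" * 100
        assert not win.truncated

    def test_minus_window_is_reverse_complement(self):
        genome = {"chr1": "A" * 901 + "C" * 400 + "G" * 1000}
        (win,) = promoter_windows([self._peak(1000, "-")], genome)
        # genomic [901, 1301) = C*400, revcomp = G*400
        assert win.sequence == "G" * 400

    def test_truncation_at_chromosome_start(self):
        genome = {"chr1": "A" * 2000}
        (win,) = promoter_windows([self._peak(100)], genome)
        assert win.truncated and len(win.sequence) == 200


class TestActivity:
    def test_perfect_correlations(self):
        assert motif_activity([0, 1, 2, 3], [0, 1, 2, 3]) == pytest.approx(1.0)
        assert motif_activity([0, 1, 2, 3], [3, 2, 1, 0]) == pytest.approx(-1.0)

    def test_constant_vector_degenerate(self):
        assert motif_activity([0, 1, 2, 3], [5, 5, 5, 5]) == 0.0

    def test_permutation_preserves_rows_and_is_seeded(self):
        rng = np.random.default_rng(0)
        pwm = random_pwm(9, rng)
        p1 = permute_pwm_rows(pwm, seed=42)
        p2 = permute_pwm_rows(pwm, seed=42)
        assert (p1.matrix == p2.matrix).all()
        ours = {tuple(r) for r in p1.matrix}
        assert ours == {tuple(r) for r in pwm.matrix}
        with pytest.raises(ValueError, match="degenerate"):
            permute_pwm_rows(Pwm("one", [[0.25, 0.25, 0.25, 0.25]]))

    def test_zscore_arithmetic_and_normal_tail(self):
        # frozen example: null mean 0.1, sd 0.2, observed 0.5 -> z=2, p~0.02275
        z = (0.5 - 0.1) / 0.2
        assert z == 2.0
        assert stats.norm.sf(z) == pytest.approx(0.0227501, rel=1e-5)

    def test_identical_rows_pwm_degenerate(self):
        rng = np.random.default_rng(5)
        seqs = synth_promoter_sequences(30, 200, 0.409, rng)
        ss = PromoterScanSet([f"p{i}" for i in range(30)], seqs)
        pwm = Pwm("flat", np.tile([[0.7, 0.1, 0.1, 0.1]], (6, 1)))
        expr = rng.normal(size=30)
        res = activity_zscore(pwm, BackgroundModel(), ss, expr, n_rand=20, seed=1)
        assert res.degenerate and res.z == 0.0 and res.p == 1.0

    def test_seeded_runs_bit_identical(self):
        rng = np.random.default_rng(11)
        seqs = synth_promoter_sequences(40, 300, 0.409, rng)
        ss = PromoterScanSet([f"p{i}" for i in range(40)], seqs)
        pwm = random_pwm(7, rng, alpha=0.2)
        expr = rng.normal(size=40)
        a = activity_zscore(pwm, BackgroundModel(), ss, expr, n_rand=30, seed=9)
        b = activity_zscore(pwm, BackgroundModel(), ss, expr, n_rand=30, seed=9)
        assert (a.r_obs, a.null_mean, a.null_sd, a.z, a.p) == \
            (b.r_obs, b.null_mean, b.null_sd, b.z, b.p)

    def test_n_rand_lower_bound(self):
        ss = PromoterScanSet(["a", "b", "c"], ["ACGTACGT"] * 3)
        pwm = consensus_pwm("ACGT", "m")
        with pytest.raises(ValueError, match="n_rand"):
            activity_zscore(pwm, BackgroundModel(), ss, [1, 2, 3], n_rand=1, seed=0)


class TestPoissonEnrichment:
    def test_lambda_two_observed_two(self):
        counts = {f"p{i}": 0.0 for i in range(100)}
        counts["p0"], counts["p1"] = 1.0, 1.0
        # universe mean = 0.02 -> cluster of 100 would have lam 2; build directly
        cluster = CoexpressionCluster("c", tuple(counts))
        res = poisson_enrichment(counts, cluster)
        assert res.expected == pytest.approx(2.0)
        assert res.observed == pytest.approx(2.0)
        assert res.p == pytest.approx(1 - 3 * np.exp(-2), rel=1e-12)

    def test_unit_counts_cluster_of_five(self):
        counts = {f"p{i}": 1.0 for i in range(100)}
        cluster = CoexpressionCluster("c", tuple(f"p{i}" for i in range(5)))
        res = poisson_enrichment(counts, cluster)
        assert res.expected == pytest.approx(5.0)
        # P(X >= 5 | lam=5) by direct mass summation
        from math import factorial

        direct = 1.0 - sum(np.exp(-5) * 5.0**k / factorial(k) for k in range(5))
        assert res.p == pytest.approx(direct, rel=1e-10)
        assert res.p == pytest.approx(0.55951, abs=5e-6)

    def test_zero_lambda_zero_observed(self):
        counts = {f"p{i}": 0.0 for i in range(10)}
        res = poisson_enrichment(counts, CoexpressionCluster("c", ("p0", "p1")))
        assert res.p == 1.0

    def test_non_integer_observed_uses_ceiling(self):
        counts = {"a": 1.3, "b": 1.2, "c": 0.0, "d": 0.5}
        cluster = CoexpressionCluster("c", ("a", "b"))
        res = poisson_enrichment(counts, cluster)
        lam = np.mean([1.3, 1.2, 0.0, 0.5]) * 2
        assert res.p == pytest.approx(float(stats.poisson.sf(2, lam)), rel=1e-12)
        cont = poisson_enrichment(counts, cluster, continuous=True)
        # ceiling is the conservative-smaller tail: P(X>=3) < P(X>=2.5)
        assert 0 < res.p < cont.p

    def test_empty_cluster_and_foreign_members_rejected(self):
        counts = {"a": 1.0}
        with pytest.raises(ValueError, match="empty cluster"):
            poisson_enrichment(counts, CoexpressionCluster("c", ()))
        with pytest.raises(ValueError, match="outside promoter universe"):
            poisson_enrichment(counts, CoexpressionCluster("c", ("zzz",)))
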