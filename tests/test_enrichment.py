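"""Enrichment statistics against closed-form and brute-force oracles."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import special

from duoreg.core_io import GeneAnnotation, GenomicInterval
from duoreg.enrichment import (EnrichmentCurve, ParameterError, default_grid,
                               filter_above_median, genes_within,
                               hypergeom_right_tail, pair_distance_counts,
                               poisson_enrichment, proximity_enrichment_scan,
                               randomised_background, tss_region_distances)
from duoreg.motifs import MotifHit


def hit(rid, off, name="A", score=float("nan")):
    return MotifHit(rid, off, "+", 0, score, "T", name)


class TestFilterAboveMedian:
    def test_strict_median_boundary(self):
        hits = [hit("r", i, score=s) for i, s in enumerate([1.0, 2.0, 3.0])]
        kept = filter_above_median(hits)
        assert [h.score for h in kept] == [3.0]

    def test_all_equal_scores_empty(self):
        assert filter_above_median([hit("r", i, score=2.0) for i in range(5)]) == []

    def test_empty_input(self):
        assert filter_above_median([]) == []

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(0)
        hits = [hit("r", i, score=float(s)) for i, s in enumerate(rng.normal(size=101))]
        med = float(np.median([h.score for h in hits]))
        expect = {h.offset for h in hits if h.score > med}
        assert {h.offset for h in filter_above_median(hits)} == expect


class TestPairDistances:
    LEN = {"A": 9, "B": 15}

    def test_centre_rule_hand_computation(self):
        ha = {"r": [hit("r", 10, "A")]}
        hb = {"r": [hit("r", 60, "B")]}
        # centres: 10 + 4 = 14 and 60 + 7 = 67 -> distance 53 -> bin 5
        h = pair_distance_counts(ha, hb, self.LEN, bin_width=10, max_distance=500)
        assert h[53 // 10] == 1 and h.sum() == 1

    def test_self_pairs_excluded_when_same_collection(self):
        ha = {"r": [hit("r", 10, "A")]}
        h = pair_distance_counts(ha, ha, self.LEN, bin_width=10)
        assert h.sum() == 0

    def test_distinct_overlapping_hits_counted(self):
        ha = {"r": [hit("r", 10, "A"), hit("r", 12, "A")]}
        h = pair_distance_counts(ha, ha, self.LEN, bin_width=10)
        assert h.sum() == 2  # both ordered pairs at distance 2

    def test_cross_region_pairs_never_counted(self):
        ha = {"r1": [hit("r1", 0, "A")]}
        hb = {"r2": [hit("r2", 0, "B")]}
        assert pair_distance_counts(ha, hb, self.LEN).sum() == 0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(1)
        ha, hb = {}, {}
        for r in range(50):
            rid = f"r{r}"
            ha[rid] = [hit(rid, int(o), "A") for o in rng.integers(0, 390, rng.integers(0, 4))]
            hb[rid] = [hit(rid, int(o), "B") for o in rng.integers(0, 380, rng.integers(0, 4))]
        got = pair_distance_counts(ha, hb, self.LEN, bin_width=10, max_distance=500)
        expect = np.zeros(50, int)
        for rid in ha:
            for a in ha[rid]:
                for b in hb[rid]:
                    d = abs((a.offset + 4) - (b.offset + 7))
                    if d < 500:
                        expect[d // 10] += 1
        np.testing.assert_array_equal(got, expect)


class TestRandomisedBackground:
    LEN = {"A": 9, "B": 15}

    def _regions(self, n, length=400):
        return [GenomicInterval("chr1", i * 1000, i * 1000 + length, f"r{i}")
                for i in range(n)]

    def test_reproducible_given_seed(self):
        regions = self._regions(20)
        ha = {f"r{i}": [hit(f"r{i}", 5, "A")] for i in range(20)}
        hb = {f"r{i}": [hit(f"r{i}", 100, "B")] for i in range(20)}
        e1 = randomised_background(ha, hb, regions, self.LEN, n_shuffles=1, seed=9)
        e2 = randomised_background(ha, hb, regions, self.LEN, n_shuffles=1, seed=9)
        np.testing.assert_array_equal(e1, e2)

    def test_total_pair_count_conserved(self):
        rng = np.random.default_rng(2)
        regions = self._regions(30)
        ha = {f"r{i}": [hit(f"r{i}", int(o), "A") for o in rng.integers(0, 390, 2)]
              for i in range(30)}
        hb = {f"r{i}": [hit(f"r{i}", int(o), "B") for o in rng.integers(0, 380, 3)]
              for i in range(30)}
        obs = pair_distance_counts(ha, hb, self.LEN, bin_width=10, max_distance=500)
        exp = randomised_background(ha, hb, regions, self.LEN, n_shuffles=5,
                                    seed=0, bin_width=10, max_distance=500)
        # regions are 400 bp, so no distance exceeds the 500 bp histogram
        assert exp.sum() == pytest.approx(obs.sum())

    def test_short_region_hits_skipped(self):
        regions = [GenomicInterval("chr1", 0, 10, "tiny")]
        ha = {"tiny": [hit("tiny", 0, "B")]}  # 15-mer cannot fit in 10 bp
        exp = randomised_background(ha, ha, regions, self.LEN, n_shuffles=2, seed=0)
        assert exp.sum() == 0


class TestPoissonTail:
    def test_observed_zero_gives_one(self):
        c = poisson_enrichment(np.array([0]), np.array([3.7]))
        assert c.pvalue[0] == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        # oracle 1: regularised incomplete-gamma identity P(X>=k) = gammainc(k, lam)
        # oracle 2: direct summation of pmf terms in log space
        for lam in (0.1, 1.0, 5.0, 50.0):
            obs = np.arange(0, 201)
            c = poisson_enrichment(obs, np.full_like(obs, lam, dtype=float))
            expect = np.where(obs == 0, 1.0, special.gammainc(np.maximum(obs, 1), lam))
            np.testing.assert_allclose(c.pvalue, expect, rtol=1e-10)
            for k in (0, 1, 3, 10, 60, 200):
                i = np.arange(k, max(4 * int(lam) + 20 * k, 400) + 1)
                logpmf = -lam + i * np.log(lam) - special.gammaln(i + 1)
                direct = np.exp(special.logsumexp(logpmf))
                assert c.pvalue[k] == pytest.approx(direct, rel=1e-10)

    def test_monotone_in_observed(self):
        c = poisson_enrichment(np.arange(30), np.full(30, 4.0))
        assert (np.diff(c.pvalue) <= 1e-15).all()

    def test_degenerate_zero_expected(self):
        c = poisson_enrichment(np.array([0, 3]), np.array([0.0, 0.0]))
        assert c.pvalue[0] == 1.0 and c.pvalue[1] == 0.0
        assert c.meta["degenerate_bins"] == 1

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            poisson_enrichment(np.array([-1]), np.array([1.0]))


class TestGenesWithin:
    def _genes(self):
        return [GeneAnnotation("inside", "chr1", 150),
                GeneAnnotation("edge", "chr1", 250),
                GeneAnnotation("far", "chr1", 5000),
                GeneAnnotation("otherchrom", "chr2", 150)]

    def test_boundary_semantics(self):
        regions = [GenomicInterval("chr1", 100, 200, "r")]
        got = {g.gene_id for g in genes_within(self._genes(), regions, 0)}
        assert got == {"inside"}
        # TSS 250 is 51 bp from the last covered base (199)
        got = {g.gene_id for g in genes_within(self._genes(), regions, 51)}
        assert got == {"inside", "edge"}
        got = {g.gene_id for g in genes_within(self._genes(), regions, 50)}
        assert got == {"inside"}

    def test_same_chromosome_required(self):
        regions = [GenomicInterval("chr1", 100, 200, "r")]
        assert "otherchrom" not in {g.gene_id for g in
                                    genes_within(self._genes(), regions, 10**9)}

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(3)
        genes = [GeneAnnotation(f"g{i}", f"chr{rng.integers(1, 3)}",
                                int(rng.integers(0, 100_000))) for i in range(200)]
        regions = [GenomicInterval(f"chr{rng.integers(1, 3)}", int(s), int(s) + 200,
                                   f"r{i}")
                   for i, s in enumerate(rng.integers(0, 99_000, 50))]
        d = tss_region_distances(genes, regions)
        for i, g in enumerate(genes):
            brute = np.inf
            for r in regions:
                if r.chrom != g.chrom:
                    continue
                if r.start <= g.tss < r.end:
                    brute = 0
                    break
                brute = min(brute, r.start - g.tss if g.tss < r.start
                            else g.tss - (r.end - 1))
            assert d[i] == brute


class TestProximityScan:
    def test_exact_enumeration_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)*C(5,0)/C(10,4) = 5/210
        genes = [GeneAnnotation(f"g{i}", "chr1", 10_000 * i + 5) for i in range(10)]
        regions = [GenomicInterval("chr1", 10_000 * i, 10_000 * i + 10, f"r{i}")
                   for i in range(5)]
        curve = proximity_enrichment_scan([f"g{i}" for i in range(4)], genes,
                                          regions, grid=np.array([0]))
        assert curve.pvalue[0] == pytest.approx(5 / 210)

    def test_saturation_gives_one(self):
        genes = [GeneAnnotation(f"g{i}", "chr1", 100 * i) for i in range(10)]
        regions = [GenomicInterval("chr1", 0, 10, "r")]
        curve = proximity_enrichment_scan(["g0", "g1"], genes, regions,
                                          grid=np.array([10**6]))
        assert curve.pvalue[0] == pytest.approx(1.0)

    def test_de_gene_outside_universe_rejected(self):
        genes = [GeneAnnotation("g0", "chr1", 0)]
        with pytest.raises(ParameterError):
            proximity_enrichment_scan(["missing"], genes,
                                      [GenomicInterval("chr1", 0, 10, "r")])

    def test_k_and_capture_monotone_in_x(self):
        rng = np.random.default_rng(4)
        genes = [GeneAnnotation(f"g{i}", "chr1", int(t))
                 for i, t in enumerate(rng.integers(0, 50_000, 100))]
        regions = [GenomicInterval("chr1", int(s), int(s) + 100, f"r{i}")
                   for i, s in enumerate(rng.integers(0, 49_000, 5))]
        curve = proximity_enrichment_scan([g.gene_id for g in genes[:20]], genes,
                                          regions, grid=default_grid(1, 1e5, 20))
        assert (np.diff(curve.observed) >= 0).all()
        assert (np.diff(curve.expected) >= -1e-12).all()

    def test_hypergeometric_matches_enumeration_small_n(self):
        """Exhaustive sweep N <= 12 against direct combinatorial enumeration."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(n + 1):
                        expect = sum(comb(K, j) * comb(N - K, n - j)
                                     for j in range(k, min(K, n) + 1)) / comb(N, n)
                        assert hypergeom_right_tail(N, K, n, k) == \
                            pytest.approx(expect, abs=1e-12)


def test_curve_arrays_must_align():
    with pytest.raises(ParameterError):
        EnrichmentCurve(np.arange(3), np.arange(2), np.arange(3),
                        np.ones(3), "poisson")
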