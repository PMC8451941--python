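"""Peak-set operations and the NB differential machinery."""

import numpy as np
import pandas as pd
import pytest

from duoreg.binding import (BindingMatrix, ParameterError, bh_adjust, de_filter,
                            differential_test, exclude_blacklist,
                            merge_peak_sets, normalise, reproducible_peaks,
                            size_factors, zscore_foldchanges)
from duoreg.core_io import GenomicInterval


def iv(chrom, s, e, name=None):
    return GenomicInterval(chrom, s, e, name or f"{chrom}:{s}-{e}")


class TestReproduciblePeaks:
    def test_identical_sets(self):
        sets = [[iv("chr1", 0, 100)]] * 3
        out = reproducible_peaks(sets, 3)
        assert [(r.start, r.end) for r in out] == [(0, 100)]

    def test_union_span_over_triple_core(self):
        sets = [[iv("chr1", 0, 100)], [iv("chr1", 50, 150)], [iv("chr1", 60, 90)]]
        out = reproducible_peaks(sets, 3)
        # core covered by all three is 60-90; reported span is the union
        # of the contributing replicate peaks
        assert [(r.start, r.end) for r in out] == [(0, 150)]

    def test_min_one_is_plain_union(self):
        sets = [[iv("chr1", 0, 100)], [iv("chr1", 50, 150)], [iv("chr2", 0, 10)]]
        out = reproducible_peaks(sets, 1)
        assert {(r.chrom, r.start, r.end) for r in out} == {("chr1", 0, 150),
                                                            ("chr2", 0, 10)}

    def test_monotone_in_min_replicates(self):
        rng = np.random.default_rng(0)
        sets = []
        for _ in range(4):
            starts = np.sort(rng.choice(5000, size=30, replace=False)) * 3
            sets.append([iv("chr1", int(s), int(s) + int(rng.integers(50, 200)))
                         for s in starts])
        prev = None
        for k in range(1, 5):
            out = reproducible_peaks(sets, k)
            if prev is not None:
                # raising min_replicates never adds covered ground: every
                # stricter-threshold region sits inside a looser-threshold one
                for r in out:
                    assert any(p.chrom == r.chrom and p.start <= r.start
                               and r.end <= p.end for p in prev)
            prev = out

    def test_sweep_matches_bruteforce_coverage(self):
        rng = np.random.default_rng(1)
        sets = [[iv("chr1", int(s), int(s) + 40)
                 for s in rng.integers(0, 2000, size=15)] for _ in range(3)]
        out = reproducible_peaks(sets, 2)
        # oracle: per-base coverage
        cov = np.zeros(3000, int)
        for s in sets:
            for r in s:
                cov[r.start:r.end] += 1
        covered = set(np.nonzero(cov >= 2)[0])
        got = set()
        for r in out:
            # every reported span must contain its >=2x core bases
            got |= set(range(r.start, r.end)) & covered
        assert got == covered

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            reproducible_peaks([], 1)


class TestMergePeakSets:
    def test_disjoint_one_hot(self):
        df = merge_peak_sets([[iv("chr1", 0, 10)], [iv("chr1", 50, 60)]],
                             ["E", "N"])
        assert len(df) == 2
        assert df.loc[0, ["E", "N"]].tolist() == [True, False]
        assert df.loc[1, ["E", "N"]].tolist() == [False, True]

    def test_overlap_merges_and_flags_both(self):
        df = merge_peak_sets([[iv("chr1", 0, 100)], [iv("chr1", 50, 150)]],
                             ["E", "N"])
        assert len(df) == 1
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (0, 150)
        assert df.loc[0, "E"] and df.loc[0, "N"]

    def test_venn_counts_match_bruteforce(self):
        rng = np.random.default_rng(2)
        a = [iv("chr1", int(s), int(s) + 30) for s in rng.integers(0, 5000, 50)]
        b = [iv("chr1", int(s), int(s) + 30) for s in rng.integers(0, 5000, 50)]
        df = merge_peak_sets([a, b], ["A", "B"])
        for row in df.itertuples(index=False):
            in_a = any(x.start < row.end and x.end > row.start for x in a)
            in_b = any(x.start < row.end and x.end > row.start for x in b)
            assert (row.A, row.B) == (in_a, in_b)


class TestBlacklist:
    def test_identity_with_empty_blacklist(self):
        regs = [iv("chr1", 0, 10)]
        assert exclude_blacklist(regs, []) == regs

    @pytest.mark.parametrize("bl,removed", [
        ((0, 100), True),     # fully inside
        ((9, 50), True),      # 1-bp overlap at the right edge
        ((10, 50), False),    # adjacent, no overlap
    ])
    def test_overlap_boundary(self, bl, removed):
        regs = [iv("chr1", 0, 10)]
        out = exclude_blacklist(regs, [iv("chr1", *bl)])
        assert (out == []) is removed


class TestNormalise:
    def _matrix(self):
        samples = pd.DataFrame({"sample_id": ["s1"], "tf": ["T"],
                                "condition": ["++"], "replicate": [1]})
        return BindingMatrix(["r1"], samples, np.array([[100.0]]),
                             np.array([1_000_000]))

    def test_scales(self):
        assert normalise(self._matrix(), "per-million").counts[0, 0] == 100.0
        assert normalise(self._matrix(), "per-ten-million").counts[0, 0] == 1000.0

    def test_double_normalise_guarded(self):
        m = normalise(self._matrix())
        with pytest.raises(ParameterError):
            normalise(m)


def _make_matrix(counts, conds):
    counts = np.asarray(counts, float)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(counts.shape[1])],
        "tf": "T", "condition": conds,
        "replicate": list(range(1, counts.shape[1] + 1))})
    return BindingMatrix([f"r{i}" for i in range(counts.shape[0])], samples,
                         counts, np.full(counts.shape[1], 1e7))


class TestDifferentialTest:
    def test_null_identity(self):
        counts = np.tile([100.0, 50.0, 200.0], (2, 1)).T.reshape(3, 2)
        counts = np.hstack([counts, counts])  # identical in both conditions
        m = _make_matrix(counts, ["++", "++", "-E", "-E"])
        res = differential_test(m, ("++", "-E"))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-9)
        assert (res["pvalue"] > 0.9).all()

    def test_all_zero_unit_flagged(self):
        counts = np.array([[0, 0, 0, 0], [100, 120, 90, 110]], float)
        m = _make_matrix(counts, ["++", "++", "-E", "-E"])
        res = differential_test(m, ("++", "-E"))
        assert res.loc[0, "log2fc"] == 0.0 and res.loc[0, "pvalue"] == 1.0
        assert bool(res.loc[0, "flagged"])

    def test_bh_closed_form(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_fdr_never_below_pvalue(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_recovers_planted_effect_direction(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(np.log(100), 0.3, 300)
        mu = np.outer(base, np.ones(6))
        mu[:100, 3:] *= 0.25  # first 100 units down 2 log2 in condition B
        counts = rng.negative_binomial(10, 10 / (10 + mu))
        m = _make_matrix(counts, ["++"] * 3 + ["-E"] * 3)
        # one-directional effect on a third of units: depth normalisation
        # (equal libraries here) avoids the median-of-ratios anchor problem
        res = differential_test(m, ("++", "-E"), normalisation="library")
        assert np.median(res["log2fc"][:100]) < -1.5
        assert (res.loc[:99, "call"] == "down").mean() > 0.8

    def test_single_replicate_flagged(self):
        counts = np.array([[100, 50], [80, 70], [20, 10], [200, 150]], float)
        m = _make_matrix(counts, ["++", "-E"])
        res = differential_test(m, ("++", "-E"))
        assert res["flagged"].all()


class TestSizeFactors:
    def test_geometric_mean_one(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(200, 4)).astype(float)
        sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_scaling_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=(500,)).astype(float) + 1
        counts = np.column_stack([base, base * 2, base * 4])
        sf = size_factors(counts)
        np.testing.assert_allclose(sf / sf[0], [1, 2, 4], rtol=1e-6)


class TestDeFilter:
    def _results(self, lfc, fdr, n):
        return pd.DataFrame({"unit_id": [f"u{i}" for i in range(n)],
                             "log2fc": lfc, "pvalue": fdr, "fdr": fdr,
                             "call": "ns"})

    def test_count_rule_any_condition(self):
        res = self._results([2.0], [1e-5], 1)
        raw = np.array([[19, 25, 25, 30, 30, 30]])
        masks = [np.array([1, 1, 1, 0, 0, 0], bool), np.array([0, 0, 0, 1, 1, 1], bool)]
        assert len(de_filter(res, raw, masks)) == 1  # passes via condition B
        raw2 = np.array([[19, 25, 25, 19, 30, 30]])
        assert len(de_filter(res, raw2, masks)) == 0

    def test_fc_boundary_strict(self):
        lfc = np.log2(1.5)
        res = self._results([lfc, lfc + 1e-6], [1e-5, 1e-5], 2)
        raw = np.full((2, 4), 50)
        masks = [np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool)]
        out = de_filter(res, raw, masks)
        assert list(out["unit_id"]) == ["u1"]

    def test_matches_bruteforce_on_synthetic_truth(self):
        rng = np.random.default_rng(6)
        n = 500
        lfc = rng.normal(0, 1.2, n)
        fdr = rng.uniform(0, 0.2, n)
        raw = rng.integers(0, 60, size=(n, 6))
        masks = [np.array([1, 1, 1, 0, 0, 0], bool),
                 np.array([0, 0, 0, 1, 1, 1], bool)]
        res = self._results(lfc, fdr, n)
        got = set(de_filter(res, raw, masks)["unit_id"])
        expect = set()
        for i in range(n):
            c_ok = all(raw[i, :3] >= 20) or all(raw[i, 3:] >= 20)
            if c_ok and 2 ** abs(lfc[i]) > 1.5 and fdr[i] < 0.01:
                expect.add(f"u{i}")
        assert got == expect


class TestZscore:
    def test_two_point_closed_form(self):
        np.testing.assert_allclose(zscore_foldchanges([-1.0, 1.0]),
                                   [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_location_invariance_and_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 3, 50)
        z1, z2 = zscore_foldchanges(x), zscore_foldchanges(x + 17.5)
        np.testing.assert_allclose(z1, z2, atol=1e-10)
        assert abs(z1.mean()) < 1e-12 and abs(z1.std(ddof=1) - 1) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            zscore_foldchanges([1.0, 1.0, 1.0])
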