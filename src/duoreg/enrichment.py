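"""Bespoke enrichment statistics.

Two analyses live here:

* **Motif-pair distance enrichment.** Within each bound region, the
  absolute centre-to-centre distances between all pairs of half-site and
  partner (Oct/Sox composite) motifs are histogrammed; the observation is
  compared against a randomised background in which hit positions are
  re-drawn uniformly within their own region, and a Poisson right-tail
  p-value is computed per distance bin. A short preferred spacing between
  the nuclear-receptor half-site and the Oct/Sox element signals
  positional cooperation.

* **Gene-peak proximity enrichment.** For a distance grid x over
  [1, 1e6] bp, the excess of differentially expressed genes whose TSS lies
  within x bp of a region class, relative to all genes within x bp, is
  scored with a hypergeometric right-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneAnnotation, GenomicInterval
from .motifs import MotifHit

P_FLOOR = 1e-300  # underflow clamp before -log10


class ParameterError(ValueError):
    pass


@dataclass
class EnrichmentCurve:
    """Observed/expected counts and right-tail p-values on an ordered grid."""

    grid: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    pvalue: np.ndarray
    kind: str  # 'poisson' or 'hypergeometric'
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.grid)
        if not (len(self.observed) == len(self.expected) == len(self.pvalue) == n):
            raise ParameterError("curve arrays must be aligned")

    @property
    def neglog10p(self) -> np.ndarray:
        return -np.log10(np.clip(self.pvalue, P_FLOOR, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid,
            "observed": self.observed,
            "expected": self.expected,
            "pvalue": self.pvalue,
            "neglog10p": self.neglog10p,
        })


# ---------------------------------------------------------------------------
# Motif-pair distance enrichment


def filter_above_median(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Keep hits scoring strictly above the median score of the hit set.

    With all-equal scores the result is empty (strict inequality); an
    empty input yields an empty output.
    """
    if not hits:
        return []
    scores = np.array([h.score for h in hits], float)
    med = np.median(scores)
    return [h for h, s in zip(hits, scores) if s > med]


def _centres(hits: Iterable[MotifHit], motif_lengths: Mapping[str, int]) -> np.ndarray:
    return np.array([h.offset + motif_lengths[h.motif_name] // 2 for h in hits], int)


def pair_distance_counts(hits_a: Mapping[str, Sequence[MotifHit]],
                         hits_b: Mapping[str, Sequence[MotifHit]],
                         motif_lengths: Mapping[str, int],
                         bin_width: int = 10, max_distance: int = 500) -> np.ndarray:
    """Histogram of absolute centre-to-centre distances of within-region
    motif pairs.

    The motif centre is offset + floor(length/2). Cross-region pairs are
    never counted. When the two hit collections are identical objects,
    self-pairs (a hit paired with itself) are excluded; distinct
    overlapping hits still count. Distances beyond ``max_distance`` are
    dropped.
    """
    if bin_width < 1:
        raise ParameterError("bin width must be >= 1")
    n_bins = int(np.ceil(max_distance / bin_width))
    hist = np.zeros(n_bins, dtype=int)
    same = hits_a is hits_b
    for rid, ha in hits_a.items():
        hb = hits_b.get(rid, ())
        if not ha or not hb:
            continue
        ca = _centres(ha, motif_lengths)
        cb = _centres(hb, motif_lengths)
        d = np.abs(ca[:, None] - cb[None, :])
        if same:
            mask = ~np.eye(len(ca), dtype=bool)
            d = d[mask]
        else:
            d = d.ravel()
        d = d[d < max_distance]
        if d.size:
            hist += np.bincount(d // bin_width, minlength=n_bins)[:n_bins]
    return hist


def randomised_background(hits_a: Mapping[str, Sequence[MotifHit]],
                          hits_b: Mapping[str, Sequence[MotifHit]],
                          regions: Sequence[GenomicInterval],
                          motif_lengths: Mapping[str, int],
                          n_shuffles: int = 100, seed: int = 0,
                          bin_width: int = 10, max_distance: int = 500) -> np.ndarray:
    """Expected pair-distance histogram under within-region repositioning.

    Each shuffle re-draws every hit's offset uniformly over the placements
    at which the motif fits inside its region, preserving per-region hit
    counts and strand labels; the expectation is the mean histogram over
    shuffles. Hits in regions shorter than their motif are skipped.
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    region_len = {iv.id: iv.length for iv in regions}
    n_bins = int(np.ceil(max_distance / bin_width))
    total = np.zeros(n_bins, dtype=float)
    same = hits_a is hits_b

    def shuffled(hits: Mapping[str, Sequence[MotifHit]]) -> dict[str, list[MotifHit]]:
        out: dict[str, list[MotifHit]] = {}
        for rid, hs in hits.items():
            length = region_len.get(rid)
            kept = []
            for h in hs:
                m = motif_lengths[h.motif_name]
                if length is None or length < m:
                    continue  # motif does not fit; skip with no contribution
                new_off = int(rng.integers(0, length - m + 1))
                kept.append(MotifHit(h.region_id, new_off, h.strand, h.mismatches,
                                     h.score, h.seventh_base, h.motif_name))
            out[rid] = kept
        return out

    for _ in range(n_shuffles):
        sa = shuffled(hits_a)
        sb = sa if same else shuffled(hits_b)
        total += pair_distance_counts(sa, sb, motif_lengths, bin_width, max_distance)
    return total / n_shuffles


def poisson_enrichment(observed: np.ndarray, expected: np.ndarray,
                       bin_width: int = 10, meta: dict | None = None) -> EnrichmentCurve:
    """Right-tail Poisson p-value per distance bin: P(X >= observed) with
    X ~ Poisson(expected).

    ``expected = 0`` with ``observed = 0`` gives p = 1; ``expected = 0``
    with ``observed > 0`` gives p = 0 and is flagged degenerate in meta.
    """
    observed = np.asarray(observed)
    expected = np.asarray(expected, float)
    if np.any(observed < 0) or np.any(expected < 0):
        raise ParameterError("observed and expected must be non-negative")
    if observed.shape != expected.shape:
        raise ParameterError("observed and expected must be aligned")
    p = stats.poisson.sf(observed - 1, expected)  # P(X >= obs)
    zero_zero = (expected == 0) & (observed == 0)
    degenerate = (expected == 0) & (observed > 0)
    p = np.where(zero_zero, 1.0, p)
    p = np.where(degenerate, 0.0, p)
    grid = np.arange(len(observed)) * bin_width
    m = dict(meta or {})
    m["degenerate_bins"] = int(degenerate.sum())
    m["p_floor"] = P_FLOOR
    return EnrichmentCurve(grid, observed, expected, p, "poisson", m)


def pair_distance_enrichment(hits_a, hits_b, regions, motif_lengths,
                             bin_width: int = 10, max_distance: int = 500,
                             n_shuffles: int = 100, seed: int = 0) -> EnrichmentCurve:
    """Observed vs randomised-background pair-distance Poisson curve."""
    obs = pair_distance_counts(hits_a, hits_b, motif_lengths, bin_width, max_distance)
    exp = randomised_background(hits_a, hits_b, regions, motif_lengths,
                                n_shuffles, seed, bin_width, max_distance)
    return poisson_enrichment(obs, exp, bin_width,
                              meta={"n_shuffles": n_shuffles, "seed": seed,
                                    "bin_width": bin_width})


# ---------------------------------------------------------------------------
# Gene-peak proximity enrichment


def tss_region_distances(genes: Sequence[GeneAnnotation],
                         regions: Sequence[GenomicInterval]) -> np.ndarray:
    """Minimum distance from each gene's TSS to any region of the set.

    Distance is 0 when the TSS lies inside a region; genes on
    chromosomes with no region get +inf. Vectorised per chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = np.full(len(genes), np.inf)
    chrom_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        chrom_cache[chrom] = (np.array([iv.start for iv in ivs]),
                              np.array([iv.end for iv in ivs]))
    for i, g in enumerate(genes):
        if g.chrom not in chrom_cache:
            continue
        starts, ends = chrom_cache[g.chrom]
        # distance to each interval: 0 if inside, else gap to nearest edge
        d = np.maximum.reduce([starts - g.tss, g.tss - (ends - 1), np.zeros(len(starts), int)])
        out[i] = d.min()
    return out


def genes_within(genes: Sequence[GeneAnnotation], regions: Sequence[GenomicInterval],
                 x: int) -> list[GeneAnnotation]:
    """Genes whose TSS lies within x bp (inclusive) of any region."""
    if x < 0:
        raise ParameterError("x must be >= 0")
    d = tss_region_distances(genes, regions)
    return [g for g, di in zip(genes, d) if di <= x]


def hypergeom_right_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def default_grid(lo: float = 1.0, hi: float = 1e6, n: int = 50) -> np.ndarray:
    """Log-spaced distance grid over [lo, hi] bp, rounded to integers."""
    return np.unique(np.round(np.logspace(np.log10(lo), np.log10(hi), n)).astype(int))


def proximity_enrichment_scan(de_genes: Sequence[str], all_genes: Sequence[GeneAnnotation],
                              cluster_regions: Sequence[GenomicInterval],
                              grid: np.ndarray | None = None) -> EnrichmentCurve:
    """Hypergeometric right-tail scan of DE-gene excess near a region set.

    At each distance x: N = number of genes in the universe, K = genes
    within x of the region set, n = DE genes, k = DE genes within x;
    p = P(X >= k | N, K, n). ``de_genes`` must be a subset of the
    universe's gene ids.
    """
    grid = default_grid() if grid is None else np.asarray(grid)
    universe_ids = [g.gene_id for g in all_genes]
    de_set = set(de_genes)
    missing = de_set - set(universe_ids)
    if missing:
        raise ParameterError(f"DE genes absent from universe: {sorted(missing)[:5]}")
    d = tss_region_distances(all_genes, cluster_regions)
    is_de = np.array([g in de_set for g in universe_ids])
    N, n = len(all_genes), int(is_de.sum())
    observed = np.zeros(len(grid), int)
    expected = np.zeros(len(grid), float)
    pvals = np.ones(len(grid), float)
    for i, x in enumerate(grid):
        within = d <= x
        K = int(within.sum())
        k = int((within & is_de).sum())
        observed[i] = k
        expected[i] = n * K / N if N else 0.0
        pvals[i] = hypergeom_right_tail(N, K, n, k)
    return EnrichmentCurve(grid, observed, expected, pvals, "hypergeometric",
                           {"N": N, "n": n, "p_floor": P_FLOOR})
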