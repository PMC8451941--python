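"""Peak-set logic and count statistics.

Covers replicate-reproducible peak calling output, per-TF peak merging with
provenance flags (the overlap Venn), blacklist exclusion, library-size
normalisation (reads per million / per ten million), a self-contained
negative-binomial Wald test for differential binding or expression with
Benjamini-Hochberg correction, and the raw-count / fold-change / FDR filter
used to call differentially expressed genes.

The differential test is a deliberately simple DESeq2-style stand-in:
median-of-ratios size factors, method-of-moments per-unit dispersion shrunk
toward a mean-dispersion trend, and a Wald test on the log2 fold change of
normalised condition means. It is exposed behind a ``method`` switch so a
different engine can be plugged in without changing downstream contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomicInterval, ValidationError

DISPERSION_FLOOR = 1e-8


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Interval set operations


def _sweep_runs(intervals: Sequence[GenomicInterval], min_cov: int):
    """Maximal runs of coverage >= min_cov per chromosome (plane sweep)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    runs: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        events: list[tuple[int, int]] = []
        for s, e in ivs:
            events.append((s, +1))
            events.append((e, -1))
        events.sort()
        cov = 0
        run_start = None
        chrom_runs = []
        for pos, delta in events:
            prev = cov
            cov += delta
            if prev < min_cov <= cov:
                run_start = pos
            elif prev >= min_cov > cov:
                chrom_runs.append((run_start, pos))
                run_start = None
        runs[chrom] = chrom_runs
    return runs


def reproducible_peaks(replicate_sets: Sequence[Sequence[GenomicInterval]],
                       min_replicates: int | None = None) -> list[GenomicInterval]:
    """Regions supported by at least ``min_replicates`` replicate peak sets.

    For each maximal genomic run where replicate coverage >= min_replicates,
    the reported interval is the union-span of all replicate peaks
    overlapping that run. ``min_replicates`` defaults to the number of
    replicate sets (a peak must be called in all replicates).
    """
    if not replicate_sets:
        raise ParameterError("need at least one replicate peak set")
    if min_replicates is None:
        min_replicates = len(replicate_sets)
    if not (1 <= min_replicates <= len(replicate_sets)):
        raise ParameterError("min_replicates must be in [1, n_sets]")
    flat = [iv for s in replicate_sets for iv in s]
    runs = _sweep_runs(flat, min_replicates)
    out: list[GenomicInterval] = []
    seen: set[tuple[str, int, int]] = set()
    for chrom in sorted(runs):
        chrom_ivs = sorted((iv.start, iv.end) for iv in flat if iv.chrom == chrom)
        starts = np.array([s for s, _ in chrom_ivs])
        ends = np.array([e for _, e in chrom_ivs])
        for rs, re_ in runs[chrom]:
            mask = (starts < re_) & (ends > rs)
            span = (chrom, int(starts[mask].min()), int(ends[mask].max()))
            if span not in seen:
                seen.add(span)
                out.append(GenomicInterval(span[0], span[1], span[2],
                                           f"{span[0]}:{span[1]}-{span[2]}"))
    return out


def merge_peak_sets(sets: Sequence[Sequence[GenomicInterval]],
                    set_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Merge overlapping peaks across sets into single regions, recording a
    bound/not flag per input set (the basis of the binding-overlap Venn).
    """
    if set_names is None:
        set_names = [f"set{i}" for i in range(len(sets))]
    flat = [iv for s in sets for iv in s]
    runs = _sweep_runs(flat, 1)
    rows = []
    for chrom in sorted(runs):
        for rs, re_ in runs[chrom]:
            row = {"chrom": chrom, "start": rs, "end": re_,
                   "id": f"{chrom}:{rs}-{re_}"}
            for name, s in zip(set_names, sets):
                row[name] = any(iv.chrom == chrom and iv.start < re_ and iv.end > rs
                                for iv in s)
            rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", *set_names])


def exclude_blacklist(regions: Sequence[GenomicInterval],
                      blacklist: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Drop any region overlapping any blacklist interval by >= 1 bp."""
    bl: dict[str, list[tuple[int, int]]] = {}
    for iv in blacklist:
        bl.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for r in regions:
        hits = bl.get(r.chrom, ())
        if not any(s < r.end and e > r.start for s, e in hits):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Binding matrix


@dataclass
class BindingMatrix:
    """Regions x samples count matrix with sample metadata.

    ``samples`` is a DataFrame with columns sample_id, tf, condition,
    replicate; ``counts`` has shape (n_regions, n_samples).
    """

    region_ids: list[str]
    samples: pd.DataFrame
    counts: np.ndarray
    library_sizes: np.ndarray
    normalised: bool = False
    scale: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.region_ids), len(self.samples)):
            raise ValidationError("counts shape does not match regions x samples")
        if np.any(self.library_sizes <= 0):
            raise ParameterError("library sizes must be positive")
        if not self.normalised and np.any(self.counts.sum(axis=0) > self.library_sizes):
            raise ValidationError("library sizes smaller than assigned counts")

    def select(self, mask: np.ndarray) -> "BindingMatrix":
        return replace(self, samples=self.samples.loc[mask].reset_index(drop=True),
                       counts=self.counts[:, np.asarray(mask)],
                       library_sizes=self.library_sizes[np.asarray(mask)])


_SCALES = {"per-million": 1e6, "per-ten-million": 1e7}


def normalise(matrix: BindingMatrix, scale: str = "per-million") -> BindingMatrix:
    """Library-size normalise counts to reads per (ten) million."""
    if matrix.normalised:
        raise ParameterError("matrix is already normalised")
    if scale not in _SCALES:
        raise ParameterError(f"scale must be one of {sorted(_SCALES)}")
    vals = matrix.counts / matrix.library_sizes[None, :] * _SCALES[scale]
    return replace(matrix, counts=vals, normalised=True, scale=scale)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors; total-count fallback when no row is
    positive in every sample."""
    counts = np.asarray(counts, float)
    pos = np.all(counts > 0, axis=1)
    if counts.shape[1] >= 2 and pos.sum() >= 1:
        logc = np.log(counts[pos])
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        tot = counts.sum(axis=0)
        if np.any(tot <= 0):
            return np.ones(counts.shape[1])
        sf = tot / np.exp(np.mean(np.log(tot)))
    return sf / np.exp(np.mean(np.log(sf)))


# ---------------------------------------------------------------------------
# Differential testing


@dataclass(frozen=True)
class DifferentialResult:
    unit_id: str
    log2fc: float
    pvalue: float
    fdr: float
    call: str  # up / down / ns
    flagged: bool = False


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = b0 + b1/mu by least squares on units with usable
    moment estimates, clipped to stay positive."""
    ok = (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        a = float(np.nanmedian(np.clip(alpha_mom[ok], DISPERSION_FLOOR, None))) \
            if ok.any() else 0.1
        return np.full_like(mu, max(a, DISPERSION_FLOOR))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    y = np.clip(alpha_mom[ok], 0.0, None)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    with np.errstate(divide="ignore"):
        tr = beta[0] + beta[1] / np.where(mu > 0, mu, np.nan)
    fallback = max(float(np.median(y)), DISPERSION_FLOOR)
    tr = np.where(np.isfinite(tr) & (tr > 0), tr, fallback)
    return np.clip(tr, DISPERSION_FLOOR, None)


def differential_test(matrix: BindingMatrix, contrast: tuple[str, str],
                      method: str = "nb_wald", shrink_weight: float = 0.5,
                      fdr_threshold: float = 0.05, lfc_pseudo: float = 0.5,
                      normalisation: str = "median_ratios") -> pd.DataFrame:
    """Negative-binomial Wald test of condition B vs condition A.

    Returns a DataFrame with unit_id, log2fc, pvalue, fdr, call, flagged.
    log2fc > 0 means higher in condition B. Units with zero counts in both
    conditions get log2fc 0 and p 1 and are flagged. With a single
    replicate per condition the per-unit dispersion cannot be estimated;
    the trended (pooled) dispersion is used alone and results are flagged.

    ``normalisation`` is ``median_ratios`` (expression-style, assumes a
    mostly-null unit set) or ``library`` (sequencing-depth size factors,
    the RPM convention; appropriate for binding counts where occupancy can
    shift globally between conditions and median-of-ratios has no null
    anchor).
    """
    if method != "nb_wald":
        raise ParameterError(f"unknown differential method {method!r}")
    if matrix.normalised:
        raise ParameterError("differential_test expects raw counts")
    cond_a, cond_b = contrast
    conds = matrix.samples["condition"].to_numpy()
    in_a, in_b = conds == cond_a, conds == cond_b
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a == 0 or n_b == 0:
        raise ParameterError(f"contrast {contrast} has an empty condition")
    use = in_a | in_b
    counts = matrix.counts[:, use]
    in_a, in_b = in_a[use], in_b[use]

    if normalisation == "median_ratios":
        sf = size_factors(counts)
    elif normalisation == "library":
        lib = matrix.library_sizes[use]
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        raise ParameterError(f"unknown normalisation {normalisation!r}")
    y = counts / sf[None, :]
    mu_a = y[:, in_a].mean(axis=1)
    mu_b = y[:, in_b].mean(axis=1)
    df_resid = n_a + n_b - 2
    single_rep = df_resid < 1

    # method-of-moments dispersion from within-condition residuals
    if not single_rep:
        ss = ((y[:, in_a] - mu_a[:, None]) ** 2).sum(axis=1) + \
             ((y[:, in_b] - mu_b[:, None]) ** 2).sum(axis=1)
        s2 = ss / df_resid
        w = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_mom = (s2 - w) / w**2
    else:
        w = (mu_a + mu_b) / 2.0
        alpha_mom = np.full(len(w), np.nan)

    alpha_tr = _dispersion_trend(w, alpha_mom)
    if single_rep:
        alpha = alpha_tr
    else:
        clipped = np.clip(np.nan_to_num(alpha_mom, nan=DISPERSION_FLOOR),
                          alpha_tr / 8.0, alpha_tr * 8.0)
        alpha = np.exp((1 - shrink_weight) * np.log(np.clip(clipped, DISPERSION_FLOOR, None))
                       + shrink_weight * np.log(alpha_tr))

    # Wald statistic on the log fold change of pseudo-counted means
    eps = lfc_pseudo
    ma, mb = mu_a + eps, mu_b + eps
    lfc = np.log2(mb / ma)
    inv_sf_a = (1.0 / sf[in_a]).sum() / n_a**2
    inv_sf_b = (1.0 / sf[in_b]).sum() / n_b**2
    var_ma = ma * inv_sf_a + alpha * ma**2 / n_a
    var_mb = mb * inv_sf_b + alpha * mb**2 / n_b
    se_ln = np.sqrt(var_ma / ma**2 + var_mb / mb**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(mb / ma) / se_ln
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (mu_a == 0) & (mu_b == 0)
    lfc[all_zero] = 0.0
    pvals[all_zero] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)

    fdr = bh_adjust(pvals)
    call = np.where(fdr < fdr_threshold, np.where(lfc > 0, "up", "down"), "ns")
    flagged = all_zero | single_rep
    return pd.DataFrame({
        "unit_id": matrix.region_ids,
        "log2fc": lfc,
        "pvalue": pvals,
        "fdr": fdr,
        "call": call,
        "flagged": flagged,
    })


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def de_filter(results: pd.DataFrame, raw_counts: np.ndarray,
              condition_masks: Sequence[np.ndarray], min_count: int = 20,
              fc_threshold: float = 1.5, fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Differential-expression call filter.

    A unit is kept iff (i) some condition has all replicates with raw
    counts >= ``min_count``, (ii) |FC| > ``fc_threshold`` (strict, on the
    linear scale), and (iii) FDR < ``fdr_threshold``. Returns the surviving
    subset with a ``direction`` column from the sign of log2fc.
    """
    raw_counts = np.asarray(raw_counts)
    count_ok = np.zeros(len(results), dtype=bool)
    for mask in condition_masks:
        count_ok |= np.all(raw_counts[:, np.asarray(mask)] >= min_count, axis=1)
    fc = 2.0 ** np.abs(results["log2fc"].to_numpy())
    keep = count_ok & (fc > fc_threshold) & (results["fdr"].to_numpy() < fdr_threshold)
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def zscore_foldchanges(log2fc: Sequence[float]) -> np.ndarray:
    """Z-score a fold-change vector with the n-1 sample standard deviation."""
    x = np.asarray(log2fc, float)
    if x.size < 2:
        raise ParameterError("need at least two values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ParameterError("zero variance fold-change vector")
    return (x - x.mean()) / sd
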