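"""Occupancy dependence classes.

Regions co-bound by the two nuclear receptors and the pluripotency TFs are
described by a max-normalised occupancy row (per TF, the depletion
condition with maximal binding is set to one) and grouped by K-means into
dependence classes: sets of regulatory elements sharing a pattern of
Oct4/Sox2/Nanog binding loss across the single and double depletions.

The number of classes k is chosen by the robustness of downstream
gene-proximity enrichment: the selected k is the first candidate at which
the differential-expression gene groups (one per contrast x direction with
any called genes) can each be matched to a distinct cluster showing
hypergeometric enrichment below a threshold somewhere on the distance
grid, stably across re-seeded clusterings. Resolving every responsive
gene group into its own cluster of regulatory regions is this package's
formalisation of "enrichment is robust"; it is configurable and reported
per k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .core_io import GeneAnnotation, GenomicInterval
from .enrichment import default_grid, proximity_enrichment_scan


class ParameterError(ValueError):
    pass


def max_normalise(means: pd.DataFrame, tfs: Sequence[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Divide each region's per-TF condition vector by its maximum.

    ``means`` is indexed by region with columns named ``{tf}|{condition}``.
    Returns the normalised frame (values in [0, 1]) and a boolean flag per
    region marking rows where some TF had an all-zero vector (left at 0).
    """
    out = means.copy().astype(float)
    flagged = np.zeros(len(means), dtype=bool)
    for tf in tfs:
        cols = [c for c in means.columns if c.startswith(f"{tf}|")]
        if not cols:
            raise ParameterError(f"no columns for TF {tf!r}")
        block = means[cols].to_numpy(float)
        mx = block.max(axis=1)
        zero = mx <= 0
        flagged |= zero
        mx_safe = np.where(zero, 1.0, mx)
        out[cols] = block / mx_safe[:, None]
        out.loc[zero, cols] = 0.0
    return out, flagged


def occupancy_matrix(matrix, tfs: Sequence[str], conditions: Sequence[str]) -> pd.DataFrame:
    """Per-region mean RPM per (TF, condition), as columns
    ``{tf}|{condition}``. Accepts a raw-count BindingMatrix; replicate
    means are taken on reads-per-ten-million values (depth normalisation,
    robust to global occupancy shifts between conditions)."""
    y = matrix.counts / matrix.library_sizes[None, :] * 1e7
    cols = {}
    samp = matrix.samples
    for tf in tfs:
        for cond in conditions:
            mask = ((samp["tf"] == tf) & (samp["condition"] == cond)).to_numpy()
            if not mask.any():
                raise ParameterError(f"no samples for ({tf}, {cond})")
            cols[f"{tf}|{cond}"] = y[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.region_ids)


@dataclass
class RegionClassAssignment:
    region_id: str
    class_label: int
    occupancy_row: np.ndarray


def kmeans_classes(occupancy: pd.DataFrame, k: int, seed: int = 0,
                   n_init: int = 10,
                   order_by: Sequence[str] | None = None) -> pd.DataFrame:
    """Euclidean K-means on occupancy rows, deterministic given the seed.

    Best of ``n_init`` k-means++ initialisations by within-cluster sum of
    squares. Labels (1..k) are renumbered by descending cluster mean over
    ``order_by`` columns (default: the double-depletion columns, suffix
    ``|-EN``) so numbering does not depend on initialisation order.
    Returns a DataFrame with region_id and class_label.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    X = occupancy.to_numpy(float)
    if len(np.unique(X, axis=0)) < k:
        raise ParameterError(f"k={k} exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=300, tol=1e-6,
                random_state=seed)
    labels = km.fit_predict(X)
    if order_by is None:
        order_by = [c for c in occupancy.columns if c.endswith("|-EN")]
    if order_by:
        key_cols = [occupancy.columns.get_loc(c) for c in order_by]
        centre_key = km.cluster_centers_[:, key_cols].mean(axis=1)
    else:
        centre_key = km.cluster_centers_.mean(axis=1)
    order = np.argsort(-centre_key)  # descending: class 1 = least depleted
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return pd.DataFrame({"region_id": occupancy.index,
                         "class_label": remap[labels]})


def _de_groups(de: pd.DataFrame, fc_threshold: float = 1.5,
               fdr_threshold: float = 0.01) -> dict[str, list[str]]:
    """Called DE gene ids per (contrast, direction) group."""
    called = de[(de["fdr"] < fdr_threshold) &
                (2.0 ** de["log2fc"].abs() > fc_threshold)]
    groups: dict[str, list[str]] = {}
    for row in called.itertuples(index=False):
        direction = "up" if row.log2fc > 0 else "down"
        groups.setdefault(f"{row.contrast}|{direction}", []).append(row.gene_id)
    return {g: ids for g, ids in groups.items() if len(ids) >= 5}


def cluster_enrichment_matrix(assignment: pd.DataFrame,
                              regions: Sequence[GenomicInterval],
                              genes: Sequence[GeneAnnotation],
                              de_groups: Mapping[str, Sequence[str]],
                              grid: np.ndarray | None = None) -> pd.DataFrame:
    """Minimum proximity-enrichment p-value over the distance grid for every
    (cluster, DE group) pair."""
    grid = default_grid() if grid is None else grid
    by_id = {iv.id: iv for iv in regions}
    rows = []
    for cls in sorted(assignment["class_label"].unique()):
        cluster_regions = [by_id[r] for r in
                           assignment.loc[assignment["class_label"] == cls, "region_id"]]
        for gname, gids in de_groups.items():
            curve = proximity_enrichment_scan(list(gids), genes, cluster_regions, grid)
            i = int(np.argmin(curve.pvalue))
            rows.append({"class_label": cls, "de_group": gname,
                         "min_p": float(curve.pvalue[i]),
                         "argmin_x": int(curve.grid[i])})
    return pd.DataFrame(rows)


def _groups_resolved(enr: pd.DataFrame, n_groups: int, threshold: float) -> bool:
    """True when a bipartite matching assigns every DE group its own
    enriched cluster."""
    sig = enr[enr["min_p"] < threshold]
    if sig.empty:
        return False
    groups = sorted(sig["de_group"].unique())
    clusters = sorted(sig["class_label"].unique())
    if len(groups) < n_groups or len(clusters) < n_groups:
        return False
    cost = np.ones((len(groups), len(clusters)))
    for row in sig.itertuples(index=False):
        cost[groups.index(row.de_group), clusters.index(row.class_label)] = 0.0
    gi, ci = linear_sum_assignment(cost)
    matched = sum(1 for a, b in zip(gi, ci) if cost[a, b] == 0.0)
    return matched >= n_groups


def select_k(occupancy: pd.DataFrame, regions: Sequence[GenomicInterval],
             genes: Sequence[GeneAnnotation], de: pd.DataFrame,
             candidate_ks: Sequence[int] = tuple(range(2, 9)), seed: int = 0,
             threshold: float = 1e-3, min_successes: int = 4, n_reseeds: int = 5,
             grid: np.ndarray | None = None) -> tuple[int | None, pd.DataFrame]:
    """First k at which gene-proximity enrichment is robust.

    For each candidate k the occupancy rows are clustered with
    ``n_reseeds`` different seeds; a clustering "resolves" the DE gene
    groups when every group can be matched to a distinct cluster with
    min-p < ``threshold`` somewhere on the grid. k is robust when at
    least ``min_successes`` of the reseeds resolve. Returns the first
    robust k (or None) and a per-k report.
    """
    de_groups = _de_groups(de)
    report_rows = []
    if not de_groups:
        return None, pd.DataFrame(columns=["k", "n_resolved", "robust"])
    n_groups = len(de_groups)
    rng = np.random.default_rng(seed)
    reseeds = rng.integers(0, 2**31 - 1, size=n_reseeds)
    chosen = None
    for k in sorted(candidate_ks):
        if k < n_groups:
            # fewer clusters than responsive gene groups can never resolve
            report_rows.append({"k": k, "n_resolved": 0, "robust": False})
            continue
        n_ok = 0
        for s in reseeds:
            assignment = kmeans_classes(occupancy, k, seed=int(s))
            enr = cluster_enrichment_matrix(assignment, regions, genes,
                                            de_groups, grid)
            if _groups_resolved(enr, n_groups, threshold):
                n_ok += 1
        robust = n_ok >= min_successes
        report_rows.append({"k": k, "n_resolved": n_ok, "robust": robust})
        if robust and chosen is None:
            chosen = k
            break
    return chosen, pd.DataFrame(report_rows)
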