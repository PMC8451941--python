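"""End-to-end orchestration of the analysis stages.

Stages run in dependency order on a single output directory:

``simulate -> scan -> diff -> classify -> pairdist -> proximity -> trend
-> coop``

Each stage reads only files earlier stages wrote, every floating-point
output is written with fixed precision, and one top-level seed is
expanded deterministically into per-stage seeds, so a run is bit-for-bit
reproducible from its config. A JSON manifest records the config
snapshot, per-stage seeds and the SHA-256 digest of every output file.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import BindingMatrix, differential_test, zscore_foldchanges
from .core_io import genes_from_table, read_bed, read_fasta, read_table, write_table
from .enrichment import pair_distance_enrichment
from .motifs import (HALF_SITE_T, hits_to_table, scan_consensus, scan_regions,
                     scan_trimmed_halfsite, table_to_hits)
from .region_classes import (cluster_enrichment_matrix, _de_groups, kmeans_classes,
                             max_normalise, occupancy_matrix, select_k)
from .synthetic import CLUST_TFS, CONDITIONS, OCT_SOX_CONSENSUS, simulate_preset
from .trend import additivity_test, gp_trend, single_site_regions

STAGES = ("simulate", "scan", "diff", "classify", "pairdist", "proximity",
          "trend", "coop")

MOTIF_LENGTHS = {"halfsite": len(HALF_SITE_T), "octsox": len(OCT_SOX_CONSENSUS)}

DEFAULT_CONFIG = {
    "seed": 0,
    "preset": "full",
    "k": 5,
    "select_k": None,          # e.g. "2:8" to choose k by enrichment robustness
    "max_mismatch": 1,
    "bin_width": 10,
    "max_distance": 500,
    "n_shuffles": 100,
    "contrasts": ["-E", "-N", "-EN"],
    "clustering_tfs": list(CLUST_TFS),
    "trend_tf": "Oct4",
    "trend_contrast": "-EN",
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the top-level seed."""
    return (int(base_seed) + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(user) - set(DEFAULT_CONFIG) - {"outdir", "stages"}
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _comment(stage: str, cfg: dict) -> str:
    return (f"duoreg {__version__} stage={stage} preset={cfg['preset']} "
            f"seed={cfg['seed']}")


# ---------------------------------------------------------------------------
# Stage implementations. Each takes (outdir, cfg) and returns output paths.


def _stage_simulate(outdir: Path, cfg: dict) -> list[Path]:
    res = simulate_preset(cfg["preset"], outdir, seed=stage_seed(cfg["seed"], "simulate"))
    return sorted(res["paths"].values())


def _stage_scan(outdir: Path, cfg: dict) -> list[Path]:
    genome = read_fasta(outdir / "genome.fa")
    regions = read_bed(outdir / "regions.bed")
    mm = cfg["max_mismatch"]
    half = scan_regions(genome, regions, scan_trimmed_halfsite, max_mismatch=mm)
    octsox = scan_regions(genome, regions, scan_consensus,
                          consensus=OCT_SOX_CONSENSUS, max_mismatch=mm,
                          motif_name="octsox")
    p1, p2 = outdir / "hits_halfsite.tsv", outdir / "hits_octsox.tsv"
    write_table(hits_to_table(half), p1, comment=_comment("scan", cfg))
    write_table(hits_to_table(octsox), p2, comment=_comment("scan", cfg))
    return [p1, p2]


def _load_matrix(outdir: Path) -> BindingMatrix:
    cdf = read_table(outdir / "counts.tsv", required=["region_id"])
    sdf = read_table(outdir / "samples.tsv",
                     required=["sample_id", "tf", "condition", "replicate",
                               "library_size"])
    counts = cdf[sdf["sample_id"]].to_numpy()
    return BindingMatrix(region_ids=list(cdf["region_id"]),
                         samples=sdf[["sample_id", "tf", "condition", "replicate"]],
                         counts=counts,
                         library_sizes=sdf["library_size"].to_numpy())


def _stage_diff(outdir: Path, cfg: dict) -> list[Path]:
    matrix = _load_matrix(outdir)
    frames = []
    for tf in matrix.samples["tf"].unique():
        sub = matrix.select((matrix.samples["tf"] == tf).to_numpy())
        for cond in cfg["contrasts"]:
            if not (sub.samples["condition"] == cond).any():
                continue
            res = differential_test(sub, ("++", cond), normalisation="library")
            res.insert(0, "tf", tf)
            res.insert(1, "contrast", cond)
            frames.append(res)
    out = outdir / "diff.tsv"
    write_table(pd.concat(frames, ignore_index=True), out,
                comment=_comment("diff", cfg))
    return [out]


def _stage_classify(outdir: Path, cfg: dict) -> list[Path]:
    matrix = _load_matrix(outdir)
    occ_raw = occupancy_matrix(matrix, cfg["clustering_tfs"], CONDITIONS)
    occ, flagged = max_normalise(occ_raw, cfg["clustering_tfs"])
    seed = stage_seed(cfg["seed"], "classify")
    paths = []
    k = cfg["k"]
    if cfg.get("select_k"):
        lo, hi = (int(v) for v in str(cfg["select_k"]).split(":"))
        regions = read_bed(outdir / "regions.bed")
        genes = genes_from_table(read_table(outdir / "genes.tsv"))
        de = read_table(outdir / "de.tsv",
                        required=["gene_id", "contrast", "log2fc", "fdr"])
        chosen, report = select_k(occ, regions, genes, de,
                                  candidate_ks=range(lo, hi + 1), seed=seed)
        rp = outdir / "select_k.tsv"
        write_table(report, rp, comment=_comment("classify", cfg))
        paths.append(rp)
        if chosen is not None:
            k = chosen
    assignment = kmeans_classes(occ, k, seed=seed)
    assignment["flagged"] = flagged
    ap = outdir / "assignment.tsv"
    write_table(assignment, ap, comment=_comment("classify", cfg))
    op = outdir / "occupancy.tsv"
    occ_out = occ.reset_index(names="region_id")
    write_table(occ_out, op, comment=_comment("classify", cfg))
    return [ap, op, *paths]


def _stage_pairdist(outdir: Path, cfg: dict) -> list[Path]:
    regions = read_bed(outdir / "regions.bed")
    half = table_to_hits(read_table(outdir / "hits_halfsite.tsv"))
    octsox = table_to_hits(read_table(outdir / "hits_octsox.tsv"))
    curve = pair_distance_enrichment(
        half, octsox, regions, MOTIF_LENGTHS,
        bin_width=cfg["bin_width"], max_distance=cfg["max_distance"],
        n_shuffles=cfg["n_shuffles"], seed=stage_seed(cfg["seed"], "pairdist"))
    out = outdir / "pairdist.tsv"
    write_table(curve.to_frame(), out, comment=_comment("pairdist", cfg))
    return [out]


def _stage_proximity(outdir: Path, cfg: dict) -> list[Path]:
    regions = read_bed(outdir / "regions.bed")
    genes = genes_from_table(read_table(outdir / "genes.tsv"))
    de = read_table(outdir / "de.tsv",
                    required=["gene_id", "contrast", "log2fc", "fdr"])
    assignment = read_table(outdir / "assignment.tsv",
                            required=["region_id", "class_label"])
    enr = cluster_enrichment_matrix(assignment, regions, genes, _de_groups(de))
    out = outdir / "proximity.tsv"
    write_table(enr, out, comment=_comment("proximity", cfg))
    return [out]


def _region_c_share(half_hits: dict) -> pd.Series:
    """Per-region share of C-variant half-site hits among T/C hits."""
    rows = {}
    for rid, hs in half_hits.items():
        t = sum(1 for h in hs if h.seventh_base == "T")
        c = sum(1 for h in hs if h.seventh_base == "C")
        if t + c:
            rows[rid] = c / (t + c)
    return pd.Series(rows)


def _stage_trend(outdir: Path, cfg: dict) -> list[Path]:
    half = table_to_hits(read_table(outdir / "hits_halfsite.tsv"))
    diff = read_table(outdir / "diff.tsv")
    sel = diff[(diff["tf"] == cfg["trend_tf"]) &
               (diff["contrast"] == cfg["trend_contrast"])]
    lfc = sel.set_index("unit_id")["log2fc"]
    c_share = _region_c_share(half)
    shared = c_share.index.intersection(lfc.index)
    cs = c_share.loc[shared].sort_values(kind="mergesort")
    z = pd.Series(zscore_foldchanges(lfc.loc[cs.index]), index=cs.index)
    # aggregate into rank bins to keep the GP solve small and smooth
    n_bins = min(100, max(5, len(cs) // 10))
    bins = np.array_split(np.arange(len(cs)), n_bins)
    xb = np.array([cs.iloc[b].mean() for b in bins])
    yb = np.array([z.iloc[b].mean() for b in bins])
    fit = gp_trend(xb, yb, seed=stage_seed(cfg["seed"], "trend"))
    out = outdir / "trend.tsv"
    write_table(fit.to_frame(), out, comment=_comment("trend", cfg))
    return [out]


def _stage_coop(outdir: Path, cfg: dict) -> list[Path]:
    half = table_to_hits(read_table(outdir / "hits_halfsite.tsv"))
    regions = read_bed(outdir / "regions.bed")
    singles = single_site_regions(half, [iv.id for iv in regions])
    diff = read_table(outdir / "diff.tsv")
    tf = cfg["trend_tf"]
    per = {c: diff[(diff["tf"] == tf) & (diff["contrast"] == c)]
           .set_index("unit_id")["log2fc"] for c in ("-E", "-N", "-EN")}
    idx = pd.Index(singles)
    res = additivity_test(per["-E"].loc[idx], per["-N"].loc[idx],
                          per["-EN"].loc[idx])
    out = outdir / "coop.tsv"
    write_table(pd.DataFrame([{
        "tf": tf, "n_single_site": len(singles),
        "median_delta": res.median_delta, "statistic": res.statistic,
        "pvalue": res.pvalue, "computable": res.computable,
    }]), out, comment=_comment("coop", cfg))
    return [out]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "diff": _stage_diff,
    "classify": _stage_classify,
    "pairdist": _stage_pairdist,
    "proximity": _stage_proximity,
    "trend": _stage_trend,
    "coop": _stage_coop,
}

_STAGE_OUTPUTS = {
    "simulate": ["genome.fa", "regions.bed"],
    "scan": ["hits_halfsite.tsv", "hits_octsox.tsv"],
    "diff": ["diff.tsv"],
    "classify": ["assignment.tsv", "occupancy.tsv"],
    "pairdist": ["pairdist.tsv"],
    "proximity": ["proximity.tsv"],
    "trend": ["trend.tsv"],
    "coop": ["coop.tsv"],
}


def run_pipeline(config: dict | str | Path, outdir: str | Path,
                 stages: list[str] | None = None, resume: bool = False) -> dict:
    """Run the stages in order, writing outputs and a manifest to outdir.

    With ``resume``, a stage whose outputs already exist is skipped unless
    an upstream stage was (re)run. A stage failure stops the run but
    leaves completed-stage outputs and an error manifest behind.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = list(stages) if stages else list(STAGES)
    bad = set(todo) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages {sorted(bad)}")
    todo = [s for s in STAGES if s in todo]

    manifest = {"version": __version__, "config": {k: v for k, v in cfg.items()},
                "stages": [], "status": "ok"}
    upstream_ran = False
    for stage in todo:
        have = all((outdir / f).exists() for f in _STAGE_OUTPUTS[stage])
        if resume and have and not upstream_ran:
            manifest["stages"].append({"stage": stage, "skipped": True})
            continue
        try:
            paths = _STAGE_FUNCS[stage](outdir, cfg)
        except Exception as exc:
            manifest["status"] = f"failed at stage {stage}: {exc}"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                             default=str))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        upstream_ran = True
        manifest["stages"].append({
            "stage": stage,
            "seed": stage_seed(cfg["seed"], stage),
            "outputs": {p.name: _sha256(Path(p)) for p in paths},
        })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest
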