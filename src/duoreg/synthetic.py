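"""Synthetic study generator with planted ground truth.

Produces, from explicit parameters and a seed, a complete artificial study
of two cooperating nuclear receptors: a random genome, non-overlapping
bound regions carrying planted TCAAGG(T/C)CA half-sites (and optionally an
Oct/Sox composite element at a controlled spacing), negative-binomial read
counts per region and sample whose condition-dependent fold changes follow
planted region dependence classes, and genes whose differential-expression
status is tied to proximity to regions of a designated class.

Every downstream stage of the pipeline therefore has a recoverable truth:
motif positions, strands and seventh-base variants; region classes and
their depletion fold changes; the planted half-site/Oct-Sox spacing; and
gene-region links.

The Oct/Sox element used here is a *synthetic* composite consensus
(CTTTGTTATGCAAAT, a Sox element followed by the reverse octamer), built
for planting and rescanning; it is not a database matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingMatrix
from .core_io import (GeneAnnotation, GenomicInterval, MotifMatrix, write_bed,
                      write_fasta, write_table)
from .motifs import HALF_SITE_C, HALF_SITE_T, reverse_complement

OCT_SOX_CONSENSUS = "CTTTGTTATGCAAAT"  # synthetic Sox+octamer composite
HALF_SITE_LEN = len(HALF_SITE_T)

CONDITIONS = ("++", "-E", "-N", "-EN")
CLUST_TFS = ("Oct4", "Sox2", "Nanog")


class ParameterError(ValueError):
    pass


class CapacityError(ValueError):
    pass


def indicator_motif(consensus: str, name: str, weight: float = 0.85,
                    total: int = 100) -> MotifMatrix:
    """Near-indicator PFM for a consensus: the consensus base carries
    ``weight`` of each column, the rest is spread evenly. Synthetic
    construction used for planting/scoring in simulated studies."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    counts = np.full((L, 4), total * (1 - weight) / 3)
    for i, b in enumerate(consensus.upper()):
        counts[i, base_idx[b]] = total * weight
    return MotifMatrix(name=name, counts=counts)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic study."""

    seed: int
    params: dict
    regions: list[GenomicInterval]
    region_class: dict[str, int]
    motif_plants: pd.DataFrame  # region_id, motif_name, offset, strand, variant
    planted_spacing: int | None
    effect_sizes: dict[tuple[int, str, str], float]  # (class, tf, condition) -> lfc
    tf_bias: dict[str, np.ndarray] = field(default_factory=dict)
    gene_truth: pd.DataFrame | None = None
    dispersion: float = 0.1
    library_sizes: np.ndarray | None = None

    def class_labels(self) -> np.ndarray:
        return np.array([self.region_class[iv.id] for iv in self.regions])


# ---------------------------------------------------------------------------
# Genome


def generate_genome(n_chroms: int, chrom_len: int, gc: float = 0.42,
                    seed: int = 0) -> dict[str, str]:
    """I.i.d. background genome with the stated GC content."""
    if chrom_len < 1000:
        raise ParameterError("chrom_len must be >= 1000")
    if not (0 <= gc <= 1):
        raise ParameterError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for i in range(n_chroms):
        arr = rng.choice(bases, size=chrom_len, p=p)
        out[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# Regions and motif plants


def plant_regions_and_motifs(genome: dict[str, str], n_regions: int,
                             region_len: int = 400,
                             class_props: Sequence[float] = (1.0,),
                             variant_mix: Sequence[float] = (0.5,),
                             octsox_fraction: float = 0.0,
                             octsox_spacing: int | None = None,
                             spacing_jitter: int = 5,
                             variant_gradient: tuple[float, float] | None = None,
                             seed: int = 0) -> tuple[list[GenomicInterval], SyntheticTruth]:
    """Place non-overlapping regions and write motif instances into them.

    Each region gets exactly one half-site plant whose seventh base is C
    with the class-specific probability in ``variant_mix`` (T otherwise).
    A fraction ``octsox_fraction`` of regions additionally receives one
    Oct/Sox composite element: at a uniformly random non-overlapping
    position when ``octsox_spacing`` is None, else at a centre-to-centre
    distance of ``octsox_spacing`` +/- ``spacing_jitter`` from the
    half-site. ``variant_gradient=(p_lo, p_hi)`` overrides ``variant_mix``
    with a per-region C probability that rises linearly along a planted
    Esrrb:Nr5a2 binding-bias gradient (stored in ``tf_bias``).

    Planted strings overwrite the background sequence in place (``genome``
    is mutated), so rescanning recovers plants exactly.
    """
    if region_len < 200:
        raise ParameterError("region_len must be >= 200")
    props = np.asarray(class_props, float)
    if abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ParameterError("class_props must be non-negative and sum to 1")
    if len(variant_mix) != len(props):
        raise ParameterError("variant_mix must have one entry per class")
    rng = np.random.default_rng(seed)

    # non-overlapping placement on a slot grid (one region per 2x slot)
    slot = 2 * region_len
    chroms = sorted(genome)
    slots = [(c, i) for c in chroms for i in range(len(genome[c]) // slot)]
    if n_regions > len(slots):
        raise CapacityError(f"cannot place {n_regions} non-overlapping regions; "
                            f"capacity {len(slots)}")
    chosen = rng.choice(len(slots), size=n_regions, replace=False)
    chosen.sort()
    buf = {c: bytearray(genome[c], "ascii") for c in chroms}

    n_classes = len(props)
    classes = rng.choice(np.arange(1, n_classes + 1), size=n_regions, p=props)
    octsox_mask = rng.random(n_regions) < octsox_fraction
    if variant_gradient is not None:
        # planted log2 Esrrb:Nr5a2 bias runs from +1.5 down to -1.5 over the
        # region index; C probability rises along it
        bias = np.linspace(1.5, -1.5, n_regions)
        p_lo, p_hi = variant_gradient
        p_c = np.linspace(p_lo, p_hi, n_regions)
    else:
        bias = np.zeros(n_regions)
        p_c = np.array([variant_mix[c - 1] for c in classes])

    regions: list[GenomicInterval] = []
    region_class: dict[str, int] = {}
    plants = []
    oct_len = len(OCT_SOX_CONSENSUS)
    margin = octsox_spacing + spacing_jitter + oct_len if octsox_spacing else 0

    def write_motif(chrom: str, pos: int, motif: str, strand: str) -> None:
        s = motif if strand == "+" else reverse_complement(motif)
        buf[chrom][pos:pos + len(s)] = s.encode("ascii")

    for idx, slot_i in enumerate(chosen):
        chrom, si = slots[slot_i]
        slack = slot - region_len
        start = si * slot + int(rng.integers(0, slack + 1))
        rid = f"reg{idx:05d}"
        iv = GenomicInterval(chrom, start, start + region_len, rid)
        regions.append(iv)
        region_class[rid] = int(classes[idx])

        variant = "C" if rng.random() < p_c[idx] else "T"
        half = HALF_SITE_C if variant == "C" else HALF_SITE_T
        hs_strand = "+" if rng.random() < 0.5 else "-"
        lo = max(margin, 0)
        hi = region_len - HALF_SITE_LEN - max(margin, 0)
        if hi <= lo:
            raise ParameterError("region too short for requested spacing margin")
        hs_off = int(rng.integers(lo, hi + 1))
        write_motif(chrom, start + hs_off, half, hs_strand)
        plants.append({"region_id": rid, "motif_name": "halfsite", "offset": hs_off,
                       "strand": hs_strand, "variant": variant})

        if octsox_mask[idx]:
            os_strand = "+" if rng.random() < 0.5 else "-"
            hs_centre = hs_off + HALF_SITE_LEN // 2
            if octsox_spacing is not None:
                jit = int(rng.integers(-spacing_jitter, spacing_jitter + 1)) \
                    if spacing_jitter else 0
                side = 1 if rng.random() < 0.5 else -1
                os_centre = hs_centre + side * (octsox_spacing + jit)
                os_off = os_centre - oct_len // 2
                if not (0 <= os_off <= region_len - oct_len):
                    os_centre = hs_centre - side * (octsox_spacing + jit)
                    os_off = os_centre - oct_len // 2
            else:
                # uniform placement avoiding the half-site footprint
                for _ in range(100):
                    os_off = int(rng.integers(0, region_len - oct_len + 1))
                    if os_off + oct_len <= hs_off or os_off >= hs_off + HALF_SITE_LEN:
                        break
                else:  # pragma: no cover - virtually impossible at these sizes
                    continue
            write_motif(chrom, start + os_off, OCT_SOX_CONSENSUS, os_strand)
            plants.append({"region_id": rid, "motif_name": "octsox", "offset": int(os_off),
                           "strand": os_strand, "variant": ""})

    for c in chroms:
        genome[c] = buf[c].decode("ascii")

    truth = SyntheticTruth(
        seed=int(seed),
        params={"n_regions": n_regions, "region_len": region_len,
                "class_props": list(props), "octsox_fraction": octsox_fraction,
                "octsox_spacing": octsox_spacing, "spacing_jitter": spacing_jitter},
        regions=regions,
        region_class=region_class,
        motif_plants=pd.DataFrame(plants, columns=["region_id", "motif_name",
                                                   "offset", "strand", "variant"]),
        planted_spacing=octsox_spacing,
        effect_sizes={},
        tf_bias={"Esrrb": bias, "Nr5a2": -bias},
    )
    return regions, truth


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(truth: SyntheticTruth, samples: pd.DataFrame, seed: int = 0,
                    alpha: float = 0.1, baseline_mean: float = 100.0,
                    baseline_sigma: float = 0.4,
                    libfac_range: tuple[float, float] = (0.7, 1.3)) -> BindingMatrix:
    """Negative-binomial counts per region x sample.

    The mean for region i, sample j is
    ``base_i * libfac_j * 2**lfc(class_i, tf_j, cond_j) * 2**bias_tfj[i]``
    with a shared dispersion ``alpha`` (variance mu + alpha mu^2).
    ``samples`` needs columns sample_id, tf, condition, replicate. Effects
    must be present in ``truth.effect_sizes`` for every (class, tf,
    condition) with a non-reference condition; the reference ``++`` is 0.
    """
    if alpha <= 0:
        raise ParameterError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    n_r, n_s = len(truth.regions), len(samples)
    base = rng.lognormal(np.log(baseline_mean), baseline_sigma, size=n_r)
    libfac = rng.uniform(*libfac_range, size=n_s)
    classes = truth.class_labels()
    counts = np.zeros((n_r, n_s), dtype=np.int64)
    for j, row in enumerate(samples.itertuples(index=False)):
        lfc = np.zeros(n_r)
        if row.condition != "++":
            for c in np.unique(classes):
                key = (int(c), row.tf, row.condition)
                if key not in truth.effect_sizes:
                    raise ParameterError(f"missing planted effect for {key}")
                lfc[classes == c] = truth.effect_sizes[key]
        bias = truth.tf_bias.get(row.tf, 0.0)
        mu = base * libfac[j] * 2.0 ** (lfc + bias)
        r = 1.0 / alpha
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    # sequencing depth tracks the library-prep factor, not the (possibly
    # globally depleted) on-region signal: regions capture only a small
    # share of a fixed-depth library
    lib = np.maximum(np.round(2e7 * libfac).astype(np.int64),
                     counts.sum(axis=0))
    truth.dispersion = alpha
    truth.library_sizes = lib
    return BindingMatrix(region_ids=[iv.id for iv in truth.regions],
                         samples=samples.reset_index(drop=True),
                         counts=counts, library_sizes=lib)


def sample_sheet(tfs: Sequence[str], conditions: Sequence[str],
                 n_replicates: int = 3) -> pd.DataFrame:
    rows = [{"sample_id": f"{tf}_{cond}_r{r + 1}", "tf": tf,
             "condition": cond, "replicate": r + 1}
            for tf in tfs for cond in conditions for r in range(n_replicates)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genes and differential expression


def simulate_genes_and_de(truth: SyntheticTruth, chrom_lens: Mapping[str, int],
                          n_genes: int = 1000,
                          groups: Sequence[dict] = (),
                          link_distance: int = 5000, link_fraction: float = 0.8,
                          contrasts: Sequence[str] = ("-E", "-N", "-EN"),
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes with TSS positions plus per-contrast DE tables.

    ``groups`` entries are dicts with keys ``name``, ``class_label`` (the
    planted region class the group's genes sit near, or None for an
    unlinked group), ``contrast``, ``direction`` (up/down) and ``n``. A
    ``link_fraction`` of each linked group's genes gets a TSS within
    ``link_distance`` bp of a random region of the designated class; all
    other genes are placed uniformly. The DE tables carry planted log2
    fold changes and FDRs consistent with the group's direction.
    """
    if link_distance <= 0:
        raise ParameterError("link_distance must be positive")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lens)
    lens = np.array([chrom_lens[c] for c in chroms], float)
    probs = lens / lens.sum()
    regions_by_class: dict[int, list[GenomicInterval]] = {}
    for iv in truth.regions:
        regions_by_class.setdefault(truth.region_class[iv.id], []).append(iv)

    n_de = sum(g["n"] for g in groups)
    if n_de > n_genes:
        raise ParameterError("more DE genes requested than genes")

    def uniform_tss() -> tuple[str, int]:
        ci = rng.choice(len(chroms), p=probs)
        return chroms[ci], int(rng.integers(0, chrom_lens[chroms[ci]]))

    gene_rows, truth_rows = [], []
    gi = 0
    for grp in groups:
        cls = grp.get("class_label")
        pool = regions_by_class.get(cls, []) if cls is not None else []
        for _ in range(grp["n"]):
            gid = f"gene{gi:05d}"
            gi += 1
            linked_region = ""
            if pool and rng.random() < link_fraction:
                reg = pool[int(rng.integers(len(pool)))]
                delta = int(rng.integers(-link_distance, link_distance + 1))
                chrom, tss = reg.chrom, max(0, reg.centre + delta)
                linked_region = reg.id
            else:
                chrom, tss = uniform_tss()
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append({"gene_id": gid, "chrom": chrom, "tss": tss,
                              "strand": strand})
            truth_rows.append({"gene_id": gid, "group": grp["name"],
                               "contrast": grp["contrast"],
                               "direction": grp["direction"],
                               "linked_region": linked_region, "is_de": True})
    for _ in range(n_genes - n_de):
        gid = f"gene{gi:05d}"
        gi += 1
        chrom, tss = uniform_tss()
        gene_rows.append({"gene_id": gid, "chrom": chrom, "tss": tss,
                          "strand": "+" if rng.random() < 0.5 else "-"})
        truth_rows.append({"gene_id": gid, "group": "", "contrast": "",
                           "direction": "", "linked_region": "", "is_de": False})

    genes = pd.DataFrame(gene_rows)
    gene_truth = pd.DataFrame(truth_rows)

    de_rows = []
    for contrast in contrasts:
        for t in gene_truth.itertuples(index=False):
            if t.is_de and t.contrast == contrast:
                mag = rng.uniform(0.8, 2.5)
                lfc = mag if t.direction == "up" else -mag
                fdr = 10.0 ** (-rng.uniform(3, 8))
            else:
                lfc = rng.normal(0, 0.15)
                fdr = rng.uniform(0.05, 1.0)
            de_rows.append({"gene_id": t.gene_id, "contrast": contrast,
                            "log2fc": lfc, "pvalue": fdr / 2, "fdr": fdr})
    de = pd.DataFrame(de_rows)
    truth.gene_truth = gene_truth
    return genes, de


# ---------------------------------------------------------------------------
# Presets

# Planted depletion log2 fold changes per dependence class for the
# pluripotency TFs (vs the ++ reference): class 1 responds to either single
# depletion, classes 2/3 to one receptor each, class 4 only to the double
# depletion, class 5 gains binding upon the double depletion.
CLASS_EFFECTS = {
    1: {"-E": -1.0, "-N": -1.0, "-EN": -2.0},
    2: {"-E": -1.5, "-N": 0.0, "-EN": -2.0},
    3: {"-E": 0.0, "-N": -1.5, "-EN": -2.0},
    4: {"-E": 0.0, "-N": 0.0, "-EN": -1.5},
    5: {"-E": 0.0, "-N": 0.0, "-EN": 1.0},
}
RECEPTOR_EFFECTS = {
    "Esrrb": {"-E": -6.0, "-N": 0.0, "-EN": -6.0},
    "Nr5a2": {"-E": 0.0, "-N": -6.0, "-EN": -6.0},
}
CLASS_PROPS = (0.2, 0.2, 0.2, 0.25, 0.15)
CLASS_VARIANT_MIX = (0.5, 0.1, 0.9, 0.5, 0.5)  # class 2 T-rich, class 3 C-rich
# gene groups: one DE group per class, distinct (contrast, direction) pairs
GENE_GROUPS = (
    {"name": "g1", "class_label": 1, "contrast": "-E", "direction": "down", "n": 40},
    {"name": "g2", "class_label": 2, "contrast": "-N", "direction": "down", "n": 40},
    {"name": "g3", "class_label": 3, "contrast": "-EN", "direction": "down", "n": 40},
    {"name": "g4", "class_label": 4, "contrast": "-EN", "direction": "up", "n": 40},
    {"name": "g5", "class_label": 5, "contrast": "-E", "direction": "up", "n": 40},
)

PRESETS = ("null", "spacing", "classes", "full", "gradient")


def _full_effects(n_classes: int = 5) -> dict[tuple[int, str, str], float]:
    eff = {}
    for c in range(1, n_classes + 1):
        for tf in CLUST_TFS:
            for cond, v in CLASS_EFFECTS[c].items():
                eff[(c, tf, cond)] = v
        for tf, tbl in RECEPTOR_EFFECTS.items():
            for cond, v in tbl.items():
                eff[(c, tf, cond)] = v
    return eff


def simulate_preset(name: str, outdir: str | Path, seed: int = 0) -> dict:
    """Generate one of the named study presets into ``outdir``.

    Returns a dict with the truth object and the paths of every emitted
    file. Presets:

    * ``null``     - 2 x 1 Mb genome, 2000 regions, half-sites plus an
      Oct/Sox element in 30% of regions at uniformly random positions.
    * ``spacing``  - as null, but the Oct/Sox element sits at a planted
      50 +/- 5 bp centre-to-centre distance from the half-site.
    * ``classes``  - 2 x 10 Mb genome, 1000 regions in 5 dependence
      classes, counts for Oct4/Sox2/Nanog/Esrrb/Nr5a2 across the four
      depletion conditions (3 replicates), and 1000 genes with one DE
      group linked to each class (80% within 5 kb).
    * ``full``     - as classes, plus the planted 50 bp spacing; the
      class-5 DE group is left unlinked as a decoy.
    * ``gradient`` - 2 x 1 Mb genome, 2000 regions with a planted T->C
      seventh-base gradient tied to a planted Esrrb:Nr5a2 binding bias,
      plus Esrrb/Nr5a2 counts for ranking.
    """
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {PRESETS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)

    if name in ("null", "spacing", "gradient"):
        genome = generate_genome(2, 1_000_000, seed=int(sub[0]))
        spacing = 50 if name == "spacing" else None
        grad = (0.05, 0.95) if name == "gradient" else None
        frac = 0.0 if name == "gradient" else 0.3
        regions, truth = plant_regions_and_motifs(
            genome, n_regions=2000, region_len=400, class_props=(1.0,),
            variant_mix=(0.5,), octsox_fraction=frac, octsox_spacing=spacing,
            spacing_jitter=5, variant_gradient=grad, seed=int(sub[1]))
        matrix = None
        if name == "gradient":
            samples = sample_sheet(("Esrrb", "Nr5a2"), ("++",), n_replicates=3)
            matrix = simulate_counts(truth, samples, seed=int(sub[2]))
        genes = de = None
    else:
        genome = generate_genome(2, 10_000_000, seed=int(sub[0]))
        spacing = 50 if name == "full" else None
        frac = 0.3
        regions, truth = plant_regions_and_motifs(
            genome, n_regions=1000, region_len=400, class_props=CLASS_PROPS,
            variant_mix=CLASS_VARIANT_MIX, octsox_fraction=frac,
            octsox_spacing=spacing, spacing_jitter=5, seed=int(sub[1]))
        truth.effect_sizes = _full_effects()
        samples = sample_sheet(("Oct4", "Sox2", "Nanog", "Esrrb", "Nr5a2"),
                               CONDITIONS, n_replicates=3)
        matrix = simulate_counts(truth, samples, seed=int(sub[2]))
        groups = list(GENE_GROUPS)
        if name == "full":  # decoy: class-5 genes exist but are unlinked
            groups[4] = dict(groups[4], class_label=None)
        genes, de = simulate_genes_and_de(
            truth, {c: len(s) for c, s in genome.items()}, n_genes=1000,
            groups=groups, link_distance=5000, link_fraction=0.8,
            seed=int(sub[3]))

    paths = {"genome": outdir / "genome.fa", "regions": outdir / "regions.bed"}
    write_fasta(genome, paths["genome"])
    write_bed(regions, paths["regions"])
    tag = f"duoreg simulate preset={name} seed={seed}"
    paths["truth_regions"] = outdir / "truth_regions.tsv"
    classes = truth.class_labels()
    write_table(pd.DataFrame({
        "region_id": [iv.id for iv in regions],
        "chrom": [iv.chrom for iv in regions],
        "start": [iv.start for iv in regions],
        "end": [iv.end for iv in regions],
        "class": classes,
        "esrrb_bias": truth.tf_bias.get("Esrrb", np.zeros(len(regions))),
    }), paths["truth_regions"], comment=tag)
    paths["truth_plants"] = outdir / "truth_plants.tsv"
    write_table(truth.motif_plants, paths["truth_plants"], comment=tag)

    if matrix is not None:
        paths["counts"] = outdir / "counts.tsv"
        cdf = pd.DataFrame(matrix.counts.astype(int),
                           columns=matrix.samples["sample_id"])
        cdf.insert(0, "region_id", matrix.region_ids)
        write_table(cdf, paths["counts"], comment=tag)
        paths["samples"] = outdir / "samples.tsv"
        sdf = matrix.samples.copy()
        sdf["library_size"] = matrix.library_sizes.astype(int)
        write_table(sdf, paths["samples"], comment=tag)
    if genes is not None:
        paths["genes"] = outdir / "genes.tsv"
        write_table(genes, paths["genes"], comment=tag)
        paths["de"] = outdir / "de.tsv"
        write_table(de, paths["de"], comment=tag)
        paths["truth_genes"] = outdir / "truth_genes.tsv"
        write_table(truth.gene_truth, paths["truth_genes"], comment=tag)

    return {"truth": truth, "genome": genome, "matrix": matrix,
            "genes": genes, "de": de, "paths": paths}
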