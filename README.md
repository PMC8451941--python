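# duoreg

Analysis toolkit for studying how two redundant orphan nuclear receptors —
Esrrb and Nr5a2 in mouse embryonic stem cells — jointly control the DNA
binding of the core pluripotency factors Oct4, Sox2 and Nanog.

Both receptors read the same 9-bp extended oestrogen-response half-site,
**TCAAGG(T/C)CA**, whose seventh base tilts the preference between them
(T → Esrrb, C → Nr5a2). `duoreg` implements the computational analyses that
turn ChIP-seq peak sets, count matrices and differential-expression tables
into statements about this redundancy, and ships a synthetic-data generator
with planted ground truth so every stage can be validated end to end.

## What it computes

| Stage | Statistic |
| --- | --- |
| `motifs` | exact / ≤1-mismatch consensus scanning for both seventh-base variants; trimmed-consensus `TCAAGGXCA` scanning with a free seventh base; PWM log-odds scoring; region variant classes (T-only / C-only / both / none); seventh-base frequency profiles along binding-ratio-ranked regions |
| `binding` | replicate-reproducible peaks, per-TF merging with overlap flags, blacklist exclusion; RPM normalisation; a negative-binomial Wald differential test (median-of-ratios or sequencing-depth size factors, trend-shrunk moment dispersions, BH correction); the ≥20-raw-counts / \|FC\|>1.5 / FDR<0.01 differential-expression filter |
| `region_classes` | per-TF max-normalised occupancy rows; K-means dependence classes; selection of k by robustness of downstream gene-proximity enrichment |
| `enrichment` | motif-pair centre-to-centre distance histograms vs a within-region shuffle background with per-bin Poisson right-tail p-values; hypergeometric right-tail proximity scans of differentially expressed genes near region classes over distances in [1, 10⁶] bp |
| `trend` | Gaussian-process regression (RBF + noise, marginal-likelihood hyperparameters) of z-scored binding fold change against motif-variant composition; single-site region selection; a one-sided Wilcoxon test of greater-than-additive double-depletion effects; fold-change Pearson correlations between contrasts |
| `synthetic` | parameterised studies with planted motifs, spacings, dependence classes, NB counts and gene–region links (presets: `null`, `spacing`, `classes`, `full`, `gradient`) |

## Worked example

Run the complete pipeline on a synthetic study with planted truth:

```sh
duoreg run --preset full --seed 3 --outdir run/
```

This generates a 2 × 10 Mb genome with 1000 bound regions in five planted
dependence classes, scans motifs, tests differential binding, clusters
occupancy, and computes both enrichment statistics. Inspect the motif-pair
spacing curve:

```sh
$ head -4 run/pairdist.tsv
# duoreg 0.1.0 stage=pairdist preset=full seed=3
grid	observed	expected	pvalue	neglog10p
0	0	17.81	1	-0
10	6	18.56	0.999786	9.27811e-05
```

and its peak (the planted 50 ± 5 bp half-site↔Oct/Sox spacing):

```sh
$ sort -t$'\t' -k5 -gr run/pairdist.tsv | head -2
50	172	17.17	4.36227e-107	106.36
40	137	16.2	1.05214e-76	75.9779
```

The bins starting at 40 and 50 bp hold 309 observed motif pairs against ~17
expected per bin under the shuffle background — the planted spacing stands
out at −log₁₀p ≈ 106. The cooperativity summary in `run/coop.tsv` reports
the greater-than-additive test over the 768 single-half-site regions
(median delta −0.41 log₂, Wilcoxon p ≈ 7×10⁻²³), and `run/assignment.tsv`
holds the five recovered occupancy classes.

## Layout

```
src/duoreg/
  core_io.py        FASTA/BED/JASPAR/TSV readers-writers, shared types
  motifs.py         half-site and PWM scanning, variant classes, profiles
  binding.py        peak-set logic, normalisation, NB differential test
  region_classes.py occupancy K-means and k selection
  enrichment.py     pair-distance Poisson and proximity hypergeometric scans
  trend.py          GP trend, single-site additivity, correlations
  synthetic.py      planted-truth study generator and presets
  pipeline.py       staged runner with manifest and per-stage seeds
  cli.py            `duoreg` command-line interface
```

See `docs/methods.md` for the statistical models, parameter defaults and
the limits of what the synthetic studies can show.
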