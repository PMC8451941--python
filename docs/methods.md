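# Methods

This note documents the statistical models behind `duoreg`, the defaults
that matter, the structure the synthetic-data generator plants, and the
design choices made where several formalisations were defensible.

## Motif model

The binding element is the 9-bp extended half-site `TCAAGG(T/C)CA`.
Scanning is plain Hamming matching of a consensus over every window of both
strands with 0 or 1 mismatches allowed (`N` in the sequence never matches a
constrained position). The trimmed form `TCAAGGXCA` leaves the seventh base
entirely free and excludes it from the mismatch count; each hit records the
base actually read at that position in motif orientation (`T`, `C` or
`other`). Pinning the discriminating base this way prevents a T-variant
site with a mismatch *at* position 7 from being miscounted as a C site —
the alternative (tolerating a mismatch at position 7 in the variant
consensi) is ambiguous and is deliberately not used.

Conventions: a hit's offset is the leftmost base of the match on the
region's + strand regardless of hit strand (one coordinate convention for
all distance computations); overlapping hits are all reported, with no
masking. PWM scoring is the summed per-position log₂ odds of the
pseudocount-adjusted frequency (default pseudocount 0.5) over a background
(default uniform); `N` scores as the column minimum.

Region variant classes (T-only / C-only / both / none) come from the
seventh bases of trimmed-half-site hits at ≤1 mismatch. The seventh-base
frequency profile tiles regions ranked by the binding ratio
log₂((RPM_Esrrb + c)/(RPM_Nr5a2 + c)), c = 0.5 RPM to guard zeros, into
windows (default 100 regions, tiled; sliding is available) and reports the
T and C hit fractions per window.

## Count model and differential testing

Counts are modelled as negative binomial with variance μ + αμ². Size
factors are median-of-ratios by default — appropriate for expression data
where most units are unchanged. For binding counts the package offers
sequencing-depth size factors (`normalisation="library"`, the RPM
convention): when occupancy collapses globally in a depletion condition,
median-of-ratios has no null anchor and would absorb most of the signal,
whereas sequencing depth is measured independently of on-region binding.
The pipeline uses depth normalisation for its ChIP stages.

Per-unit dispersions are method-of-moments estimates from within-condition
residuals, winsorised to within 8× of a fitted mean–dispersion trend
α(μ) = b₀ + b₁/μ and shrunk toward the trend with weight 0.5 on the log
scale (floor 10⁻⁸). The Wald statistic is the log fold change of
pseudocounted condition means (pseudo 0.5 normalised counts) over a
delta-method standard error; p-values are two-sided normal and BH-adjusted.
With one replicate per condition the trend dispersion is used alone and
results are flagged. Measured on the generator's null (200 regions,
α = 0.1, 3 vs 3, 20 replicate simulations) the rejection rate at nominal
0.05 is ≈ 0.08.

Differential-expression calls use the standard filter: some condition has
all replicates at ≥ 20 raw counts, |FC| > 1.5 (strict), FDR < 0.01.
Binding calls default to FDR < 0.05. Both are configurable.

## Occupancy classes and choosing k

For each TF the per-region vector of mean RPM across conditions is divided
by its maximum ("the condition displaying maximal binding is set to one";
all-zero vectors are flagged and left at zero). K-means (k-means++,
n_init = 10, max 300 iterations, tol 10⁻⁶, seeded) clusters the
max-normalised Oct4/Sox2/Nanog columns only; receptor columns are carried
for display but excluded from clustering. Labels are renumbered by
descending cluster mean of the double-depletion columns so numbering is
initialisation-independent.

k is selected by the robustness of downstream gene-proximity enrichment.
The criterion implemented here: partition the called DE genes into
(contrast × direction) groups; a clustering *resolves* the groups when
every group can be assigned its own distinct cluster with hypergeometric
min-p < 10⁻³ somewhere on the distance grid (maximum bipartite matching);
k is robust when ≥ 4 of 5 re-seeded clusterings resolve, and the selected
k is the first robust candidate. This formalisation was chosen over the
looser "every cluster is enriched" reading because the looser rule cannot
reject k below the true class count — merged clusters still contain linked
regions and stay enriched — and never accepts any k when some class is
genuinely unlinked. Requiring each responsive gene group to find its own
cluster is what "enrichment is robust" has to mean for k to be
identifiable, and it recovers the planted class count on synthetic studies
(and the planted count of 2 when only two linked classes exist). All
thresholds (10⁻³, 4/5, grid) are parameters.

## Enrichment statistics

**Motif-pair spacing.** Within each region, all half-site × partner-motif
pairs contribute the absolute distance between motif centres
(centre = offset + ⌊length/2⌋) to a histogram (default 10-bp bins over
[0, 500] bp). Self-pairs are excluded when a hit set is paired with
itself; distinct overlapping hits count. The null is generated by
re-drawing each hit's position uniformly over the placements at which its
motif fits inside its own region (per-region hit counts and strands
preserved; default 100 shuffles, seeded); the expected histogram is the
shuffle mean and each bin gets a Poisson right-tail p-value
P(X ≥ obs | λ = expected). Expected 0 with observed 0 gives p = 1;
expected 0 with observed > 0 gives p = 0 and is flagged degenerate.
p-values are clamped at 10⁻³⁰⁰ before −log₁₀.

A score filter keeping hits strictly above the median score of their hit
set is available for PWM-scored scans. It is not applied in the synthetic
flows: planted consensus instances share one score, and a strict median
filter on an (almost) constant score set is empty by construction.

**Gene proximity.** For each distance x on a log-spaced grid over
[1, 10⁶] bp (default 50 points): N = genes in the universe, K = genes with
TSS within x bp of the region set (inclusive; 0 if the TSS is inside a
region; same chromosome required), n = DE genes, k = DE genes within x;
p = hypergeometric right tail P(X ≥ k). The universe is the annotated
gene set supplied by the caller — in the pipeline, all genes passing the
expression count filter, so the DE set is always a subset. K and k are
non-decreasing in x by construction. No multiple-testing correction is
applied across the grid; curves are reported as raw −log₁₀ p.

## Trend and cooperativity

The trend of binding change against motif composition is an exact GP
regression with an RBF-plus-independent-noise kernel on mean-centred
responses. Hyperparameters start at length-scale = x-range/5, signal
variance = var(y), noise variance = var(y)/10 and are optimised by L-BFGS
on the log marginal likelihood (3 seeded restarts); ill-conditioned kernel
matrices receive escalating jitter (recorded, capped at 10⁻⁴). The
pipeline aggregates regions into rank bins of the per-region C-variant
share before fitting, which keeps the solve small and the trend readable.
Posterior mean ± 1 s.d. of the latent function is reported.

Cooperativity is assessed at single-site regions — exactly one
recognisable half-site — where both receptors necessarily act at the same
base pairs. For aligned log₂ fold changes of a third TF under the two
single depletions and the double, delta = fc_double − (fc_E + fc_N);
greater-than-additive loss is a one-sided Wilcoxon signed-rank test of
delta < 0 (zeros rank-split, normal approximation; < 6 regions is
reported not-computable). Fold-change correlations between contrasts are
Pearson r over genes called DE in either contrast (union; intersection
available).

## Synthetic studies

The generator writes an i.i.d. background genome at a stated GC (default
0.42), places non-overlapping 400-bp regions on a slot grid, and
overwrites the background with motif instances (no blending — truth is
unambiguous and rescanning recovers plants exactly). Each region gets one
half-site with a class-dependent probability of the C variant; optionally
an Oct/Sox composite element is added, either uniformly placed (avoiding
the half-site footprint) or at a planted centre distance ± jitter. The
Oct/Sox element is a synthetic composite consensus (CTTTGTTATGCAAAT — a
Sox element followed by the reverse octamer) built for simulation, not a
database matrix. Counts are NB with shared dispersion α = 0.1, region
baselines log-normal around 100, per-sample library factors in
[0.7, 1.3], sequencing depth 2×10⁷ × factor, and per-class planted log₂
fold changes per TF and condition. Genes are placed uniformly except for
linked DE groups, a stated fraction of which (default 0.8) sit within a
stated distance (default 5 kb) of a region of their designated class; DE
tables carry planted fold changes and FDRs consistent with direction.

Preset scales: `null`, `spacing` and `gradient` use 2 × 1 Mb and 2000
regions; `classes` and `full` use 2 × 10 Mb and 1000 regions. The larger
genome for the proximity-bearing presets is deliberate: the scan needs the
region footprint to cover a minority of the genome at kilobase distances,
otherwise every gene is near some region and K approaches N. The planted
class effects (five classes: either-receptor-sensitive; Esrrb-dependent;
Nr5a2-dependent; double-depletion-only; gaining on double depletion) are
separated by ≥ 1 log₂ between classes, which with α = 0.1 and 3 replicates
leaves class recovery comfortably above ARI 0.7 while keeping single-region
calls noisy — deliberately not a trivial recovery problem.

What the synthetic studies do *not* emulate: read-level artefacts
(fragment length, GC bias, duplicates), mappability structure, motif
degeneracy beyond the planted consensus (plants are exact, so scanner
sensitivity to weak sites is exercised only by the PWM path), correlated
replicates, and realistic gene density or regulatory-domain structure.
Passing tests therefore demonstrate correctness and calibration of the
statistics under the stated model, not performance on real libraries.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds; the pipeline expands one
top-level seed into per-stage seeds by CRC-32 of the stage name. TSV
floats are written at 6 significant digits, making repeated runs
byte-identical; a JSON manifest records config, per-stage seeds and
SHA-256 digests of every output. Degenerate inputs are handled as stated
inline: all-zero units (p = 1, flagged), zero occupancy rows (flagged, set
to 0), empty hit sets (empty outputs), hits that cannot fit their region
when shuffling (skipped), fewer than 3 shared genes in a correlation or
fewer than 6 regions in the additivity test (not-computable flags).
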