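# Methods

This note records the models, defaults and design decisions behind each
module, what the synthetic generators do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort subgrouping

Records are classified from the annotation vocabulary
(`Missense_Mutation`, `In_Frame_Del/Ins`, `Nonsense_Mutation`,
`Frame_Shift_Del/Ins`, …) — never from the protein-change string, which is
parsed separately for residue positions (dialects `p.X###Y`, `X###Y`,
`###_###del`, `X###fs`, `X###*`; anything else yields a missing residue and
a logged warning). The "truncating" group defaults to nonsense mutations
alone; frameshifts are kept as their own subgroup so the caller can merge
them when the broader definition is wanted.

Domain intervals are closed and matched in declaration order, with the more
specific Wing2 (247–269) declared before the enclosing Forkhead domain
(168–269) so that Wing2 residues resolve to Wing2. The boundaries are a
literature convention and fully configurable, as is the whole map.

Patients contributing several samples are counted once in patient totals;
case totals de-duplicate on sample id. The inframe-indel hotspot share at
M253/F254 is reported descriptively (`indel_hotspot_fraction`) because
published accounts of that share conflict; the module measures and takes no
side.

`synthetic.make_reference_cohort()` is a deterministic synthetic
reconstruction realizing exactly the published cohort marginals
(991 mutations; 686 primary / 305 metastatic; 339/335/287
missense/indel/nonsense; 906 cases; 874 patients; the 30 residual records
are split 20 frameshift / 10 other). It stands in for the deposited
per-patient table, which is not redistributed here; only the marginals are
faithful, not the per-patient structure.

## QC filters

Boundary handling is uniform: the published rules are strict inequalities
on the removal side ("fewer than 500", "greater than 40%", "<4"), so
equality keeps the cell — totals of exactly 500 or 100000, mitochondrial
fraction exactly 0.40, TSS enrichment exactly 4.0, 1000 fragments and
exactly 1M reads all survive.

The TSS enrichment statistic is this package's contract (the published
analysis delegates it to its toolkit without defining it): per-bp fragment
coverage over TSS ± 50 divided by per-bp coverage over the distal flanks
[−2000, −1901] ∪ [+1901, +2000], with pseudo-coverage 0.1 added to the
denominator. Cells with no fragments score 0. The read ceiling is applied
to total reads; whether the published rule means reads or fragments is
ambiguous, and the threshold object exposes both fields.

Mitochondrial genes are identified by configurable name prefixes
(`mt-`, `MT-`) or an explicit id set; ids absent from the feature list are
dropped with a warning and the fraction is computed over the intersection.

## Lineage scoring and mixture classification

Expression is normalized as `log(1 + 1e4·x/total)`; this log-CPM transform
replaces the published variance-stabilizing normalization with cell-cycle
and mitochondrial regression, which is out of scope — signature scores are
z-standardized afterwards, which absorbs most of the difference in scale
but not the variance stabilization itself.

Signature scores use per-gene z-scores across units with sample (ddof=1)
standard deviation; zero-variance genes contribute 0 rather than being
dropped, preserving signature length. The score matrix feeds the mixture on
all three signature axes (the alternative luminal-vs-basal contrast is
supported by passing a 1-D score).

The Gaussian mixture is fitted by EM with diagonal covariances (a
full-covariance option exists but is not default: at 3 dimensions and a few
thousand cells the diagonal family is stable and the published toolkit's
automatic family selection is not reproduced here). Initialization is
seeded k-means++; EM runs from 5 initializations and keeps the highest
final log-likelihood, guarding against single-start local optima.
Convergence is a relative log-likelihood gain below 1e-6 (max 500
iterations); a component variance collapsing below 1e-8 triggers a
re-seeded restart (max 5) before erroring. The log-likelihood trace is
recorded and is non-decreasing by construction of EM; the final element is
clamped against sub-tolerance floating-point dips.

Components are mapped to lineages by maximum-weight bipartite assignment
between component means and score axes. Discrete fates are
maximum-posterior with ties to the lower component index. Ternary
coordinates use the standard barycentric embedding with vertices (0,0),
(1,0), (1/2, √3/2); the embedding is exactly invertible for valid
posteriors. Proportion fold changes against a reference group report a
zero reference fraction as infinite with an `unbounded` flag.

## Motif scanning and enrichment

PWM files are parsed with Bio.motifs (JASPAR and minimal MEME). Counts are
made column-stochastic with a pseudocount (default 0.8, distributed by
background composition); an all-zero column becomes uniform. Log-odds
scores treat the stored probabilities as frequencies from 100
count-equivalents, so a deterministic column scores ≈ log2 4 under a
uniform background.

The hit threshold for p = 5e-05 is computed by dynamic programming over the
null score distribution. When every distinct partial sum fits in memory
(≤ 2·10⁶ states) the DP is exact, and — because it accumulates scores in
the same left-to-right order as the scanner — the threshold is bit-identical
to an achievable window score; for wider or denser matrices the entries are
*ceiled* onto a grid of 1/1000 of the score range, which can only overstate
word scores and therefore keeps the true false-positive rate at or below p.
(Flooring, the intuitive choice, is anti-conservative: it understates the
tail.) When no achievable tail is ≤ p — e.g. any width-7 motif under a
uniform background, where each word has probability 4⁻⁷ ≈ 6.1e-05 — the
maximum score plus epsilon is returned with a warning, so nothing is
called. The published scanner's "discovery window of 7 nt" is a lookahead
performance parameter of that library, not a semantic one, and is not
reproduced; results are defined solely by the p-value threshold. Background
nucleotide frequencies default to uniform and are configurable (the
published analysis uses mouse genome background).

Both strands are scanned; windows containing N are skipped. The binomial Z
statistic is `(C − Np)/√(Np(1−p))`; p ∈ {0, 1} has undefined variance and
such rows are flagged with Z = NaN rather than fabricated.

chromVAR-style deviations use the cell-depth × peak-mean expectation;
each motif's raw deviation is standardized against ≥ 10 (default 50)
background peak sets drawn within matched deciles of (GC, mean
accessibility). "Significant" deviation — undefined in the published text —
is operationalized as mean |z| exceeding the 95th percentile of the
matched-background null (resampled with the caller's seed); motif selection
additionally requires positive Spearman correlation with the motif's TF
expression at BH-adjusted p < 0.05. Motifs with fewer than 5 member peaks
are excluded with a warning.

## Peak atlas

Summit standardization produces [summit − 250, summit + 251), width 501,
clipped at chromosome bounds when sizes are provided. Blacklist filtering
removes any ≥ 1 bp overlap under the half-open convention. Atlas merging
iteratively retains the highest-scoring peak and discards overlaps; ties
break by (chrom, start), making the result order-invariant. IDR replicate
filtering is consumed, not reimplemented: the module accepts pre-filtered
peak lists.

Median-of-ratios normalization follows the DESeq2 definition exactly
(rows with any zero are excluded from the geometric-mean reference); it is
cross-checked against pydeseq2 in the tests. Note the factors are
equivariant only up to the reference's response: scaling one of *m* sample
columns by *k* scales its factor by k^((m−1)/m), not by *k*, because the
scaled sample also moves the geometric means.

The differential test is Welch's t on log2(normalized + 1) with BH
adjustment — a deliberate, documented substitute for the published
dispersion-modeled engine; the selection thresholds (|log2FC| ≥ 0.5
inclusive, padj < 0.05) are preserved verbatim and the selection rule can
be applied to externally computed statistics. The one-sided variant
(`two_sided_abs=False`) matches the alternative published phrasing.

## Enhancer linking

Windows are [gene start − 250 kb, gene end + 250 kb), tiled into 500-nt
half-open bins (a 10-kb gene gives 1020 tiles). The regression is Poisson
with log link, offset log(depth), and an L2 penalty on slopes only;
λ ∈ {0.01, 0.1, 1, 10, 100} is chosen by minimum mean held-out deviance
over a seeded 5-fold split, then the model is refit on all cells. The IRLS
solver uses step-halving on the penalized deviance and clips the linear
predictor to ±30 against overflow; it is cross-checked against the
statsmodels GLM at near-zero penalty.

Shapley values are computed on the linear-predictor scale, where they are
exact for an additive model: `φ_t(c) = coef_t · (acc_ct − mean_c acc_t)`,
with efficiency `Σ_t φ_t(c) + base = η_c − offset_c` holding to machine
precision. Response-scale attribution is out of scope. Scores are averaged
within cell states; note that averaging over *all* cells gives identically
zero (the contributions are centered), so per-state grouping is not
optional.

Per gene, tile scores are standardized across the gene's tiles
(genome-wide standardization is offered as an option but within-gene is the
default, matching per-gene ranking). The "gene length" adjustment is not
defined in the published text; this package divides z by `√(2 ln n_tiles)`,
the leading-order growth rate of the expected maximum of n independent
standard normals, so the top tile of a 10000-tile window is not favoured
over the top tile of a 100-tile window merely by multiplicity. Two genes
with identical z but 100 vs 10000 tiles differ in adjusted z by exactly
`√(ln 10000/ln 100) = √2`.

The integration score aligns all component vectors per tile and sums
`z_adj · atac_norm · chip_norm` over tiles satisfying both the accessible
AR-motif mask and the ChIP-peak mask (the operand alignment is unspecified
in the published text; per-tile alignment over doubly-qualified tiles is
this package's reading of "overlap of these signals"). ATAC and ChIP
vectors are counts-per-million within their assay on per-state pseudobulk;
alternative normalizations plug in. Ranking is by descending score with
alphabetical ties.

## Synthetic data: what it emulates and what it does not

RNA counts are negative-binomial per gene (dispersion 0.3, gamma–Poisson
sampling) around lognormal base abundances scaled to a mean depth of 5000;
each lineage's signature genes (30 per lineage, disjoint) are shifted by
`effect_size` (default 1.0) on the log scale in that lineage. ATAC counts
are Bernoulli × (1 + Poisson): peaks open with probability 0.55 in their
own lineage, 0.05 elsewhere, 0.30 for shared peaks. Default lineage
proportions are 6% basal / 28% L2 / 66% L1 over 3000 cells, echoing a
truncation-mutant culture dominated by L1 cells. Peak sequences are 501-nt
i.i.d. nucleotides at GC 0.42; planted motif instances are sampled
column-wise from the PFM on a uniformly chosen strand at a configurable
per-lineage rate (default 0.6 of a lineage's specific peaks for that
lineage's motif). The built-in motif set contains synthetic analogues of
the relevant site classes (ARE half-site + FOXA1 composite, canonical
inverted-repeat ARE, POU octamer, GATA site, p53-family half-site) built
from consensus sequences with 0.88 dominant-base probability — they are
stand-ins, not matrices exported from any database.

The enhancer-truth generator draws sparse accessibility (zero-inflated,
open rate 0.2) and Poisson expression with
`log rate = log(depth) + intercept + Σ β_t·acc_t + N(0, noise_sd)`, the
same offset convention the regression assumes. With `active_open_rate`
set, causal tiles open at that rate in an "active" half of the cells and at
a quarter of the background rate elsewhere, giving the state-biased
accessibility that per-state Shapley means detect. The QC fixture
constructs disjoint violation classes (each failing cell violates exactly
one rule; passing cells sit safely inside all thresholds), so expected
filter counts are exact, not probabilistic.

Not emulated: read-level data (FASTQ, fragments files), doublets, ambient
RNA, batch effects, chromosomal structure (peaks are abstract ids, not
coordinates), linkage between the RNA and ATAC modalities beyond shared
lineage labels, and realistic motif co-occurrence. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
statistical model, not performance on real multiome data, where
separations are weaker and the noise is structured.

## Problem sizes and numerical choices

The recovery experiments run at deliberately moderate scale — 3000 cells
for mixture recovery, 400 peaks × 20 replicates for motif enrichment,
600 cells × 40 tiles × 21 genes × 20 replicates for TF nomination — sizes
at which the planted effects are comfortably detectable and a full suite
run stays fast on one CPU. Tolerances: posterior rows and mixture weights
sum to 1 within 1e-9; Shapley efficiency holds to 1e-9 (observed at machine
precision); the threshold DP is exact for widths where enumeration is
feasible and conservative otherwise; EM tie-breaks and ranking ties are
deterministic (lower index, alphabetical). All randomness flows through
explicit integer seeds; identical configuration reproduces byte-identical
outputs.
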