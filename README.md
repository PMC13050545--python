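# multifate

Single-cell multiome analysis of epithelial lineage fate in FOXA1-mutant
prostate cancer: mutation-cohort subgrouping, RNA/ATAC quality filtering,
Gaussian-mixture fate assignment, motif enrichment, peak-atlas
normalization and an integration score that ranks androgen-receptor (AR)
regulated transcription-factor targets. A seeded synthetic-data module
generates every input the pipeline consumes, with planted ground truth, so
each stage can be validated by recovery experiments.

## The problem

FOXA1 is a pioneer transcription factor recurrently mutated in prostate
cancer. Its mutations fall into three subgroups — Wing2 missense, Wing2
inframe indels (hotspots at M253/F254) and C-terminal truncations — that
bias prostate epithelial cells between three states: basal, differentiated
secretory luminal (L1) and stem-like proximal luminal (L2). The package
implements the quantitative core of that analysis:

- **Cohort subgrouping** (`multifate.cohort`). A MAF-like table of somatic
  FOXA1 mutations is classified from its annotation column into
  missense / inframe-indel / nonsense / frameshift / other, localized onto
  protein domains (Wing2 247–269, Forkhead 168–269, C-terminus 270–472,
  configurable) and summarized by tumor site.
- **QC filters** (`multifate.qc`). RNA cells are kept with transcript
  totals in [500, 100000] and mitochondrial fraction ≤ 0.40; ATAC cells
  with TSS enrichment ≥ 4, ≥ 1000 unique fragments and ≤ 1M reads.
  Equality always keeps the cell.
- **Lineage scoring** (`multifate.lineage`). A unit's epithelial output
  score for signature *S* is `Σ_{g∈S} z_g`, with per-gene z-scores taken
  across units (sample sd). Score matrices are classified by a K-component
  diagonal-covariance Gaussian mixture fitted by EM (K=2 luminal/basal,
  K=3 basal/L1/L2); fates are maximum-posterior assignments, summarized by
  ECDFs, ternary coordinates and proportion fold changes.
- **Motif enrichment** (`multifate.motifs`). PWMs are scored as log2 odds
  against a background model; hit thresholds are calibrated by dynamic
  programming so a random background word passes with probability ≤ 5e-05.
  Per-cluster enrichment uses the binomial Z statistic
  `Z = (C − Np)/√(Np(1−p))` for *C* motif-bearing peaks among *N* cluster
  peaks with background rate *p*. chromVAR-style deviations, standardized
  against GC/accessibility-matched background peak sets and filtered by
  positive Spearman correlation with TF expression, select motifs.
- **Peak atlas** (`multifate.atlas`). narrowPeak entries are re-centered
  at summits ± 250 nt (501-nt width), blacklist-filtered, merged by
  iterative highest-score retention, normalized with median-of-ratios size
  factors, and tested for differential accessibility
  (|log2FC| ≥ 0.5, BH-adjusted p < 0.05).
- **Enhancer linking** (`multifate.linking`). Gene windows (gene body
  ± 250 kb) are tiled into 500-nt bins; a ridge-penalized Poisson
  regression with log-depth offset predicts expression from tile
  accessibility; tile importance is the exact Shapley value of the linear
  predictor, `coef_t · (acc_t − mean acc_t)`, standardized per gene and
  length-adjusted by `√(2 ln n_tiles)`. The per-gene integration score is
  the dot product of length-adjusted z, normalized ATAC and normalized
  ChIP signal over tiles carrying both an accessible AR motif and a ChIP
  peak; candidate TFs are ranked by this score.

## Worked example

```python
import tempfile, numpy as np, pandas as pd
from pathlib import Path
from multifate import synthetic, cohort, lineage

# 1. cohort: reconstruct the reference mutation table and summarize it
path = Path(tempfile.mkdtemp()) / "foxa1_cohort.tsv"
synthetic.make_reference_cohort().to_csv(path, sep="\t", index=False)
summary = cohort.summarize_cohort(cohort.parse_maf(path))
print(summary.counts)
fr = cohort.subgroup_fractions(summary)
print(f"missense+indel: {fr['missense']+fr['inframe_indel']:.0f}%  "
      f"truncation: {fr['nonsense']:.0f}%")

# 2. lineage: simulate a 3000-cell multiome and recover the planted fates
cfg = synthetic.SimConfig(seed=0)
rna, atac, seqs, truth = synthetic.gen_multiome(cfg)
expr = pd.DataFrame(lineage.normalize_expression(rna.X),
                    index=rna.obs_names, columns=rna.var_names)
sigs = [lineage.GeneSignature(name=k, genes=tuple(v))
        for k, v in truth.signatures.items()]
scores = lineage.score_matrix(expr, sigs)
fit = lineage.fit_gmm(scores.to_numpy(), K=3, seed=0)
labels = lineage.classify_units(
    fit, lineage.match_components(fit, list(scores.columns)))
print("agreement with planted labels:",
      f"{(labels == truth.lineage_labels).mean():.1%}")
```

prints

```
               primary  metastasis
missense           239         100
inframe_indel      234         101
nonsense           191          96
frameshift          14           6
other                8           2
missense+indel: 68%  truncation: 29%
agreement with planted labels: 100.0%
```

The cohort table carries 991 mutations (686 primary, 305 metastatic) over
906 cases from 874 patients; missense and inframe indels together account
for 68% of mutations and truncations for 29%. On the default synthetic
multiome (3000 cells, 6% basal / 28% L2 / 66% L1), the three-component
mixture recovers every planted lineage label.

## Command line

Each stage is also a `multifate` subcommand writing a `manifest.json`
(inputs, parameters, seed, output checksums):

```sh
multifate --seed 7 --outdir out simulate
multifate --seed 7 --outdir out qc      --simdir out/simulate
multifate --seed 7 --outdir out lineage --simdir out/simulate
multifate --seed 7 --outdir out motif   --simdir out/simulate
multifate --seed 7 --outdir out atlas   --counts out/simulate/pseudobulk_counts.tsv
multifate --seed 7 --outdir out link
multifate --seed 7 --outdir out cohort  --maf out/simulate/cohort.tsv
```

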