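# vasculotype

Analysis toolkit for expression profiles of microdissected (tumor)
vasculature: unsupervised discovery of vascular expression subtypes,
empirical-Bayes moderated differential expression, pericyte-marker
characterisation, gene-signature overlap and induced-segregation testing,
and a subtype-adjusted recurrence predictor evaluated under nested
leave-one-out cross-validation. A synthetic cohort generator with planted
ground truth makes the whole pipeline testable without any external data.

## What it does

- **`vasculotype.simulate`** — synthetic log2 expression cohorts
  (default: 15 normal + 9/8 tumor samples, 5 recurrent) with planted
  tumor, subtype, pericyte-marker and recurrence effects, gene-specific
  variances drawn from a scaled inverse chi-square prior, and full ground
  truth (`SynthTruth`).
- **`vasculotype.expression`** — matrix/annotation I/O (TSV/CSV), probe
  collapsing by maximal IQR, strict `IQR > t` variance filtering, row
  Z-scoring, gene-set readers (plain/GMT).
- **`vasculotype.cluster`** — correlation distance, Lance–Williams Ward
  linkage (classical variant by default, squared behind a flag), tree
  cutting, gene-resampling bootstrap clade support, PCA sample summaries,
  Newick export.
- **`vasculotype.de`** — two-group fits, method-of-moments estimation of
  the variance-moderation prior (trigamma inversion), moderated t tests,
  Benjamini–Hochberg FDR, Wilcoxon rank-sum (exact for small groups) and
  Welch t.
- **`vasculotype.subtypes`** — pericyte-marker scoring/ordering, Spearman
  correlation, Fisher exact tests, gene-set overlap, signature-induced
  segregation (ARI + misassignment), clinical-covariate association.
- **`vasculotype.predictor`** — per-gene inter-subtype mean adjustment,
  Wilcoxon top-k gene selection, pooled-covariance LDA, nested LOOCV with
  every data-dependent step inside the fold, and a gene-set-size scan.
- **`vasculotype.pipeline`** — end-to-end orchestration with YAML config
  and a JSON report bundle.

## CLI

```sh
vasculotype simulate --seed 1 --out cohort/
vasculotype cluster  --matrix cohort/matrix.tsv --iqr-threshold 2 \
                     --boot 10000 --seed 0 --k 2 --out clusters/
vasculotype de       --matrix cohort/matrix.tsv --annot cohort/samples.csv \
                     --contrast B_vs_A --out de.tsv
vasculotype markers  --matrix cohort/matrix.tsv --genes ACTA2,PDGFRB,RGS5,LAMB1 \
                     --annot cohort/samples.csv --out markers/
vasculotype overlap  --a sigA.txt --b sigB.txt --universe universe.txt
vasculotype induce   --matrix cohort/matrix.tsv --signature sig.txt \
                     --annot cohort/samples.csv
vasculotype predict  --matrix cohort/matrix.tsv --annot cohort/samples.csv \
                     --k 6 --scan 2:100 --out pred/
vasculotype run      --matrix cohort/matrix.tsv --annot cohort/samples.csv \
                     --out full/ --iqr-threshold 2 --boot 10000
```

All commands are deterministic given their inputs and seeds.

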