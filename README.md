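# isomir-prognosis

Analysis pipeline for prognostic 5' isomiRs in tumor expression data:

- **Annotation / quantification** — parses miRBase-style GFF3 and GDC-style
  `isoforms.quantification.txt` tables, computes strand-aware signed 5'
  shifts (`MIMAT0000062|-2` style labels, shift 0 = archetype), aggregates
  reads into an isomiR count/RPM matrix, and reconstructs isomiR sequences
  and seed regions.
- **Survival screen** — per-isomiR multivariate Cox proportional-hazards
  models (expression + age + cigarettes/day + T stage) with an EPV-based
  dead-sample expression filter; features are classed protective (β < 0)
  or harmful (β > 0) at Wald p < α. The Cox engine is a Newton–Raphson
  maximizer of the partial likelihood with the Efron tie correction.
- **Differential expression** — upper-quartile (isomiRs) and TMM (genes)
  normalization to log2-CPM, then an empirical-Bayes moderated t with
  Benjamini–Hochberg adjustment.
- **Target consensus** — ≥3-of-4 consensus over external predictor pair
  tables, crossed with DE directions and survival classes; a canonical
  seed-matcher ships as a test-fixture predictor.
- **Co-expression network** — pairwise Spearman correlation on non-zero
  sample intersections, z-score significance calls with group enrichment
  tests, and top-fraction/degree-pruned edge selection.
- **Figure statistics** — exact Fisher tests, rank-sum tests, shift
  preference analysis, PCA + PERMANOVA, logistic ROC/AUC, hypergeometric
  gene-set over-representation.
- **Synthetic data** — a seeded generator that emits every input file the
  pipeline consumes (GFF3 + genome FASTA, per-sample isoform tables, gene
  counts, clinical table, predictor tables, GMT) with planted ground truth
  for recovery testing. No downloads required anywhere.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` implements the acceptance criteria (oracle
equality checks, null calibration, planted-effect recovery, end-to-end
byte determinism).

## CLI

```sh
isomir-prognosis simulate --seed 1 --out inputs/
isomir-prognosis quantify --gff inputs/annotation.gff3 --input-dir inputs/isoforms --out matrices/
isomir-prognosis survival-screen --rpm matrices/isomir_rpm.tsv \
    --counts matrices/isomir_counts.tsv --clinical inputs/clinical.tsv \
    --alpha 0.05 --dead-fraction 0.5 --ties efron --out screen.tsv
isomir-prognosis de --counts matrices/isomir_counts.tsv --groups groups.tsv --adjp 0.01 --out de.tsv
isomir-prognosis targets --prediction-dir inputs/predictions --min-support 3 --out pairs.tsv
isomir-prognosis network --rpm matrices/isomir_rpm.tsv --top 0.05 --z 2 --out edges.tsv
isomir-prognosis run-all --seed 1 --out pipeline_out/
```

`run-all` accepts a YAML config (`--config`); flags override it, and every
run writes a `manifest.json` with seeds, thresholds, per-stage counts and
(on synthetic runs) planted-truth recovery metrics.

## Notes and documented choices

- Expression enters Cox models as log2(RPM+1); `raw` is available.
- Rows with equal (accession, shift) but different 3' ends are summed
  before analysis; 3'-only variation is not a separate feature class.
- "Expressed" in the EPV filter means read_count > 0.
- The Wald p gates the significance call; the likelihood-ratio p is
  reported alongside.
- The top-5% network selection takes the intersection of the by-rho and
  by-p lists; degree pruning iterates to a fixed point.
- isomiR DE significance uses the BH-adjusted p by default (raw available).
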