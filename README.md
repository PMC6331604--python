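# apscore

Astrocytoma progression (AP) scoring: construction and evaluation of a
two-gene-set prognostic signature for diffuse astrocytoma / glioblastoma
expression cohorts.

The package implements, end to end:

- **Gene selection** (`apscore.selection`) — a five-criterion cascade:
  (i) differential expression tumour vs normal, (ii) differential expression
  GBM vs LGG (both at BH-FDR `q < 0.01` and `|logFC| >= 1.5`), (iii) high
  variability (scaled MAD > 1.0), (iv) consistent logFC sign across the two
  contrasts, and (v) per-gene prognostic relevance (median-split log-rank
  `p < 0.05`). Output: the POS_AP / NEG_AP gene-set pair plus a per-gene
  audit table.
- **Scoring** (`apscore.scoring`) — single-sample rank-weighted running-sum
  enrichment (ssGSEA-style, `alpha = 0.25`, global range normalization);
  `AP score = POS_AP score − NEG_AP score` per sample.
- **Survival statistics** (`apscore.survival`) — Kaplan–Meier product-limit
  curves with median survival, two-group log-rank test with the
  Mantel–Haenszel hazard ratio, and Cox proportional-hazards regression
  (Newton–Raphson, Efron ties), all implemented from explicit formulas.
- **Association statistics** (`apscore.association`) — ANOVA,
  chi-square/Fisher contingency tests, Pearson correlation, paired/Welch t,
  ROC-AUC with mean-OS outcome labelling, logistic factor combination,
  mutation-frequency and CNV group comparisons, gene–score correlation and
  immune-set enrichment reports.
- **Synthetic cohorts** (`apscore.synthetic`) — a seeded generator producing
  NT/LGG/GBM expression with planted monotone progression genes, survival
  coupled to a latent progression axis, clinical covariates, mutation and
  CNV panels, and paired primary–recurrent samples — so the whole pipeline
  is testable offline.
- **Pipeline + IO** (`apscore.pipeline`, `apscore.data_io`) — TSV/GMT
  readers/writers, subgroup evaluation with global-median dichotomization,
  and a deterministic orchestrated run writing TSV reports and a
  `summary.json`.

A packaged 18-gene signature (`POS_AP`, 12 genes; `NEG_AP`, 6 genes) ships
as `apscore/data/ap_signature.gmt` for scoring real cohorts; `apscore score`
uses it by default.

## CLI

```bash
apscore simulate    --outdir run/sim --seed 1            # synthetic cohort TSVs
apscore select-genes --expression run/sim/expression.tsv \
                     --clinical run/sim/clinical.tsv --outdir run/sel
apscore score       --expression run/sim/expression.tsv \
                     --gmt run/sel/signature.gmt --out run/ap.tsv
apscore survival    --scores run/ap.tsv --clinical run/sim/clinical.tsv \
                     --outdir run/surv
apscore associate   --scores run/ap.tsv --clinical run/sim/clinical.tsv \
                     --mutations run/sim/mutations.tsv --cnv run/sim/cnv.tsv \
                     --outdir run/assoc
apscore run-all     --outdir run/all --seed 1            # everything at once
```

## File formats

- Expression / CNV: TSV, genes in rows (first column `gene_id`), samples in
  columns; log2 scale for expression.
- Clinical: one row per sample with columns `sample_id, tissue_group,
  os_days, event, age, gender, grade, idh, mgmt, subtype, chemo, radio`;
  `NA` for missing.
- Mutations: long TSV `sample_id, gene, mutated` (0/1).
- Gene sets: standard GMT (name, description, members).
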