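# metasig

A reusable, tested pipeline for building miRNA *meta-signatures* from
study-level differential-expression lists and evaluating their clinical
value:

1. **Ingestion** (`metasig.ingest`) — parse per-study ordered miRNA lists,
   standardize names against a bundled alias map (viral miRNAs and control
   probes excluded), assemble direction-stratified normalized rank matrices
   (rank *j* on a platform of *N* probes → *j/N*; unreported → 1.0), and
   report cross-study bookkeeping (sample totals, recurrence percentages,
   discordant miRNAs).
2. **Robust rank aggregation** (`metasig.rra`) — exact beta
   order-statistic tail probabilities per miRNA, rho scores, per-item
   p-values and Bonferroni correction across the platform.
3. **Diagnostic meta-analysis** (`metasig.diagmeta`) — bivariate
   random-effects ML fit of per-study (logit sensitivity, logit
   specificity), pooled estimates with Wald CIs, summary ROC curve and
   trapezoidal AUC, Deeks' funnel-plot asymmetry test, residual
   diagnostics.
4. **Target/pathway enrichment & co-expression** (`metasig.targets`) —
   hypergeometric over-representation with BH FDR, Fisher combination
   across miRNAs, correlation-distance average-linkage heatmap ordering,
   and Pearson screening of gene expression against miRNA profiles
   (r² and raw-p thresholds).
5. **Survival analysis** (`metasig.survival`) — Newton–Raphson Cox
   partial-likelihood fit (Breslow/Efron ties), risk-score median split,
   Kaplan–Meier curves, log-rank test, hazard ratio with Wald CI.
6. **Synthetic data** (`metasig.simulate`) — seeded generators producing
   inputs with the statistical structure each stage assumes (planted rank
   signal, bivariate-normal 2×2 tables, planted expression correlations,
   proportional-hazards cohorts), so the whole pipeline is testable
   offline.

## CLI

```bash
# generate a full synthetic input bundle
metasig simulate --stage all --seed 42 --out sim/

# run every stage over it
metasig run-all --in sim/ --out results/

# or stage by stage
metasig ingest   --signatures sim/signatures.tsv --metadata sim/study_metadata.tsv --out work/
metasig rra      --matrix work/rank_matrix_up.tsv --direction up --m 2064 --alpha 0.05 --out rra_up.tsv
metasig diagmeta --input sim/diagnostic_tables.tsv --auc-range full --out dm/
metasig enrich   --targets sim/targets.tsv --gmt sim/pathways.gmt --out enr/
metasig coexpr   --mirna-matrix sim/mirna_expression.tsv --expr-matrix sim/gene_expression.tsv \
                 --r2-min 0.1 --p-max 0.01 --out cx/
metasig survival --input sim/survival_cohort.tsv --panel hsa-miR-200a-3p,hsa-miR-200c-3p --out sv/
```

`run-all` writes a `report.json` with the resolved configuration,
per-stage headline numbers, and a SHA-256 checksum for every output file;
reruns with identical inputs are byte-identical.

## File formats

All inputs/outputs are plain text: long-format signature TSVs, rank
matrix TSV (+ sibling `.mask.tsv` carrying the reported mask), 2×2 count
TSVs, GMT gene sets, feature×sample expression TSVs, cohort TSVs
(`patient_id`, `time`, `event`, one column per panel miRNA), and JSON
summaries.
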