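# famnet

Multi-omic analysis of a gene family across paired cancer/normal cohorts,
driven end-to-end by a synthetic cohort generator so no external download is
required. Stages:

- **genomics** — per-gene mutation and copy-number amplification/deletion
  frequencies; Wilcoxon tests of alteration status vs expression; Pearson
  correlation of expression with CNV dosage.
- **differential** — differential expression (Welch t on log2 values,
  Benjamini–Hochberg adjustment, calls at |log2fc| > 1 and adjusted p < 0.05)
  and promoter-methylation beta-mean comparison (Wilcoxon rank-sum,
  delta-beta direction).
- **coexpression** — family co-expression networks with edge significance
  from an empirical null: |Pearson r| over 10,000 random background gene
  pairs per condition; edges kept at empirical p < 0.01; cancer-vs-normal
  rewiring summarized by an exact binomial test on condition-exclusive edges.
- **dysregulation** — TF–target correlation rewiring
  `delta_r = r(cancer) − r(normal)` with label-permutation significance
  (1000 shuffles, p = Σ Sᵢ / N, no small-sample correction), an exhaustive
  enumeration oracle for small instances, BH adjustment per TF, and
  gain/loss pattern calls.
- **clinical** — median-split survival groups (ties to "low"), Kaplan–Meier
  curves, log-rank test, univariate Cox (hand-rolled Newton on the partial
  likelihood, Breslow or Efron ties), and drug-sensitivity screening
  (|PCC| > 0.2 and p < 0.05, both strict) joined into a
  pathway–drug–gene–target axis table.
- **synthetic** — cohort generator planting pair correlations per condition,
  mutation/CNV/methylation effects on expression, exponential
  proportional-hazards survival coupled to one gene, and linear
  expression–IC50 couplings, with a complete ground-truth ledger.

All randomness derives from a single integer seed; reruns are byte-identical.

## CLI

```sh
# generate a synthetic cohort plus a matching pipeline config
famnet simulate --seed 1 --outdir demo/

# run the full pipeline (all thresholds overridable in the YAML)
famnet run --config demo/pipeline_config.yaml

# run one stage, or re-print the summary of a finished run
famnet stage coexpression --config demo/pipeline_config.yaml
famnet report --outdir demo/results
```

Inputs are plain TSVs: expression/CNV/methylation matrices (identifier in
column 1, one header row of sample IDs), a 3-column mutation table
(sample, gene, variant_class), a probe map (probe, gene, region), TF–target
scores (tf, target, score), survival (sample, time, event) and drug tables
(cell_line, drug, ic50) + (drug, target_gene, pathway). Outputs are one TSV
per result table plus `summary.json`, `stage_reports.json` and
`manifest.json`.

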