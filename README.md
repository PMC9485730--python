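# irlncpair

Prognostic modelling of esophageal squamous cell carcinoma (ESCC) from
**immune-related lncRNA pairs**: a reusable, fully offline-testable
implementation of the relative-expression pair-signature workflow used in
radioresistance transcriptomics.

## The problem and who this is for

Radioresistance is a major cause of radiotherapy failure in ESCC.
One line of work screens long non-coding RNAs whose expression tracks
immune genes (*ir-lncRNAs*), asks which of them differ between patients
whose tumours did and did not respond to chemoradiotherapy, and builds a
survival model from them. Because lncRNA abundances are low and
platform-dependent, the model is not built on expression levels but on
**relative ordering within each sample**: for an ordered gene pair A|B the
predictor is

```
indicator(A|B, sample) = 1  if expr(A) > expr(B) in that sample, else 0
```

which needs no cross-cohort normalization. This package is for
bioinformaticians who want that workflow as a tested library and CLI
rather than a one-off script collection.

## The method

1. **Screen** — a lncRNA is immune-related if it correlates with ≥1 immune
   gene at |ρ| ≥ 0.4 and p ≤ 1e-4 (Spearman by default).
2. **Differential expression** — empirical-Bayes moderated t between
   non-responders and responders; genes are called Up/Down when raw
   p ≤ 0.05 and log2FC falls outside mean(logFC) ± 2·sd(logFC).
3. **Pair encoding** — all C(n,2) 0/1 pairs of the DE ir-lncRNAs; pairs
   with pairRatio (fraction of samples scoring 1) outside (0.2, 0.8) are
   dropped; pair sets are intersected across the discovery and survival
   cohorts.
4. **Model building** — univariate Cox (keep p < 0.05) → LASSO-penalized
   Cox with 10-fold cross-validated deviance (λ_min) → multivariate Cox;
   the final model keeps the multivariate-significant pairs and

   ```
   riskscore(sample) = Σ_i coef_i × indicator_i(sample)
   ```

5. **Evaluation** — median-split into high/low risk (ties go low, so
   splits can be uneven), Kaplan–Meier + log-rank, time-dependent ROC at
   1/2/3 years (cumulative-case/dynamic-control with KM censoring
   weights), Cox on clinical covariates ± riskscore, Wilcoxon rank-sum of
   riskscore across clinical factors, reverse extraction of immune genes
   correlated with the model lncRNAs, their differential expression, and
   hypergeometric over-representation against user-supplied gene sets.

A `synthetic_data` module generates discovery (28 samples, 17
non-responders / 11 responders) and survival (179 samples) cohorts with
planted immune–lncRNA correlations, group effects and pair-indicator
proportional-hazards effects, so the whole pipeline runs and is tested
with no downloads.

## Worked example

```bash
irlncpair simulate --seed 42 --outdir sim/
irlncpair run-all --config config.yaml --outdir run/   # paths + thresholds
irlncpair report --outdir run/
```

where `config.yaml` points at the simulated files (defaults carry the
standard thresholds):

```yaml
discovery_expression: sim/discovery_expression.tsv
discovery_labels: sim/discovery_labels.tsv
survival_expression: sim/survival_expression.tsv
clinical: sim/clinical.tsv
immune_list: sim/immune_genes.txt
gmt: sim/example_sets.gmt
seed: 42
```

Output of `report` for that seed:

```
ir-lncRNA pair prognostic pipeline summary
seed: 42

ir_lncRNAs_screened: 251
de_ir_lncRNAs: 26
de_up: 13
de_down: 13
pairs_built: 325
pairs_filtered_discovery: 144
pairs_filtered_survival: 84
pairs_intersected: 66
pairs_univariate_significant: 6
pairs_lasso_selected: 6
pairs_in_model: 2
n_high_risk: 36
n_low_risk: 143
reverse_immune_genes: 31
de_immune_genes: 26

riskscore = 0.922 x LNC0001|LNC0002 + 0.715 x LNC0002|LNC0022
median riskscore: 0.922
log-rank chi-sq: 21.8783 (p = 2.91e-06)
AUC at 12 months: 0.639
AUC at 24 months: 0.669
AUC at 36 months: 0.683
```

Reading this: the 26 planted differential ir-lncRNAs produce exactly
C(26,2) = 325 pairs; the pairRatio filter and cross-cohort intersection
leave 66 informative pairs; 6 are univariately prognostic; the final
multivariate model keeps 2, whose weighted indicator sum separates the
survival cohort (log-rank p ≈ 3e-6) with 1/2/3-year AUCs of 0.64–0.68.
Every intermediate table is written under `run/` as TSV/JSON, and a rerun
at the same seed is bit-identical.

The same steps are available as library calls (`screen_ir_lncRNAs`,
`moderated_t_test`, `encode_pairs`, `pair_ratio_filter`,
`lasso_cox_select`, `cox_multivariate`, `risk_score`, `stratify`,
`km_logrank`, `time_roc`, `ora_hypergeometric`, ...) and as the finer CLI
subcommands `screen`, `pair`, `model`, `evaluate`, `enrich`.

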