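# Methods

This note records the statistical model behind `irlncpair`, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not establish.

## Pair encoding and its rationale

For samples profiled on any platform, the indicator
`1{expr(A) > expr(B)}` of an ordered gene pair is invariant to monotone
per-sample transformations, so pair predictors transfer across cohorts
without normalization — the property that motivates the whole design.
Ties are encoded as 0 (a tie means "not greater"); with continuous
expression values ties have probability zero, which is why the
orientation flip A|B → B|A maps indicators x → 1−x and pairRatio
r → 1−r. Pairs are stored in canonical orientation (lexicographically
smaller symbol first); report-oriented labels are reconciled by this
complement rule. The pairRatio filter keeps `lo < r < hi` with a strict
open interval, defaults (0.2, 0.8): a pair that scores 1 in nearly all or
nearly no samples cannot discriminate outcomes.

## Screening and differential expression

Immune-relatedness is a correlation screen of each lncRNA against each
immune gene. Spearman is the default (array intensities are monotone but
not linearly related to abundance; the threshold is quoted as ρ);
Pearson is selectable. p-values use the t-approximation on n−2 df for
both methods — at the screening threshold of p ≤ 1e-4 with n = 28 this
requires |ρ| ≳ 0.66, so the approximation error is immaterial. The
reverse extraction (immune genes correlated with the model lncRNAs) uses
the same machinery at |ρ| ≥ 0.4, p < 0.05.

Two-group differential expression uses the moderated t: per-gene pooled
variances s² with d = n₁+n₂−2 df are shrunk toward a prior s₀² with d₀
prior df,

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),   t̃ = logFC / √(s̃²(1/n₁+1/n₂)),

with p from a t-distribution on d₀+d df. (d₀, s₀²) are estimated by the
method of moments on log s² (digamma/trigamma matching); d₀ = 0
degenerates exactly to the ordinary pooled t and d₀ = ∞ to a common
variance s₀². The implementation agrees with Bioconductor limma's
`eBayes` to ~1e-14 on shared input (tested via Rscript).

Genes are called Up/Down when raw p ≤ 0.05 **and** logFC lies outside
mean(logFC) ± 2·sd(logFC) over the tested genes. Two reading choices are
deliberate:

* the gate statistic is computed on the logFC vector (the gate is applied
  to fold changes; computing it on expression values would mix scales);
* the p-filter is on **raw** p. With 28 samples the Benjamini–Hochberg
  adjusted values of genuinely shifted genes typically exceed 0.05;
  adjusted p is reported but not filtered on.

The fold-change gate applies only to the lncRNA step. The immune-gene
differential analysis (`immune_gene_dea`) calls genes on p ≤ 0.05 and the
sign of logFC alone: it runs on a correlation-selected subset in which a
large fraction of genes carry real effects, and a mean ± 2·sd gate over
such a subset is dominated by the effects themselves — formally, with a
fraction f of genes shifted by Δ the gate half-width is about
2√(fΔ²+σ²) which exceeds Δ whenever f > ~0.25, making the gate reject
exactly the genes it should keep.

## Survival modelling

Cox fits maximize the partial likelihood with **Efron** tie handling
(lifelines), the better approximation when many subjects share the same
discrete pair-score; a Breslow Newton–Raphson solver is included as a
switchable alternative and doubles as an independent oracle in the tests.
Wald statistics use z = Φ⁻¹(0.975) frozen at 1.959964 so that published
3-decimal (β, se, HR, CI) rows reproduce arithmetically. A singular
information matrix raises an error naming the collinear predictors; CI
bounds of a divergent (separated) fit are reported as infinite rather
than failing.

LASSO-Cox runs on the coordinate-descent path of
`CoxnetSurvivalAnalysis` (l1_ratio = 1, 50 log-spaced λ down to 0.01·λmax)
with λ chosen by 10-fold cross-validated partial-likelihood deviance in
the Verweij–van Houwelingen form, dev = −2·[ll_full(β) − ll_train(β)],
computed with the Breslow log partial likelihood; folds are assigned by a
seeded permutation, so selection is reproducible. The model-building flow
is univariate p < 0.05 → LASSO(λ_min) → multivariate fit → keep
multivariate p < 0.05; the riskscore uses the multivariate coefficients
rounded to 3 decimals (matching how such models are reported and reused).

Stratification: `median` (default) puts a sample in the high-risk group
iff its score strictly exceeds the median. Pair scores are sums of a few
weighted indicators and therefore heavily tied; the strict inequality is
what produces uneven splits (e.g. 36/143 in the worked example) rather
than an artificial 50/50. A `roc_optimal` rule (Youden cutoff of the
time-dependent ROC at a chosen horizon) is available; published analyses
of this design report both a median value and a "best cut-off", which
cannot both be generated by one rule — both are exposed and the choice is
recorded in the output.

Time-dependent ROC at horizon t uses the cumulative-case/dynamic-control
definition (cases: event by t; controls: surviving past t). The default
`km` estimator composes case/control probabilities from Kaplan–Meier
survival within the score-split subsets; the `ipcw` alternative weights
observed cases by 1/G(T−) from the censoring KM. Both reduce exactly to
the empirical ROC — and the AUC to the Mann–Whitney statistic — when no
censoring precedes the horizon (a tested identity). AUC integrates the
staircase in descending-threshold order; under heavy censoring the `km`
curves need not be perfectly monotone, which the signed trapezoid
absorbs.

Clinical Cox models expand categorical covariates to indicator contrasts
against fixed references (Female, No, T1, N0, Stage I, Well) and
dichotomize age at 60 years; univariate means one factor per model,
multivariate is all factors plus riskscore jointly.

## Downstream statistics

Riskscore-by-clinical comparisons use the Wilcoxon rank-sum test (normal
approximation with continuity correction; exact enumeration when both
sides have n ≤ 10) for two-level factors and Kruskal–Wallis for more —
the multi-level test is not named in the source analyses and
Kruskal–Wallis is the rank-based analogue. Over-representation is the
upper-tail hypergeometric on sets intersected with the analysis universe;
the universe defaults to the reverse-extracted immune-gene pool and is
overridable. Both the "p adjust" and "Q value" columns are
Benjamini–Hochberg (published tables show them nearly identical; Storey's
estimator is unstable at a dozen tests). qPCR quantification implements
2^−ΔΔCT only; all wet-lab handling is out of scope.

## Synthetic cohorts

The generator emulates the two study cohorts: a 28-sample two-group
discovery cohort (17 non-responders / 11 responders) and a 179-sample
survival cohort. Expression is Gaussian on the log2 scale with gene means
uniform on 4–8 (the AveExpr range of array data). Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| n_immune_genes / n_lncRNAs | 120 / 700 | enough nulls that the ±2·sd gate is noise-driven, as in a real array |
| n_linked_lnc | 250 | immune-linked fraction similar to a real screen |
| rho_true | 0.8 | comfortably above the n = 28 screening threshold (|ρ| ≈ 0.66) |
| n_de_lnc / de_effect | 26 / 1.5 log2 | the screened DE count; effect in the printed logFC range (1.0–1.9) |
| noise_sd | 1.0 | gives moderated-t values ~2–4 at n = 28, matching a real discovery table |
| baseline_hazard / censor_rate | 0.008 / 0.015 per month | ~55–60% events once planted pair effects raise the average hazard; median OS ~19 months |

A linked lncRNA is a ρ-correlated transform of an immune gene plus noise;
when it also carries a group effect, its immune partner is co-shifted
(co-regulation), because an unshared shift of 1.5 log2 units would
dilute an 0.8 correlation below the screening threshold at n = 28.
Genes named in `pair_betas` get equal baseline means so their indicator
has pairRatio ≈ 0.5; survival times are exponential with rate
h₀·exp(Σβᵢ·indicatorᵢ) under independent exponential censoring. Clinical
covariates are drawn from the published cohort margins, independent of
expression; a `confounding` knob (default off) couples age to both the
hazard and the pair indicators for tests that need univariate ≠
multivariate behaviour. One seed is split into five independent streams
(gene means, discovery noise, survival noise, survival times, clinical)
so enlarging one block never perturbs another.

What the synthetic cohorts do **not** emulate: probe-level artifacts,
batch effects, correlated clinical covariates, non-proportional hazards,
and the long-tailed expression distributions of RNA-seq. Passing tests
therefore establish correctness of the statistical machinery and
end-to-end reproducibility, not field performance on real cohorts; the
real-data pair counts (325 → 180 → 74 in the original analysis) depend on
the actual datasets and are context, not targets.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own cohort sizes
(28/179) for pipeline checks; parameter-recovery uses cohorts of 2000
(estimate SD ≈ 0.06 per coefficient, averaged over 5 replicates in the
acceptance script), the LASSO selection-rate check uses 50 cohorts of
500, and null-calibration checks use 500 replicates. Newton iterations
stop at step < 1e-9; the trigamma inverse iterates Newton from
x₀ = 0.5 + 1/y; correlation p at |ρ| = 1 is set to 0 rather than
evaluated through the singular t-transform. Duplicate gene symbols
collapse to the row with maximal mean expression (the usual array
convention; the collapse is order-independent by construction). TSV
round-trips are guaranteed to 6 significant digits.

## Known limitations

* Tie handling options are Efron and Breslow only; no exact partial
  likelihood.
* The correlation screen's exact permutation p for tiny n is not
  implemented; all correlation p-values are t-approximations.
* The `km` time-ROC estimator can produce locally non-monotone curves
  under heavy censoring (inherent to the subgroup-KM construction).
* No batch/surrogate-variable correction, no competing risks, no
  time-varying covariates, no GO/KEGG retrieval (gene sets are
  user-supplied GMT), no deconvolution of immune infiltrates.
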