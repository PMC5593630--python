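# Methods

This note documents the models and procedures implemented in
`immunodissect`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions
chosen where the design was genuinely open.

## Marker derivation

### Tiered standards

Given a table mapping each cell type (B cell, CTL, Th1, Th2, monocyte)
to a seed gene list, `build_standards` tiers the genes by uniqueness:

- **high-tier positives** — genes appearing in no other cell type's
  list (high confidence of cell-type specificity);
- **low-tier positives** — the type's genes shared with at least one
  other list (relevant but ambiguous);
- **negatives** — the union of the other cell types' unique genes.

The three tiers are disjoint by construction. A cell type with no
unique genes has no high-confidence anchor and is rejected. Low-tier
positives are never placed in the negative class.

### Iterative classification

The derivation treats genes as instances: a gene's feature vector is
its expression profile across the compendium samples, after per-gene
z-transformation so decision-boundary distances are comparable between
genes. The loop is:

1. fit a regularized linear classifier (logistic regression, inverse
   regularization `C`, default 1.0) on current positives (initially the
   high tier) vs negatives;
2. score every compendium gene by its signed distance to the decision
   boundary;
3. promote low-tier positives scoring above the `promotion_quantile`
   (default 0.5) of the low tier's scores into the training positives;
4. repeat until no new gene is promoted or `max_iterations` (default
   10) is reached (a non-convergent run warns and keeps the last
   iterate).

Promotion is monotone — membership is never revoked — so the promoted
set converges. With an empty low tier the procedure is exactly one
supervised fit. The published description of the original iterative
standard-selection procedure leaves its internals open; the promotion
scheme above is this package's interpretation, chosen because it is
monotone, convergent, and reduces to the supervised baseline in the
no-overlap limit. Any margin-based regularized linear model would do;
linearity is required so that in the noiseless limit the true program
genes are linearly separable from the rest and outrank them.

The final output ranks all compendium genes by decision score, ties
broken lexicographically by gene symbol so results are deterministic.
The signature is the top `top_n` genes (default 100). A reduction of
the ranked list by marker co-expression is sometimes applied in this
setting; its definition is under-specified, so this package uses the
plain top-N and exposes `select_top_markers` for re-cutting.

Training genes remain eligible for the ranked list and are flagged in
`MarkerSet.training_genes`.

### Cross-validated evaluation

`crossval_auc` stratifies the standard genes over the tier structure
(high/low/negative) into `cv_folds` folds (default 5, seeded shuffle),
runs the full iterative procedure inside each training fold, and
computes AUROC on the held-out genes with both positive tiers counted
as positives. The ≥ 5 high-positive floor applies to the user-supplied
standard; training folds may legitimately hold fewer. A tier smaller
than the fold count is merged with the other positives for
stratification only.

## Scoring

All scores use the per-gene cohort z-transform
z_gs = (x_gs − μ_g)/σ_g with the sample (n−1) standard deviation —
matching the default of mainstream statistics environments — and the
signature average d_s = (1/n) Σ z_is. Conventions:

- genes with σ_g = 0 are **dropped**, not set to z = 0, because a
  constant gene carries no signal and a fabricated 0 would dilute
  scores;
- signature genes not assayed in the matrix are excluded and n
  adjusted; the per-signature `n_genes_used` is recorded;
- the total lymphocyte score averages over the deduplicated union of
  the four signatures (equivalently, the n-weighted average of disjoint
  component scores);
- the ER call is strict: score < 0 → ER−, score > 0 → ER+, exactly 0 →
  unknown (logged) rather than forcing a class;
- gene symbols are matched case-sensitively after whitespace trimming.

## Robustness to missing genes

`robustness_analysis` sweeps removal fractions (default 0 to 0.95 in
0.05 steps, 50 repetitions each, seeded). Each repetition removes
round(f·n) genes without replacement (at least 1 for f > 0, never all),
recomputes the score, and tests Kendall tau-b between the score and the
ordered infiltration categories. Tau-b is used because the category
variable is heavily tied. A fixed-count mode (`mode="count"`,
`n_remove` genes per repetition) is also exposed for protocols that
remove a set number of genes rather than a fraction.

`max_preserved_fraction` is the largest grid fraction f such that
**every** repetition at **every** grid fraction ≤ f is significant at
α = 0.05 — a contiguous-from-zero definition, so one unstable
intermediate fraction cannot be skipped over.

## Association suite

- **Rank-sum:** exact two-sided p when both groups have ≤ 10 samples,
  computed from the full permutation distribution of the (midrank-tied)
  rank sum via a subset-sum dynamic program — identical to literal
  enumeration of all C(n₁+n₂, n₁) assignments; the tie-corrected normal
  approximation otherwise. The reported statistic is the Mann-Whitney U.
- **ANOVA:** one-way across infiltration categories. (A two-factor
  layout is sometimes named for this comparison, but all reported
  category contrasts are one-factor; the one-way form is used.)
- **Trend:** Kendall tau-b vs category ranks; **correlation:** Pearson
  with the two-sided t-transform p.
- **Quartile stratification:** high iff score > 75th percentile with
  linear interpolation (type-7); threshold ties go to low, so high is
  strictly the upper tail.
- **Survival:** product-limit curves and the two-group log-rank test
  (via lifelines). Only two-group contrasts are supported because the
  analyses stratify by ER status and high/low score; a group with zero
  events is returned but flagged unreliable.
- P-values are reported unadjusted (per-test reporting at α = 0.05); a
  Bonferroni column is available on request via `SuiteConfig`.
- Analyses whose annotation columns are missing are skipped with a
  logged reason, never silently; paired pre/day-90 samples are excluded
  from the cross-sectional analyses.

## Synthetic data

### Blood compendium

Defaults: 400 samples × 4000 genes; five programs of 120 genes, the
Th1/Th2 programs sharing 30; each cell type active per sample with
probability 0.3; program genes shifted by +2.0 (log-intensity-like
units) in active samples over N(0, 1) noise. Standards are built from
40 seed genes sampled per program; seeds in the Th1/Th2 overlap become
low-tier positives. The scale mimics a microarray log-intensity setting
(Gaussian noise), not counts.

### Tumor cohort

Defaults: 300 cross-sectional samples × 4000 genes plus 29 paired
pre/day-90 biopsy pairs (58 paired samples, the size of a typical
aromatase-inhibitor treatment series). Per sample:

- latent ER activity a_s ~ N(0, 1); ER+ iff a_s exceeds the normal
  quantile giving 76% ER+ (the ER− share of a large breast-cancer
  cohort, ≈ 24%);
- per-cell-type infiltration fraction f_c ~ Beta with mean
  clip(0.2 − 0.045·a_s) and concentration 4; CAAI+ samples (15%) have
  all fractions halved. The slope/concentration pair was chosen by
  analytic variance decomposition so that corr(a_s, Σf_c) ≈ −0.4 and so
  that the upper-quartile survival contrast in the ER− stratum (~72
  samples, ~60 events) is adequately powered; a 20-seed Monte Carlo
  confirms r ∈ [−0.51, −0.27];
- expression = N(0, 1) noise + 1.0·a_s on the 50 ER-program genes +
  4.0·f_c on each immune program's genes;
- ordinal infiltration categories cut the total true fraction at its
  0.25/0.5/0.75 quantiles (absent/mild/moderate/severe) — a convention,
  since histology-derived category prevalences are not modelled;
- survival ~ Exponential with log-hazard −2.0 + b1·Σf_c, b1 = −1.5 in
  ER− and 0 in ER+; independent exponential censoring at rate 0.01
  (≈ 12% censored);
- day-90 fractions are the pre-treatment fractions × 1.4 (capped at 1);
  paired samples are drawn from the ER+ stratum, carry no survival, and
  are excluded from cross-sectional analyses;
- subtype is sampled consistently with ER status (ER+ → luminal A/B,
  ER− → basal/HER2/normal-like), so the subtype contrast recapitulates
  the ER contrast by construction.

All generators are pure functions of their configs; one SeedSequence is
split per sub-task so enlarging one dimension does not perturb others.

### What the generator does not emulate

No probe/platform effects, batch structure, cohort-specific sample
composition, correlated immune programs beyond the Th1/Th2 gene overlap,
tumor-intrinsic expression heterogeneity, or realistic marker-gene
biology (genes are anonymous). Passing tests therefore demonstrate that
the implementation recovers the effects it assumes — correct machinery
and calibrated statistics — not that the derived signatures would match
biologically curated marker sets on real cohorts; published cohort
statistics (AUCs, taus, cohort p-values) depend on external data and are
not reproduced here.

## Problem sizes and runtime

The default study sizes (400×4000 compendium, 300-sample cohort, 50
robustness repetitions per fraction, 50-seed null calibrations) keep a
full test run under a minute on one CPU while leaving all planted
effects well-powered (50/50 recovery of the ER, CAAI, and treatment
directions in a 50-seed meta-simulation). The demo pipeline
configuration is further scaled down (120×800 compendium) and exists
for smoke-testing and byte-identical reproducibility checks.

## Known limitations

- The iterative promotion scheme is an interpretation (see above); other
  standard-selection rules could rank genes differently on real data.
- The exact rank-sum permutation p is computed only up to 10 + 10; larger
  groups use the tie-corrected normal approximation.
- The log-rank test is two-group only.
- ER calling by the sign rule disagrees with prevalence-threshold ER
  labels near the decision boundary; on synthetic cohorts the two agree
  for ~75% of samples by construction of the latent-activity model.
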