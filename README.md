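# immunodissect

In-silico profiling of lymphocyte infiltration in bulk gene-expression
cohorts.

Bulk tumor expression profiles mix signal from cancer cells with signal
from the microenvironment, including tumor-infiltrating lymphocytes
(TILs). `immunodissect` quantifies the infiltration of four lymphocyte
cell types — B cells, CD8+ cytotoxic T cells (CTL), and the CD4+
T-helper subsets Th1 and Th2 — in any normalized expression matrix,
without prior knowledge of sample composition. It is aimed at
computational biologists who want to profile immune infiltration
retroactively in existing microarray/expression cohorts and relate it to
clinical covariates (estrogen-receptor status, molecular subtype,
genomic instability, survival, treatment response).

## Method

**Marker derivation.** Each cell type's markers are derived from a large
blood expression compendium by iterative semi-supervised classification.
Genes are instances; a gene's feature vector is its per-gene z-scored
expression profile across the compendium samples. Literature-seeded
standards are tiered: genes unique to the cell type are high-confidence
positives, genes shared with related cell types are low-confidence
positives, and the unique genes of the other cell types (including
monocytes) are negatives. A regularized linear classifier is trained on
positives vs negatives, every gene is scored by its signed distance to
the decision boundary, low-tier positives scoring above a within-tier
quantile threshold are promoted into the training positives, and the
model is retrained until the promoted set stabilizes. The top 100 genes
of the final ranking form the cell type's signature; quality is measured
by stratified 5-fold cross-validated AUROC on held-out standard genes.

**Scoring.** Expression is z-transformed per gene across each cohort,
z_gs = (x_gs − μ_g)/σ_g, and a sample's signature score is the mean
z-score over the signature's n genes:

    d_s = (1/n) Σ_i z_is

Genes not assayed in a cohort are excluded and n adjusted. The total
lymphocyte score averages over the union of the four signatures; an ER
activity score applies the same formula to an estrogen-receptor gene
set, with score < 0 calling a sample ER− and score > 0 ER+.

**Statistics.** The association suite tests score differences by
Wilcoxon rank-sum (exact by enumeration for groups of ≤ 10), paired
changes by Wilcoxon signed-rank, category trends by one-way ANOVA and
Kendall tau-b against the ordered infiltration categories
(absent < mild < moderate < severe), correlations by Pearson, and
survival by Kaplan-Meier curves with a two-group log-rank test after
splitting samples at the 75th score percentile (upper quartile = high).
A gene-dropout robustness sweep removes random subsets of signature
genes and re-tests the Kendall trend.

**Synthetic ground truth.** A bundled generator simulates (a) a blood
compendium with co-expressed cell-type programs (only Th1/Th2 overlap)
and (b) tumor cohorts mixing a baseline, an ER program driven by a
latent ER activity, and immune programs weighted by Beta-distributed
infiltration fractions that decrease with ER activity, with reduced
infiltration in genomically unstable (CAAI+) samples, an infiltration
survival benefit only in the ER− stratum, and paired pre/day-90
treatment samples with increased infiltration. Every downstream claim
is testable against this planted truth. See `docs/methods.md` for the
full model and its limitations.

## Worked example

```python
import immunodissect as im

# derive markers from a synthetic blood compendium
compendium, programs, standards = im.generate_compendium(im.CompendiumConfig(seed=1))
z = im.zscore_transform(compendium)
params = im.DerivationParams(seed=1)
for ct in im.LYMPHOCYTES:
    folds, mean_auc = im.crossval_auc(z, standards[ct], params)
    ms = im.nanodissect(z, standards[ct], params)
    prec = len(set(ms.signature) & set(programs[ct])) / len(ms.signature)
    print(f"{ct:5s}  mean 5-fold CV AUC = {mean_auc:.3f}   "
          f"precision@100 vs planted program = {prec:.2f}")

# score a synthetic tumor cohort and run the association suite
markers = im.derive_all(z, {ct: standards[ct] for ct in im.LYMPHOCYTES}, params)
cohort = im.generate_tumor_cohort(im.TumorCohortConfig(seed=2),
                                  {ct: programs[ct] for ct in im.LYMPHOCYTES})
zt = im.zscore_transform(cohort.expression)
sigs = {ct: ms.signature for ct, ms in markers.items()}
report = im.run_association_suite(zt, cohort.annotations, sigs,
                                  er_signature=cohort.er_program)
print(report[report.signature == "total"][["analysis", "test", "statistic", "p_value"]])
```

This prints:

```
Bcell  mean 5-fold CV AUC = 1.000   precision@100 vs planted program = 1.00
CTL    mean 5-fold CV AUC = 1.000   precision@100 vs planted program = 1.00
Th1    mean 5-fold CV AUC = 1.000   precision@100 vs planted program = 1.00
Th2    mean 5-fold CV AUC = 1.000   precision@100 vs planted program = 1.00
```

and, for the total lymphocyte score, a report in which the planted
effects are recovered with the right direction: ER− samples score higher
than ER+ (rank-sum p = 1.6e−07), the ER activity score correlates
negatively with infiltration (Pearson r = −0.40, p = 9.1e−13), CAAI+
samples score lower than CAAI− (p = 4.1e−11), high infiltration predicts
survival in the ER− stratum (log-rank p = 0.014) but not in ER+
(p = 0.14), and infiltration rises from pre-treatment to day 90
(signed-rank p = 3.7e−09). On this clean synthetic compendium the
classifier separates held-out standard genes perfectly (AUC 1.0); real
compendia are noisier.

The same workflow is available from the shell:

```sh
immunodissect run --demo --seed 5 --out demo_run
immunodissect derive --compendium compendium.tsv --standards standards.tsv --out markers/
immunodissect score --matrix cohort.tsv --gmt markers/markers.gmt --out scores.tsv
```

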