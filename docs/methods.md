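# Methods

`metamarker` implements a two-track discovery procedure for two-group
metabolomic studies (case vs control plasma profiles measured by targeted
LC–MS/MS). The two tracks answer different questions:

* **Primary (concentration-shift) markers** — which small *combinations* of
  metabolites jointly discriminate the groups by their abundance values,
  even when no single metabolite does?
* **Secondary (correlation-break) markers** — which metabolites keep their
  marginal abundance distribution but lose their normal statistical
  relationships to the rest of the profile in cases?

## Data model and preprocessing

The input is an `n_samples x n_metabolites` matrix of positive peak areas
with a binary group label per sample. Preprocessing:

1. **Missing values.** A metabolite with at most 5% of samples missing
   (`missing_fraction_max`, default 0.05) has each missing cell replaced by
   the median of its observed values; the median is robust to the outliers
   common in peak-area data. Metabolites above the threshold are dropped:
   with so few observations per group, neither imputation nor testing is
   reliable. Imputation never alters observed cells and is idempotent.
2. **Log transform.** Peak areas are right-skewed and span decades; all
   downstream stages see `log(x)`. The base (default `e`) only rescales
   every column and is statistically irrelevant for rank tests, trees and
   the neural stage; it is configurable for display purposes.
3. **Scaling for the neural stage.** Each metabolite is mapped to [0, 1] by
   min–max over the *control* samples only (the autoencoder's training
   population); out-of-range case values are clipped. The autoencoder uses
   rectified-linear activations on its output layer, which cannot emit
   negative values, so unscaled log data (which contain negative entries)
   would be unlearnable. Constant metabolites map to 0.5 with a warning.

## Screening

Each metabolite is tested case-vs-control with the two-sided Mann–Whitney U
test: exact permutation distribution when both groups are small
(`min(n, m) <= 8`) and untied, the normal approximation with tie and
continuity correction otherwise. Multiplicity is controlled with
Benjamini–Yekutieli (valid under the arbitrary dependence expected between
metabolites) at `alpha = 0.05`; Benjamini–Hochberg is available and is the
default inside the anomaly stage, where one family of tests is produced per
trained model. In cohorts of this size the screen is expected to come back
empty — that negative result is what motivates the combination search.

## Primary markers: GA over subsets, boosted-tree fitness

The fitness of a metabolite subset is the **minimum held-out-fold accuracy**
of an XGBoost classifier (`n_estimators = 1000`, `learning_rate = 0.05`,
other parameters default) trained on the subset's columns under stratified
5-fold cross-validation. Taking the minimum rather than the mean makes the
score pessimistic: a subset that separates only part of the cohort is
penalized by its worst fold.

The search evolves fixed-length chromosomes of `k` distinct metabolite
indices (defaults `k ∈ {3, 4}`, one GA pass per `k`): tournament selection
(size 3), crossover that draws the child without replacement from the union
of the two parents' genes, and per-gene mutation (rate 0.1) to a random
unused index. The union-draw crossover is the set-encoding analogue of
uniform crossover: positional crossover on sorted index vectors aligns the
strongest genes at the same position and then cannot combine complementary
markers carried by different parents, which defeats the purpose of the
search. Elitism keeps the best individual; a pass stops early after
`stagnation_patience` generations without improvement (the fitness budget
dominates run time; an exhausted plateau does not change the retained
winner).

The procedure is repeated over `n_runs` independently seeded runs (default
100), each with its own fold assignment (shared by every fitness evaluation
inside the run, so within-run comparisons are fold-noise-free). Per
metabolite, the **inclusion frequency** — the fraction of per-run winning
combinations containing it — is the stability ranking; the union of winners
is the primary marker set. Subset fitness values are memoized per run.

ROC AUC for a chosen combination is computed from pooled out-of-fold case
probabilities under the same fold scheme; in-sample AUC on 39 samples with
1000 boosting rounds would be trivially near 1 and is not reported.

### Caveats measured on synthetic data

Two behaviors of the fitness matter when interpreting inclusion
frequencies, and both were verified directly on synthetic cohorts of the
study shape (27 + 12 samples):

* With default `min_child_weight = 1` and logistic hessians of at most 0.25
  per sample, XGBoost cannot split off leaves holding fewer than ~4–5
  training samples, so cleanly separated held-out samples can still be
  misclassified in 31-sample training folds. The min-fold accuracy
  therefore plateaus below 1 even for perfectly separable subsets (a
  logistic regression on the same folds scores 100%).
* Because of that plateau, a subset containing *one* strong marker plus
  arbitrary metabolites often ties the best subset containing *both*
  planted markers. Ties leave the GA without selection pressure to retain
  both, so inclusion frequencies split between redundant markers rather
  than concentrating on all of them. The union of retained combinations is
  the robust recovery target; per-marker inclusion near 1 requires markers
  that are individually insufficient but jointly separating.

## Secondary markers: denoising-autoencoder ensemble

A three-layer dense autoencoder (`n_features → hidden → n_features`,
rectifier activations on hidden *and* output layers) is trained on control
profiles only. Training pairs are (noisy, clean): each control profile
spawns 500 noisy replicates via

    CN_n = CO_n + d * e,   e ~ N(0, sigma = CO_n),   d = 0.25

i.e. corruption proportional to the value itself, applied on the scaled
representation the network consumes; a zero value receives zero noise. The
network is trained for a fixed 20 epochs (no early stopping), batch size 8,
Adam at learning rate 0.001, mean-squared-error loss against the clean
profile. Controls are split 80/20; the 20% partition only monitors loss.
The output-layer bias is initialized at the feature means of the training
targets so that no rectified output unit starts dead (a unit whose
pre-activation is negative for every input receives no gradient and never
recovers). Training is implemented as a compiled explicit-loop kernel;
results are bit-reproducible for a given seed on a given machine.

For detection, **clean** (noise-free) profiles of both groups are passed
through the trained network and the absolute reconstruction error is
recorded per sample and metabolite. Per metabolite, case vs control error
distributions are compared with the two-sided Mann–Whitney test and
Benjamini–Hochberg FDR across metabolites; a metabolite is flagged at
`fdr_alpha = 0.05`. An **ensemble** of 100 models — one per hidden width in
50..149 for the 210-metabolite study shape; for other feature counts the
band scales proportionally (~24%–71% of the feature count) — votes, and
metabolites flagged by at least `consensus_min` models (default 97) form
the secondary-marker set. By default control errors are computed on all
control samples, matching a group-vs-group comparison;
`holdout_controls_only` restricts them to each model's held-out controls.

### Known limitation: in-sample bias vs power

The default comparison is biased: most control samples were seen in
training and reconstruct with much smaller error than any case sample,
which is always out-of-sample. Measured on synthetic cohorts (52
metabolites, blocks of 8 at within-block correlation 0.6), training error
is 0.02–0.12 against held-out error 0.16–0.17 on the [0, 1] scale, and a
*null* cohort with no planted structure still shows consensus counts up to
17/20 — the same range as planted correlation-break metabolites. The
unbiased `holdout_controls_only` mode removes this but leaves ~5 control
samples per model, and the per-model rank test then has essentially no
power. Consequently, on weakly structured data the consensus *ranking*
cannot be trusted to isolate correlation-break metabolites; the
full-consensus *selection* threshold remains meaningful because bias-driven
flags are unstable across architectures and rarely reach unanimity. The
method is most informative when the control correlation structure is strong
(small idiosyncratic variance), which shrinks the generalization gap.
Deeper remedies (cross-validated control errors from multiple models) are
out of scope here.

## Enrichment

Over-representation of a marker set in pathway annotations (GMT-style
files) uses the one-sided upper-tail hypergeometric test with the
**measured-metabolite universe**: only metabolites present in the analyzed
matrix count, both as draws and as pathway members. BH FDR is applied
across pathways. Primary and secondary sets are combined by union for the
joint analysis; their intersection is the dual-status list. Web-tool
enrichment services use undocumented internal universes, so p-values from
this module are comparable only to themselves.

## Synthetic data generator

The generator emulates the features of a targeted plasma matrix that the
method relies on:

* log-normal marginals (log-means uniform on [6, 14], log-SDs on
  [0.3, 0.8] — peak areas spanning ~e^6 to e^14 with moderate biological
  variability);
* block-equicorrelation on the log scale among control metabolites
  (default: blocks of 8 covering ~80% of metabolites at correlation 0.6),
  standing in for shared pathway regulation;
* planted primary markers: case log-means shifted by a configured number of
  control log-SDs;
* planted secondary markers: case values re-drawn independently from the
  metabolite's own marginal, severing every correlation to its block while
  leaving the level untouched (one marker per block in the bundled recovery
  experiments, because a break also degrades the reconstruction of its
  intact block-mates);
* missing cells knocked out completely at random (default 2%; recovery
  fixtures use 0 so that planted columns cannot be dropped by the 5% rule).

Default cohort shape: 27 controls vs 12 cases over 210 metabolites. The
generator does **not** emulate batch effects, drift, censored-at-detection-
limit missingness, or realistic inter-pathway correlation, so passing
recovery tests demonstrate correctness of the machinery under the assumed
model, not field performance on raw LC–MS data.

## Problem sizes in the bundled experiments

The test suite and `scripts/acceptance.py` run desk-scale versions of the
study configuration, chosen as the package's own experiment sizes: 52
metabolites; 20 GA runs (population 16, up to 10 generations, patience 3)
with the full 1000-round booster; autoencoder ensembles of 20 models with
the full 500-replicate / 20-epoch training; 200 null cohorts for the
type-I-error check. Numbers in the acceptance report are computed from
scratch on each invocation from the `--seed` argument.
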