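# Methods

`metabopanel` implements a quantitative urinary-metabolomics biomarker
discovery workflow for a three-group renal study design (healthy controls
CTRL, type-2 diabetes DM2, diabetic nephropathy DN): preprocessing of an
absolutely quantified metabolite concentration table, nonparametric
univariate statistics, PLS-DA with permutation validation, two complementary
panel-selection strategies (LASSO→stepwise logistic regression, and a
genetic-algorithm wrapper with elastic-net fitness under nested
cross-validation), and metabolite-set over-representation analysis. A
synthetic-data generator with the same statistical structure makes every
stage testable without patient data.

## Preprocessing chain

The chain is fixed and order-enforced:

1. **Missingness filter** — metabolites missing in strictly more than 20% of
   samples are removed ("more than" is read as a strict inequality, so a
   metabolite at exactly 20% is retained).
2. **Left-censored imputation** — each remaining below-LOD entry is replaced
   by one fifth of that metabolite's minimum positive observed value. The
   minimum is computed over the table being fitted; inside cross-validation
   the training partition's minima are frozen and reapplied to held-out
   samples.
3. **Creatinine normalization** — concentrations (µM) are divided by the
   sample's urinary creatinine (mM), giving µmol/mmol creatinine and
   correcting for urine dilution. CSV input may declare creatinine in mg/dL,
   converted by ×0.0884.
4. **Log transform** — natural log. The base is a free choice: any fixed
   base rescales columns uniformly and the subsequent Pareto scaling removes
   the difference.
5. **Pareto scaling** — per metabolite, subtract the mean and divide by the
   square root of the sample (n−1) standard deviation. Constant columns map
   to zeros. After scaling, each column's variance equals the original
   column's standard deviation — an identity the tests verify to 1e-9.

`PreprocessPipeline` freezes the retained metabolite set, imputation minima
and Pareto (mean, sd) at fit time; `apply_frozen` transforms new samples
with training-only parameters. Every cross-validated result in the package
refits the chain inside each training fold, so no statistic of a held-out
sample ever enters its own preprocessing.

## Univariate statistics

Two-group contrasts use the two-sided Mann-Whitney U test and k-group
comparisons the Kruskal-Wallis test (scipy; average ranks, tie-corrected
variance). At small group sizes an exact permutation p-value for the H
statistic is available by exhaustive enumeration of group assignments.
Multiplicity is controlled by Benjamini-Hochberg FDR within one comparison
family (one contrast = one family). Metabolite-covariate association uses
Spearman rank correlation — rank-based to match the nonparametric stance of
the rest of the workflow — with the t approximation at n ≥ 10 and exact
pairing enumeration below that. Clinical tables report per-group n,
mean ± sd, median [IQR], a D'Agostino-Pearson normality flag that selects
the display style, Kruskal-Wallis p-values for numeric variables and a
chi-square linear-by-linear trend test for binary variables across the
ordered groups.

## PLS-DA

A NIPALS PLS2 on the centered one-hot class matrix (a single 0/1 column for
two classes), deflating X and Y per component. VIP scores use

    VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ),

with SS_a the Y-variance explained by component a, so mean(VIP²) = 1 — an
algebraic identity asserted to 1e-8. Predictive performance is measured by
stratified k-fold Q² = 1 − PRESS/TSS with per-fold refreezing of the
preprocessing chain; the component count is chosen by maximizing Q², capped
at 5. Class-separation significance uses a label-permutation test with the
add-one estimator p = (1 + #{perm ≥ obs})/(1 + n_perm), whose floor
1/(n_perm+1) is exact. The permuted statistic defaults to Q² (R²Y is
selectable); Q² pairs naturally with reporting cross-validated validity.

## Strategy 1 — LASSO panel

L1-penalized logistic regression over a 30-point geometric λ grid from λ_max
(the smallest λ with an all-zero solution) down three decades, with λ chosen
by stratified 10-fold cross-validated deviance (λ_min default; a one-
standard-error rule by option). The λ convention is glmnet-style,
(1/n)·deviance + λ‖w‖₁, mapped to scikit-learn via C = 1/(nλ); the saga
solver is used so the intercept is unpenalized, matching the elastic-net
module exactly. Surviving metabolites are refit by near-unpenalized
logistic regression with bidirectional stepwise selection minimizing AIC
(deterministic lexicographic tie-break). Quasi-separation triggers a
ridge-stabilized refit (λ = 1e-6) with a warning. Panels are evaluated by

* pooled out-of-fold ROC under stratified 10-fold CV (preprocessing and
  model refit inside each fold), with a percentile-bootstrap 95% CI; and
* balanced-subsampling Monte-Carlo CV: each split draws an equal per-class
  training subsample of size ⌊train_frac · min(n₀, n₁)⌋ (train_frac 2/3,
  500 splits by default), tests on the remainder, and summarizes the AUC
  distribution by its mean and percentile 95% CI.

Fixed-coefficient published panels can be scored as-is on frozen-scaled
inputs, and two score vectors on the same samples are compared with a
paired permutation test that swaps scores sample-wise (statistic |ΔAUC|).
Confounder handling (e.g. glucose under antidiabetic treatment) is an
exclusion list, not special-cased code.

## Strategy 2 — GA wrapper with elastic-net fitness

Candidate panels are binary masks over the metabolite set. Fitness is

    mean inner-CV MCC of the masked elastic-net logistic model
        − penalty_weight · max(0, k − max_features),

with l1_ratio 0.5, elastic-net strength 1.0 (inverse-C convention),
classification threshold 0.5, max_features 8 and penalty_weight 0.05 per
excess feature — small enough never to dominate the MCC, large enough to
break ties toward parsimony. An empty mask scores −1.

The GA evolves `population_size` individuals for up to `max_generations`
with tournament selection (size 4), two-point crossover (p = 0.8), adaptive
bit-flip mutation and elitism (top 3 copied unchanged, making the best-so-far
fitness nondecreasing). Mutation is applied per child with a probability
decaying linearly from 0.25 to 0.05 across generations; a mutated child
flips each bit with probability 1/n_features. (Reading the 0.25→0.05
schedule as a *per-bit* rate makes the search degenerate — children become
near-random and the elitist best stalls at the initial population — so the
per-individual convention of the common GA toolkits is used.) Initial masks
activate each bit with probability max_features/(2p). Evolution stops at the
generation cap or after 10 generations without improvement beyond 1e-6.
The full-scale profile is population 3000 × 60 generations; the reduced
profile (population 100 × 20 generations), used by tests, the smoke
pipeline and the acceptance script, preserves the dynamics at desk scale.

**Nested cross-validation.** Outer folds (leave-one-out, or stratified
k-fold) measure generalization; each outer-training split is cut into 4
stratified inner folds whose held-out MCCs define the fitness. One GA
replicate per inner fold is run (differing in seed, sharing a fitness
cache) and its best mask recorded; features selected by at least half the
replicates are retained (if none reaches 0.5, the maximal-frequency set is
used so the fold's prediction is defined), the elastic net is refit on the
outer-training split with the retained features, and the held-out samples
are scored. Out-of-fold probabilities are pooled into one ROC — the only
option compatible with LOO singletons. The final stable list aggregates
selection frequencies across all inner folds of all outer folds at the same
0.5 threshold.

**Performance estimation.** AUC, accuracy, F1, sensitivity, specificity,
MCC (zero-denominator convention → 0) and Brier score are computed on the
pooled out-of-fold probabilities, with nonparametric bootstrap percentile
95% CIs (n = 2000; replicates lacking a class are redrawn; the percentile
interval is expanded to include the point estimate in the rare discrete
cases where it would not). Clinical covariates such as GFR join a fixed
panel as a z-scored column standardized on each training fold.

**Fitness solver.** GA fitness evaluation performs on the order of 10⁵
elastic-net fits on matrices of a few dozen rows. These fits use a
package-local JIT-compiled FISTA proximal-gradient solver for exactly the
scikit-learn elastic-net logistic objective (unpenalized intercept; the
optimum agrees with saga to ~1e-7, asserted in a unit test) at relaxed
tolerance (1e-4, ≤300 iterations). Every reported or refit model uses
scikit-learn's saga solver at standard tolerance.

## Over-representation analysis

One-sided hypergeometric upper-tail test of a selected metabolite list
against user-supplied GMT sets, each intersected with an explicit universe
first; the enrichment ratio is observed/expected hits,
n_hits/(n_selected · set_size / universe_size), and BH FDR is applied
across sets. The default universe is the metabolites surviving
preprocessing — the sampling frame actually tested; the full assay panel
can be passed instead, which changes p-values and is left to the caller.
Sets with an empty intersection are dropped (their ratio is undefined).
Pathway database content is out of scope by design.

## Synthetic-data generator

Concentrations are log-normal — strictly positive, right-skewed, and
linear after the log step of the chain. For metabolite j and sample i,

    log X_ij = μ_j + σ(−a_j r_i + sqrt(1−a_j²) ε_ij) + ln2 · d_jg,

where r_i is the latent renal-function factor: the sample's GFR
standardized against the cohort (GFR is drawn per group — means
112.5/107.8/71.2 mL/min/1.73 m², sd 15 — so the factor carries both
within-group variation and the DN depression), a_j = |toxin_gfr_rho| for
the renal-coupled toxin-like metabolites, and d_jg is the planted log2
effect of metabolite j in group g. The default study marks the first 86
metabolites as the assay's uremic-toxin panel and couples every other one
of them (43) to the renal factor at rho −0.5: coupled toxins then both
correlate negatively with GFR across the cohort and accumulate in the
low-GFR DN group, while the rest of the panel stays null — mirroring the
observation that only a minority of catalogued uremic toxins track GFR
strongly. Per-metabolite baseline log-means are drawn
around base_log_mean 1.0 (µM scale) with unit spread; σ = 1. Censoring is
Type I: the LOD is the requested quantile (default 5%; a 12-metabolite
subset at 30% exercises the missingness filter) of the metabolite's
baseline marginal distribution, values below it are recorded missing with
the LOD retained. Creatinine is log-normal around 10 mM (log-sd 0.4); ACR,
age and sex follow the group-wise clinical profile of the emulated design
(20 subjects per group). A single `numpy.random.default_rng(seed)` stream
drives everything; equal seeds give bit-identical output, and all pipeline
stages derive their seeds from one run seed by stage-name salting.

The default study plants an eight-metabolite DN-discriminative panel
(β-alanine-like and kynurenine-like depletion at log2 −1.5/−1.4 — kept
moderate because strong depletion drives the affected group below the LOD
and the metabolite out through the missingness filter, which is realistic
but undesirable as a default; argininic-acid-, glucose-,
2-hydroxybutyrate-, shikimate- and N-acetyl-amino-acid-like elevation at
log2 1.2–1.6). What the generator does **not** emulate: batch and drift
effects, heteroscedastic assay noise, metabolite-metabolite pathway
correlation beyond the shared renal factor, and covariate confounding
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance
on real cohorts.

## Numerical and reproducibility choices

* NIPALS tolerance 1e-10 on score convergence, 500 iterations; Pareto
  constant columns map to zeros; (mean, sd) recorded per metabolite.
* All CSV and JSON output uses 10-significant-digit numerics and sorted
  keys, making rerun byte-identity a meaningful check (asserted by the
  smoke test).
* Problem sizes used by the test suite and acceptance script — e.g. 40
  samples × 100–268 metabolites, reduced GA profile, 200–500 permutations
  or MCCV splits, 2000 bootstrap replicates — are the package's desk-scale
  defaults; the full-scale profile is available by flag.

## Known limitations

* Stability selection at desk scale does not certify *complete* panels:
  once a feature subset saturates the inner-CV MCC, the remaining informative
  features are fitness-neutral and each GA replicate converges to a
  different sufficient subset, so redundant biomarkers divide the selection
  frequency between them. At n = 40, p = 100 with four strongly planted
  metabolites, typically two of the four pass the 0.5 frequency threshold
  while pooled out-of-fold AUC stays high (≈0.8–0.97). This is a property
  of wrapper selection under MCC saturation, not of the implementation;
  interpreting stable lists as "a sufficient discriminative subset" rather
  than "all true markers" is the appropriate reading.
* AIC-based stepwise refit admits a pure-noise covariate whenever its
  χ²(1) deviance gain exceeds 2 (≈16% of attempts); stricter criteria
  (BIC) are not implemented.
* The exact Kruskal-Wallis permutation test enumerates group assignments
  and is limited to ≈2·10⁵ assignments.
* Bootstrap CIs are percentile intervals; BCa is not implemented.
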