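# Methods

This note documents the statistical model behind `veganome`, the
choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Data model and preprocessing

Raw abundances are strictly positive with left-censoring at a
per-metabolite detection limit (stored as missing). The pipeline is
filter → median-scale → impute → log, enforced by a state machine:

- **Detection filter.** A metabolite is dropped when its missing
  fraction exceeds the threshold (default 0.5) in *both* diet groups.
  The conjunction reading is the default because a metabolite absent in
  one group only is biologically informative; `rule="any"` and
  `rule="overall"` are available for sensitivity analysis.
- **Median scaling** divides each metabolite by its own median over
  observed values, using midpoint interpolation for even counts (the
  scaling constants depend on this convention, so it is fixed and
  documented). The observed median becomes exactly 1.
- **Minimum imputation** replaces each missing entry with the
  metabolite's minimum observed scaled value — a detection-limit floor.
  Because scaling is a per-metabolite constant, imputing after scaling
  is identical to imputing before and then scaling; the order is fixed
  for reproducibility, not correctness.
- **Natural log.** Fold changes are produced by exponentiating mean
  differences, so the base only has to be self-consistent; natural log
  is used throughout.

## Residualized regression with surrogate variables

Per metabolite j the working model on the log scale is

    y_ij = μ_j + β_j·vegan_i + γ_j'z_i + λ_j'u_i + ε_ij

with observed covariates z (age, sex, race; BMI is considered a
*mediator* of diet and excluded from inference) and unobserved factors
u (batch, lifestyle, anything unmodelled). Inference follows the
Frisch–Waugh–Lovell two-step: residualize both y_j and the diet
indicator on the nuisance design Q = [1, age, sex, race, SV scores],
then regress residual on residual. β, SE and t equal those of the full
multiple regression, with df = n − ncol(Q) − 1; this identity is tested
against a full-design least-squares oracle to 1e-10.

Adjusted group means are computed at covariate means —
adj_vegan = ȳ + β(1−x̄), adj_nonveg = ȳ − βx̄ — so their difference is
exactly β and exp(β) is the geometric-mean fold-change ratio. CI
default is exp(β ± 1.96·se) (`ci="t"` switches to the t quantile).

### Surrogate variables

1. **Direction identification.** Residualize Y on the *full* design
   (intercept, diet, age, sex, race, BMI) and take the SVD of the
   residual matrix.
2. **Dimension choice** (`n_sv="auto"`): permutation parallel analysis
   with 19 permutations at α = 0.05, capped at k = 10. Each permutation
   scrambles every residual column independently and is re-residualized
   on the same design so the null spectrum lives in the same
   (n − rank Q)-dimensional row space; the variance the second
   projection removes is compensated exactly by √(n/(n−q)). Retained
   factors are counted until the first non-exceedance. On independent
   noise this yields k = 0 about 95% of the time; three strong planted
   factors are recovered as k = 3 essentially always.
3. **Reweighting** (one pass): each metabolite is weighted by the share
   of its residual variance explained by the initial factors,
   concentrating the decomposition on features actually affected by the
   unwanted variation.
4. **Scoring.** The surrogate scores are the leading left singular
   vectors of the *weighted nuisance-space residuals* — Y residualized
   on [1, age, sex, race] only, not on diet or BMI.

Step 4 is the one place the implementation is deliberately more careful
than a naive two-step: if scores are taken from the diet-residualized
matrix they are orthogonal to diet by construction, so whatever
component a real factor has along diet (by chance, or by confounding)
stays in the outcome and inflates the null t-scores — in simulation
this produced empirical FDRs above 0.5 under a diet-correlated factor.
Scoring in the inference-nuisance space lets the surrogate carry the
factor's diet- and BMI-aligned components, which are then removed from
*both* sides of the FWL fit. Under a factor with correlation 0.5 to
diet this restores median |β̂ − β| < 0.1 and empirical FDR ≈ 0.05,
at the price of absorbing a small part of genuine signal when effect
and factor directions overlap — the standard SVA trade-off.

## Composite subclass statistic

For subclass S with m annotated members, the composite effect is
B̄ = (1/m) Σ_{j∈S} β_j with

    Var(B̄) = (1/m²) Σ_{j,k∈S} σ̂_jk / (x̃ᵀx̃),
    σ̂_jk = r_jᵀr_k / df

where r_j are the inference-model residuals and df matches the
per-metabolite fits, so the diagonal terms reproduce se_j² and the
m = 1 case reduces exactly to the member's own t. Perfectly duplicated
members add no information (Var(B̄) = Var(β)); m independent members
with equal β = b and se = s give composite t = (b/s)√m. All three
reductions, plus an explicit GLS matrix-assembly oracle, are tested.
Ignoring the covariances (diagonal-only variance) inflates |t| by
~60% under within-subclass correlation 0.5 — the reason the composite
uses the full covariance. The subclass fold change is exp(B̄), the
exponentiated mean of member adjusted-log-mean differences, with CI
exp(B̄ ± 1.96·√Var(B̄)). Subclasses need ≥ 2 measured members;
singletons are excluded and logged.

## Permutation FDR

The joint null is built by permuting the residualized diet vector —
one permutation per draw, applied to all features — so the
between-feature covariance of the residualized abundances is retained.
Each permuted vector is **re-residualized on the nuisance design**: a
raw permutation is no longer orthogonal to the covariates, which
shrinks the null t-scores by roughly √((n−q)/n) and was measured to
push the empirical FDR from ≈0.05 to ≈0.067 at n = 93; re-projection
removes the mismatch.

- π̂0 = [#{|t_obs| ≤ λ}/p] / [#{|t_null| ≤ λ}/(Bp)], λ = median of the
  pooled null |t| (stable at small B), clipped to [1/p, 1].
- FDR(j) = min(1, π̂0 · p · P̂(|T| ≥ |t_j|) / #{k: |t_k| ≥ |t_j|}) with a
  +1 pseudo-count in the pooled tail, so the attainable floor is
  π̂0·p/(Bp+1); monotonicity is enforced step-up (cumulative minimum
  from the least significant feature towards the largest |t|).
- With π0 = 1 and a t-distributed reference null the assignment reduces
  to Benjamini–Hochberg on the corresponding p-values (tested).

The identical machinery runs at the subclass level on composite
t-scores; the per-permutation composite t has the closed form
S1·√(df·s)/√(Gsum − s·S1²) in terms of the member beta sum S1 and the
subclass Gram sum, which makes the null ensemble one matrix product.

Default B = 1000 (configurable); the manifest records the attainable
FDR floor rather than hard-coding any particular resolution.

## Resampling

**Bootstrap stability** redraws subjects with replacement, stratified
by diet group (unstratified draws at n ≈ 93 can produce degenerate
groups; a flag disables stratification). Surrogate scores and the
permutation null are re-estimated inside every resample; the SV *count*
is fixed at the parent cohort's data-driven choice so resamples differ
only through the data. Reduced inner permutation count (B = 200)
keeps the 100-resample default at seconds of runtime and is recorded in
the manifest. The identity-resample hook reproduces the parent
analysis exactly (inner seeds are aligned for resample 0).

**Cross-validation** partitions subjects into K stratified folds
(default K = 10). Per fold, nuisance coefficients and surrogate
loadings are estimated on the training folds; held-out surrogate scores
are obtained by projecting held-out residuals (using training
coefficients) onto the training loadings. The out-of-sample residual
variance Σ(y − ŷ)²/N (denominator N, the total sample size, exactly as
the procedure defines it) replaces the in-sample estimate in
Var(β) = variance/(N·var(x̃)), giving a deflated ("shrunken") t that is
re-submitted to the permutation FDR against the full-sample null. The
inflation is a property of the *average* — individual features can go
either way — so the monotonicity |t_shrunk| ≤ |t_full| is asserted
only where the CV variance exceeds the df-corrected in-sample variance.

## Multivariate analyses

- **PCA** on the covariance matrix of the centered (not
  variance-scaled) log matrix; at n samples and p > n features there
  are exactly n − 1 nonzero eigenvalues. Loadings for the high-loading
  threshold are feature–component *correlations* (eigenvector × √λ /
  feature SD) so a fixed 0.5 cutoff is scale-free. Optional outlier
  exclusion flags samples by robust (MinCovDet) Mahalanobis distance on
  the top-2 score plane, median-recalibrated against χ²₂ and cut at the
  0.999 quantile — always logged, never silent. The rule is
  approximate: axis selection makes the top-2 scores mildly
  heavy-tailed, so an occasional borderline sample is flagged alongside
  a gross outlier.
- **Component selection** by eigenvalue threshold (strict >), count, or
  cumulative variance; an empty selection falls back to the top
  component with a warning, since an eigenvalue cutoff is data-scale
  specific.
- **PC regressions / partial correlations**: ordinary least squares of
  each retained PC on a dietary variable plus age, sex, race, BMI
  (missing values mean-imputed); partial correlation as the Pearson
  correlation of residuals with df = n − 2 − #covariates.
- **Random forest**: CART trees on stratified ⌈0.5·n_class⌉ subsamples
  drawn *without* replacement; OOB majority votes give the
  misclassification error; importance is the mean decrease of a tree's
  OOB accuracy after permuting one feature, averaged over trees, with a
  per-feature Monte-Carlo SE. 50,000 trees is the full-fidelity
  profile; 5,000 is the default profile and leaves rankings stable in
  the regimes tested.

## Baseline statistics

Welch's unequal-variance t with Welch–Satterthwaite df, computed
directly from group summaries so published tables can be re-checked
from their printed cells, and the continuity-corrected (Yates)
chi-square n(|ad−bc|−n/2)²/(row·col margins) for 2×2 tables. The
continuity correction is used because it, and not the uncorrected
statistic, reproduces the published worked examples; both conventions
are standard at these sample sizes.

## Synthetic cohort generator

The generator emulates the target study design; its defaults are the
package's reference conditions:

| parameter | default | rationale |
|---|---|---|
| n_vegan / n_nonveg | 47 / 46 | study group sizes |
| n_metabolites | 930 | analytical panel size (93 subclasses of 10) |
| frac_nonnull | 0.63 | observed differential fraction (586/930) |
| effect \|log FC\| | \|N(log 1.8, 0.3)\|, P(neg) = 0.72 | typical published fold changes; 72% of differential metabolites decreased in vegans |
| residual_sd | 0.5 | mid-range untargeted-metabolomics CV on the log scale |
| n_latent / latent_sd | 3 / 0.3 | a few batch-like factors contributing ≈ half the residual variance — enough to matter, not enough to dominate |
| within_subclass_rho | 0.3 | moderate exchangeable correlation between chemically related metabolites |
| censor_quantile | 0.1 | mild detection-limit censoring |
| covariates | age N(63,10); sex, race Bernoulli(0.5); BMI group-shifted N(24.7, 3.4) / N(31.3, 7.0) | published baseline table |

BMI receives no direct metabolite effect by default: under the mediator
reading, diet → BMI → metabolite paths belong to the diet effect, and
the recorded truth `delta` covers only the direct path; a nonzero BMI
effect is available for mediator sensitivity experiments. Censoring is
deterministic by rank (the lowest values vanish), matching
detection-limit physics; the detection mechanism is this package's
choice, not an empirical fact about any instrument. Latent factor
scores can be correlated with diet (`latent_diet_corr`) to create true
confounding.

What passing tests on this generator do **not** show about real data:
the noise is Gaussian on the log scale with a single exchangeable
correlation per subclass (real metabolite panels have heteroskedastic,
heavy-tailed, block-structured correlation); censoring is exact-rank
(real detection limits wobble run-to-run); annotations are
non-overlapping; and there is no instrument drift within a batch.
Calibration results transfer to the extent these simplifications are
benign for rank- and permutation-based inference, which is their
purpose.

## Test-scale choices

The validation suite runs simulations at the study's own n (93) with
feature counts 150–930 and permutation ensembles B = 200–1000, 100
replicates for null calibration and 60 for the signal regime — sizes
chosen so Monte-Carlo error is small relative to the tolerances being
asserted. The empirical FDR of the full stack measured at these sizes
is 0.054 ± 0.004 against a 0.05 nominal (the idealized assignment
formula alone measures 0.0505 ± 0.002); π̂0 under the global null is
0.97 on average.

## Known limitations

- SVA at n ≈ 93 cannot fully separate a factor from diet when the two
  are strongly correlated; the implementation controls type-I error in
  the r = 0.5 regime tested, but recovery degrades as |r| → 1.
- π̂0 uses a single median-based λ; Storey's smoother is out of scope.
- The composite statistic assumes non-overlapping subclass membership.
- The permutation FDR floor is π̂0·p/(Bp+1); resolving FDRs much below
  1/B requires raising B.
- Mixed models, robust/sandwich errors and BMI mediation analysis are
  out of scope by design.
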