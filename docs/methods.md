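# Methods

## The model

`igwohealth` couples a swarm-based hyperparameter search with a bagged
decision-tree classifier for binary pediatric health-status prediction
(healthy vs subhealthy/diseased). The pieces are:

**Classifier.** A random forest: trees grown on bootstrap resamples, a
fraction `p_features` of columns considered at each split, depth capped at
`max_depth`, leaves of at least `min_samples_leaf = 5` samples. Prediction is
the majority vote across trees and the class-1 score of a sample is the
fraction of trees voting class 1 (not the average of leaf probabilities —
the distinction matters for the Shapley value function, which explains the
vote score). The implementation wraps scikit-learn's
`RandomForestClassifier`, whose bootstrap/subsample semantics match this
contract; the vote-fraction score is recomputed from the individual trees.

**Search space.** Three tuned dimensions: `n_trees` ∈ [50, 200] (integer),
`max_depth` ∈ [5, 15] (integer), `p_features` ∈ (0.3, 0.8] (continuous, open
below). Candidates live in the normalized unit cube [0, 1]³ and are decoded
affinely (integers by rounding, open ends nudged by 1e-9) only when a forest
is trained, so the swarm update equations are scale-free across mixed
integer/continuous ranges. Boundary repair is plain clamping to [0, 1]:
deterministic, idempotent, and the simplest operator satisfying the
box-constraint contract. `min_samples_leaf` is a fixed setting rather than a
fourth dimension. A note on `p_features`: expressed as a ratio; with 24 raw
features a per-split subset of 8 corresponds to a ratio of 8/24 ≈ 0.33.

**Fitness.** F(θ) = Σₖ Accuracyₖ − λ·Complexity(θ), the *sum* over K = 5
stratified cross-validation folds (a mean-mode flag exists but defaults
off), with λ = 0.01 and Complexity(θ) = n_trees/200 + max_depth/15 ∈ (0, 2].
The penalty's functional form was an open design choice; the normalized sum
is bounded, monotone in both arguments, and penalizes exactly the two
capacity knobs ("oversized ensembles and deep trees"). A second coefficient
α = 0.001 is carried in the config for completeness but attaches to no term
and is inert. CV folds are stratified and seeded (seed 42 by default).

**Optimizer.** Grey-wolf optimization: the three fittest wolves (α, β, δ)
jointly steer each member via D_k = |C_k·X_k − x|, X_k′ = X_k − A_k·D_k,
new position = mean of the three pulls, with A = 2a·r₁ − a and C = 2·r₂.
Three enhancements, each independently switchable:

* *Dynamic weight*: a = 2 − 2t/T, linear from 2 to 0. With the flag off the
  weight is held constant at a = 1 (the schedule's mean), which isolates the
  schedule itself while keeping |A| ≤ 1 bounded; the off-state is otherwise
  undefined, since the linear decrease is also the textbook baseline.
* *Elite opposition-based learning*: for the top 10% of the pack, one
  opposite X_new = X_best + F·(X_worst − X_best), F ~ U[0, 1] per elite.
  This interpolates toward the current worst member rather than reflecting
  through the box; the classical reflection (1 − x in the unit cube) is
  available behind `classical_opposition`. Opposites are accepted greedily:
  each replaces the current worst member only if strictly better.
* *Elite retention*: the top 20% of a generation keep guaranteed slots in
  the next; remaining slots go to the best moved candidates. The
  best-so-far archive is bookkeeping independent of retention, so its
  fitness series is non-decreasing under every flag combination.

Ranking happens once per iteration and both elite sets read from it; leader
ties break to the lower member index. Termination: iteration cap T (default
100, population 30) or |F(t) − F(t−1)| < 10⁻⁵ from the second iteration on,
where F is the best-so-far series — note this stops the run after any
fitness-flat iteration, which is the printed criterion taken literally and
in practice trades a small success-probability loss for large savings on
plateaued runs.

All randomness derives from one seed split into named streams (`init`,
`updates`, `opposition`, …) so disabling one component does not shift the
draws any other component sees; runs are bit-reproducible.

**Baselines.** Canonical global-best PSO (ω = 0.7 from the comparison
protocol; c₁ = c₂ = 1.5 chosen as the standard values since the protocol
names only ω) and uniform random search under the same contract. A
config knob `dynamic weight factor = 0.9` appears in the comparison
protocol with no accompanying equation; it is recorded but unused, as is an
"exploration–exploitation balance factor 0.8".

**Feature-selection mode.** A binary variant thresholds continuous
positions at 0.5 into masks, initializes with Levy-flight perturbations
(Mantegna algorithm, stability index 1.5, step scale 0.1 of the cube) and
jitters steps by a Cauchy mutation whose scale decays as 1 − t/T; an
all-zero mask is repaired by activating one uniformly random feature. Levy
and Cauchy parameters are named but not quantified in the source protocol;
the values here are the common defaults in the Levy-flight metaheuristic
literature.

**Shapley interpretation.** The coalition value f(S) is the interventional
expectation over a background set (default: 100 training rows): features in
S take the explained sample's values, the rest come from the background
row. Exact enumeration over all 2^d coalitions is the oracle up to d = 15;
the production path for the 24-feature cohort is permutation sampling
(default 2000 permutations), unbiased with error ~ 1/√m. Pairwise synergy
uses the standard Shapley interaction index — the weighted second
difference f(S∪{i,j}) − f(S∪{i}) − f(S∪{j}) + f(S) over coalitions
excluding the pair. (The source material sketches an alternative identity
for interaction values mixing products of main effects with an expected
second derivative; it is dimensionally unclear and is deliberately replaced
by the standard index, which satisfies the usual axioms and reduces to it
on multilinear games.) Importance is the mean |φᵢ| across attributed
samples, ranked descending with lexicographic tie-breaks.

## The synthetic cohort

No public version of the study dataset exists, so a generator reproduces
its statistical shape; all counts are assigned exactly rather than sampled:

| quantity | value |
|---|---|
| children | 1852 (846 male / 1006 female as metadata) |
| classes | 1402 healthy / 450 subhealthy (75.7% / 24.3%) |
| subgroups | obesity 187, lipid 93, respiratory 86, hypertension 84 |
| age | truncated normal on [3, 12], post-truncation mean solved to 7.2 (σ = 2.3 pre-truncation; realized SD ≈ 2.0, reported not forced) |
| missingness | exactly round(0.032·n·24) cells, MCAR, labels never masked |

The 24 features follow the study's inventory (10 physiological, 4
environmental, 6 behavioral); because the inventory itemizes only 20 names,
four synthetic-only placeholders complete the frame (sleep quality score,
BMI-for-age percentile, household income proxy, indoor humidity), kept
near-noise so they cannot rival the planted signals. Two features are
categorical (dietary habits: good/average/poor; smoking exposure: no/yes)
to exercise one-hot encoding.

Structure is planted as mean shifts (units as in the table below; all other
features are age-correlated noise or weak effects):

| effect | size |
|---|---|
| BMI, all subhealthy | +2.4 kg/m² (healthy mean 16.2, SD 1.4) |
| BMI, obesity subgroup extra | +4.4 kg/m² (past the 19.8 anchor = 85th-percentile BMI for 6–12 y) |
| exercise time, subhealthy | −22 min/day (healthy 55 ± 15) |
| PM2.5, subhealthy | +11 µg/m³ (healthy 48 ± 14); respiratory extra +24 |
| cholesterol / triglycerides / HDL, lipid subgroup | +1.3 / +0.7 / −0.3 mmol/L |
| systolic BP, hypertension subgroup | +18 mm Hg (plus 0.8·BMI coupling) |
| screen time / sleep / diet / smoking / others | smaller signed effects |

BMI = weight/height² holds exactly by construction (weight is derived).
These effect sizes were calibrated once so that (a) a forest at
(150 trees, depth 12, feature fraction 0.33) exceeds 0.85 held-out accuracy
and (b) BMI ranks first by mean |SHAP| with exercise time and PM2.5 close
behind, mirroring the study's reported importance ordering; the constants
live in one table in `cohort.py` and changes must preserve those two
properties.

What the generator does **not** emulate: the real joint distribution
(features are conditionally Gaussian given class/subgroup, with only a few
explicit couplings), non-MCAR missingness, measurement error structure,
site effects, or longitudinal dynamics. Passing tests therefore show the
pipeline recovers *planted* signal under clean conditions — they say
nothing about performance on real clinical data.

## Preprocessing

Chained-equations imputation (5 cycles): missing cells start at the column
mean (mode for categoricals); each cycle regresses every incomplete column
on all others — ordinary least squares for continuous targets,
nearest-class-centroid assignment for categorical ones — and replaces only
the missing entries. The conditionals are deliberately lightweight (the
method prescribes the chained scheme, not the conditional family), and the
sweep is deterministic. Imputation runs before outlier handling so Tukey
fences are computed on complete columns.

Winsorization caps values beyond Q1 − 1.5·IQR / Q3 + 1.5·IQR at the 1st /
99th percentiles (linear-interpolation percentile estimator). That printed
combination — detect by fences, cap at percentiles — is unusual but
implemented as stated; a cap-at-fences variant would be the textbook
alternative. The operation is a fixed point whenever the 1st/99th
percentiles lie inside the fences (true when outliers make up less than 1%
of a column); with grosser contamination a second application can re-cap
the capped values, which is inherent to the printed rule.

Min-max scaling maps each continuous column to [0, 1]; constant columns map
to 0 with a warning; parameters are fit on the training split only, so test
values may spill slightly outside [0, 1] (no clipping, keeping the inverse
exact). One-hot encoding keeps every level, lexicographic order, and fails
loudly on unseen categories. The stratified split apportions per-class
training seats by largest remainder of round(0.7·n), reproducing the study
sizes 1296/556 exactly for the 1402/450 cohort.

## Experiments harness

`run_tuning`, `run_ablation`, `run_comparison` share one protocol: simulate
(or load) → preprocess → tune on the training split via the CV fitness →
refit at the α wolf's configuration → full metric suite (accuracy,
precision, recall, F1, rank-based AUC, Cohen's κ) on the test split, with
class 1 (the minority risk class) as positive. Ablation variants and
comparison arms share the identical cohort, split and aligned seed streams
within a run; result files embed the resolved config and every seed, so a
result is reproducible from its own metadata. "Without elite retention"
keeps the best-so-far archive (reporting) but stops injecting elites into
the population. Cross-model significance uses a paired t statistic over
per-seed test metrics with Bonferroni adjustment; the pairing unit
(repetition seed) was an open choice. Two soft checks — full model ≥ each
ablated variant, tuned ≥ fixed baseline — log warnings rather than fail:
on a strongly-signaled synthetic cohort the tuning landscape is nearly
flat on top, so orderings among near-ties are seed noise.

## Problem sizes and numerical choices

Unit and property tests run on a 400-child cohort with the same class and
subgroup proportions, and on analytic fitness surfaces (quadratic,
Rastrigin-style, discretized 3×3×3 grids); the acceptance path runs the
full 1852-child cohort with desk-scale tuning budgets (5 wolves, 4
iterations) and Shapley sampling at 25 permutations over 15 test rows with
a 40-row background — sizes chosen so the whole suite runs comfortably on
one CPU while leaving the assertions' margins wide. Key tolerances: Shapley
efficiency 1e-9 (exact mode), enumerator-vs-orderings oracle 1e-12,
optimizer/grid oracle equality 1e-9, convergence tolerance 1e-5 as
specified. The empirical diversity corollary for opposition-based learning
(mid-run pairwise distance with the mechanism on vs off) is reported with a
warning rather than asserted: interpolation toward the worst member is not
guaranteed to widen spread on every landscape, and on the Rastrigin-style
test surface it sits within noise of the off-state.

## Known limitations

* The sum-over-folds fitness makes λ's leverage depend on K; the mean-mode
  flag exists for cross-package comparison.
* Exact Shapley is exponential in d; the d ≤ 15 guard is a hard refusal.
* MICE with linear conditionals will underfit strongly nonlinear
  missing-data relationships; the generator's MCAR mechanism cannot probe
  MNAR sensitivity.
* The flat-iteration termination rule can stop a run that would still have
  improved; raise the iteration budget or lower the tolerance only by
  accepting its literal definition.
* Synthetic-cohort results are calibration checks, not clinical evidence.
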