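# Methods

## Problem and model

A two-arm placebo-controlled trial can be null on average yet contain
subgroups with real — and oppositely signed — treatment effects. A
qualitative interaction tree partitions participants by baseline covariates
into leaves with homogeneous *treatment effects* and labels each leaf
P1 (treatment responders, active beats placebo), P2 (iatrogenic responders,
placebo beats active), or P3 (nonresponders). A partition is admissible only
when both a P1 and a P2 leaf exist: the method deliberately searches for
*qualitative* (sign-reversing) interactions, and reports "no qualitative
interaction" otherwise.

### Leaf statistics

Within a leaf, the placebo-minus-active mean difference Δ uses the
pooled-variance standard error
`SE = s_pool * sqrt(1/n_p + 1/n_t)`,
`s_pool² = ((n_p−1)s_p² + (n_t−1)s_t²)/(n_p+n_t−2)`, and the standardized
effect is Cohen's `d = (mean_active − mean_placebo)/s_pool` (positive =
active arm reduces drinking more; note `Δ = −d·s_pool`). The 95% CI for d is
normal-theory, `d ± 1.96·SE/s_pool`. Pooled (not Welch) variance was chosen
because it reproduces published per-leaf SE columns of this kind of analysis
exactly; a Hedges small-sample correction is available behind a flag but off
by default (plain Cohen's d is the reporting convention).

### Partitioning criterion

```
C = a1·[log(1+D1) + log(1+D2)] + a2·[log(N1/N) + log(N2/N)]
```

with D1 the size-weighted mean d over P1 leaves, D2 the size-weighted mean
−d over P2 leaves, and N1/N2 the P1/P2 participant counts. The two terms
balance effect magnitude against subgroup size; both weights default to 1.
A leaf is P1-eligible when `d ≥ dmin` and P2-eligible when `d ≤ −dmin`
(default `dmin = 0.30`, a conventional small-to-moderate effect floor;
configurable because classification near the boundary is sensitive to it).
The log-saturating form is the standard criterion of the QUINT methodology;
the source analyses state only the two balanced components, so the
functional form is adopted from the method literature and exposed through
`a1`, `a2`.

For equal positive weights and `dmin > 0`, the criterion simplifies to
`a·[log((N1+Σ n·d)/N) + log((N2−Σ n·d)/N)]` and the optimal assignment
provably includes *every* eligible leaf (each eligible leaf multiplies its
pool's term by a factor > 1). The split search exploits this closed form,
vectorized over all candidate thresholds via per-arm prefix sums; with
unequal weights it falls back to exhaustive assignment enumeration (≤ 3^k
for k leaves, k ≤ 8). Equivalence of the two paths is property-tested.

### Growth, pruning, prediction

Growth is greedy: every (leaf, predictor, threshold) triple is scored by the
criterion of the resulting full leaf set under the optimal assignment;
candidate thresholds are midpoints of consecutive distinct observed values;
splits leaving any child arm below `min_per_arm` (default 10, matching the
smallest published per-arm leaf) are inadmissible; ties break toward the
earlier leaf, earlier predictor, smaller threshold, for reproducibility.
Growth stops when no split strictly improves the criterion or at
`max_leaves` (default 8). Greedy growth is *not* a global optimizer: a
deeper tree reachable only through an inadmissible or lower-scoring
intermediate split will be missed; the oracle tests therefore verify
step-exactness (each step equals brute-force enumeration of its candidate
space) and global optimality at two leaves, where greedy and global
coincide.

Tree size is selected by a bias-corrected bootstrap (default `B = 200`,
resampling stratified by arm to preserve the 1:1 design). For each nested
size k from the growth trace, the optimism `o_k = mean(c_boot − c_orig)` is
estimated by regrowing on each resample and evaluating its size-k subtree on
the resample (`c_boot`) and on the original table (`c_orig`, assignment
re-optimized); both sides use the same evaluator, so a degenerate identity
resample yields exactly zero optimism. Replicates whose regrowth has no
admissible size-k subtree, or whose evaluation on the original data is
degenerate, are dropped and counted. The selected size is the smallest k
whose corrected criterion `Ĉ_k = C_k − o_k` is within
`c_se · SE(argmax)` (default `c_se = 1`) of the maximum; leaves of the
selected subtree are re-classified on the full table. Prediction routes a
record down the tree with "value ≤ threshold goes left" (ties left).

### Validation and model comparison

The optimism of the leaf-effect *range* (max − min over leaves, Cohen's d
scale by default, Δ scale available) is estimated with `B = 1000`
same-size refits on stratified resamples: `O_range` is the mean of
(range on resample − range of the same tree evaluated on the original data),
and `inflation_pct = 100·O_range/observed_range`. Positive values mean the
fitted model overstates the spread of subgroup effects. When the original
data admit no tree at the probed size (typical for null data), the observed
range and inflation are NaN but `O_range` is still estimated from the
admissible replicates — this is what the null sanity check uses.
The cross-outcome comparison routes participants through each fitted tree
and recomputes per-leaf d (with CI) on every outcome's complete cases,
flagging leaves where an arm has fewer than two complete cases.

## Outcome derivation

Day 0 is randomization; the baseline window is days −28..−1 and the
maintenance phase Weeks 2–25, i.e. days 8..175 (the titration week is
excluded). A heavy drinking day (HDD) is ≥ 4 standard drinks for females,
≥ 5 for males (thresholds inclusive). `pHDD_maint` is computed over
*observed* diary days only — zero-filling would fabricate abstinence for
dropouts — and a participant with no observed maintenance day has a missing
outcome. `raw_change = (pHDD_base − pHDD_maint)·28` is expressed in heavy
days per 28-day period so that its magnitude is commensurate with published
per-leaf means on a 0–28 scale (a total-count scale over the 168-day phase
would be six times larger); this per-28-day convention is an assumption,
recorded here, since the alternative cannot be ruled out from the published
values. `prop_change = (pHDD_base − pHDD_maint)/pHDD_base` is undefined
(NaN, record retained) when the baseline has no heavy days. The baseline
anchor is configurable (the windows are passed explicitly); day 0 =
randomization is the default convention throughout.

## Missing data

* **Predictor items**: deterministic chained-regression imputation — columns
  with missing cells are initialized at their medians, then swept 10 times
  in a seed-fixed random order, each regressed on all other predictors by
  exact least squares; ordinal/binary predictors snap to the nearest legally
  observed value (distance ties to the smaller). Observed cells are never
  altered. Single completed dataset per seed; no multiple-imputation
  pooling. The scheme is the simplest deterministic chained method; exact
  least squares makes perfectly collinear relations reproduce to numerical
  precision.
* **Item exclusion**: scale items whose missing/not-applicable fraction
  reaches 0.10 (inclusive ≥, so an exactly-10%-missing item is dropped) are
  excluded from their scale trial-wide before imputation and logged; scale
  scores are sums of the retained (observed + imputed) items.
* **Compliance**: missing weekly entries are zero-filled (medication is
  dispensed at weekly visits; a missed visit means no dispensation) and the
  total recomputed.
* **Outcomes**: two strategies, compared by the validation harness —
  `exclude` drops participants with missing maintenance outcomes; `impute`
  fills the change scores by the same least-squares mechanism from the
  completed predictor battery. Which shows less optimism is data-dependent;
  the harness reports both.

## Synthetic trial generator

The generator emulates the *structure* of a multisite alcohol
pharmacotherapy trial, not any particular trial's numbers: N = 338 by
default, 1:1 permuted-block randomization (block size 4) stratified across
10 sites, 34% female, a 20-variable mixed-type baseline battery (log-normal
drinking quantities, 1–10 motivation/confidence ratings, bounded-integer
anxiety/depression/impulsivity/sleep scales, binary smoking, five
consequence-scale items of which two carry high not-applicable rates of 25%
and 10%) drawn from a Gaussian copula with exchangeable correlation 0.3.

Treatment effects are planted on the proportion-change scale: participant i
in subgroup g gets latent
`pc_i = 0.35 + active_i·d_g·σ + σ·ε_i`, σ = 0.30 by default, so the
standardized arm difference within g is d_g (positive favors active).
Baseline %HDD is `clip(0.55 + 0.12·z, 4/28, 0.95)` with z tied to the
drinks-per-week covariate when present (enabling MAR dropout), and the
maintenance %HDD target is `pb·(1−pc)` clipped to [0,1]. Daily diaries then
realize exactly `round(28·pb)` baseline and `round(168·pm)` maintenance
heavy days at random positions, with drink amounts above/below the
sex-specific threshold — so downstream outcome derivation exercises the real
diary path. σ = 0.30 is realistic for proportional-change outcomes (observed
leaf SDs in published analyses of this design span ~0.24–0.86) and keeps
clipping negligible, so planted d values are recovered to ±0.05 at
N = 10,000. Outcome dropout (default rate 0.1775) removes *all* maintenance
diary days, either completely at random or, with the MAR option, with
logistic probability in baseline drinking calibrated to the target rate.
Item missingness is independent Bernoulli per item.

What the generator does **not** emulate: real covariate marginals or their
empirical correlation matrix, partial (day-level) diary missingness,
site-level effect heterogeneity, measurement error in self-report, or
informative missingness in predictors. Passing recovery tests therefore
demonstrates algorithmic correctness under the stated data-generating
process, not clinical validity on real trial data.

## Numerical choices and degenerate inputs

* Leaf d is undefined (leaf ineligible, only P3) when an arm has < 2 records
  or the pooled variance is zero; sums of squares are clamped at 0 against
  floating-point cancellation.
* The criterion is None (used as −∞ by the search) for inadmissible
  assignments; an all-P3 assignment is admissible only for the degenerate
  root-only tree.
* Assignment ties favor more P3 leaves, then the lexicographically smaller
  class tuple (P1 < P2 < P3 per leaf).
* Tree JSON stores thresholds at full precision (shortest round-trip float
  repr) with the rule text rendered as `feature <= threshold`; reloading and
  re-serializing is byte-identical.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; every stage is byte-reproducible under a fixed seed.

## Problem sizes used by the test suite and acceptance script

Recovery and specificity are measured at N = 600 with four covariates
(one planted), d = ±0.8, pruning B = 200, 50 replicates in the test suite
(10–20 in the acceptance script); optimism sanity at N = 338 with B = 200;
oracle equivalence on 100 instances of N ≤ 30 with ≤ 2 predictors and ≤ 3
leaves; convergence of the generator at N = 10,000. These sizes give stable
pass/fail margins (recovery and specificity both measure ≈ 100% against
≥ 90% requirements) while keeping the full suite to a few minutes on one
CPU.

## Known limitations

* Greedy growth can miss partitions whose qualitative interaction only
  emerges two splits deep (the first split must itself be admissible).
* No honest/sample-split inference on leaf effects: leaf CIs are computed on
  the same data that selected the partition and inherit the optimism the
  validation module quantifies.
* Numeric-only splits; ordinal/binary predictors are treated as numeric
  (all-subsets categorical splits are out of scope).
* Two arms only; no survival or longitudinal outcome types; no surrogate
  splits for records missing a split feature (routing such a record raises).
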