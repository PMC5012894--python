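# Methods

## The model

Two views of the same `n` samples are observed: `X` (`n x p`, wide — e.g.
voxelwise grey-matter probabilities) and `Y` (`n x q`, narrow — e.g. the
per-item scores of a 30-item cognitive exam). Partial Least Squares (PLS)
seeks unit weight vectors `u, v` maximising the covariance of the
projections,

```
max  u' X' Y v    s.t.  ||u||2 = ||v||2 = 1 ,
```

solved by the leading singular-vector pair of the cross-covariance
`C = X'Y`. Sparse PLS (SPLS) adds l1 budgets `||u||1 <= c_u`,
`||v||1 <= c_v`. Because a unit-l2 vector of dimension `d` satisfies
`1 <= ||w||1 <= sqrt(d)`, the admissible budget range is `[1, sqrt(p)]` and
`[1, sqrt(q)]`; the lower end forces a single feature, the upper end leaves
the constraint inactive. Smaller budgets mean fewer selected features. The
guarantee that at least one feature always survives is the reason the l1
*constraint* formulation is used rather than fixing the soft-threshold
level directly (which can zero out a whole weight vector).

### Solver

The solver alternates

```
u <- P(C v, c_u),     v <- P(C' u, c_v)
```

from the leading-SVD initialisation of `v`, where `P(a, c)` maximises `w'a`
over the intersection of the l2 unit ball and the l1 ball of radius `c`:
soft-threshold `a` at level Δ and renormalise, with Δ = 0 when the plain
renormalised vector already meets the budget and otherwise the unique
Δ > 0 at which the renormalised thresholded vector has `||.||1 = c`.

**Δ search.** `||S(a,Δ)||1 / ||S(a,Δ)||2` is continuous and non-increasing
in Δ, and algebraic between consecutive sorted magnitudes of `a` (where
the surviving support is fixed). We therefore locate the active segment by
a monotone scan over the sorted breakpoints and solve the quadratic
`(S1 - kΔ)^2 = c^2 (S2 - 2ΔS1 + kΔ^2)` (with `S1, S2` the partial sums of
the top-`k` magnitudes) in closed form, instead of bisecting on Δ
numerically. This is exact to floating point and removes a tolerance
parameter; property tests compare it against a brute-force bisection
oracle.

**Unattainable budgets.** When the largest magnitudes of `a` are exactly
tied, the renormalised l1 norm cannot drop below `sqrt(#ties)`; a budget
below that is unattainable by thresholding and the projection
deterministically keeps the tied entry with the lowest index at magnitude
one (preserving the at-least-one-feature guarantee).

**Convergence.** Iteration stops when the largest elementwise change of
`u` and `v` (after joint sign alignment) is at most `tol` (default `1e-6`)
or after `max_iter = 500` iterations; a non-converged fit is returned with
`converged=False` and a warning — near-degenerate (noise-only) data can
oscillate between near-tied supports. The nonconvexity also means the
monotonicity of support size in the budget, while reliable on
signal-bearing data, can be broken by local optima on pure noise.

**Sign convention.** `u` has the same elementwise signs as `C v` after
thresholding, so the captured covariance `u'Cv` is non-negative by
construction; the joint sign (which leaves `u'Cv` unchanged) is pinned by
forcing the largest-magnitude entry of `u` positive. The same convention
is applied to the plain SVD solution so the two agree exactly at inactive
budgets.

The two numerical kernels (projection and alternating loop) are compiled
with numba when available and run as plain Python otherwise.

## The multiple hold-out framework

Per candidate effect:

1. **Split plan.** 10 random carve-outs of 10% of the samples as hold-out
   sets; within each remaining pool, K = 100 random 80/20
   training/testing subsamples. Sizes are `round(frac * n)`; index sets are
   drawn with scikit-learn's `ShuffleSplit` and are fully reproducible
   from the master seed. The same subsamples are reused for every
   hyper-parameter combination.
2. **Grid search.** 40 x 40 budget combinations, equidistant on
   `[1, sqrt(p)] x [1, sqrt(q)]` (1600 fits per subsample). For each
   combination the mean over the K subsamples of the absolute Pearson
   correlation between the projected test views is computed; the maximum
   wins. Ties are broken towards the smaller `c_u + c_v` (the sparser
   model), then the lowest grid index, making the selection invariant to
   evaluation order.
3. **Permutation test.** The model is refit on the whole pool with the
   selected budgets and the hold-out data are projected to give
   `rho = |corr(X* u, Y* v)|`. B = 10,000 permutations shuffle the rows of
   one view of the *pool* (Y by default; configurable), refit with the
   same budgets, and re-project the intact hold-out data;
   `p = (1 + #{rho_b >= rho}) / (B + 1)`, which is bounded below by
   `1/(B+1)` and exact on enumerable nulls. Zero-variance projections
   count as correlation 0, which is conservative.
4. **Omnibus decision.** With S = 10 hold-out splits and a family-wise
   error rate of 0.05, each split is tested at `alpha = 0.05/10 = 0.005`;
   the omnibus null is rejected iff any split's p-value is at most alpha.
5. **Deflation and continuation.** On rejection, the significant pair with
   the lowest p (ties: larger hold-out correlation, then lowest split
   index) deflates the working matrices, a fresh split plan is drawn, and
   the procedure repeats; it stops at the first non-rejection or after
   `max_effects` effects.

With plain PLS there is nothing to tune, so step 2 is skipped.

### Deflation strategies

* **projection** (default): `X <- X - (Xu)u'`, `Y <- Y - (Yv)v'`. Removes
  every sample's component along the weight direction; the deflated matrix
  annihilates the weight exactly, pushing successive sparse pairs towards
  orthogonality. Sparse weight pairs are only pseudo-singular-vectors, so
  exact orthogonality across effects is not guaranteed — the absolute
  inner products of successive X-weights are a useful diagnostic but are
  not asserted.
* **pls**: the classical PLS regression residual (scores
  `xi = Xu/(u'u)`, loadings `a = X'xi/(xi'xi)`, residual `X - xi a'`).
* **hotelling**: `C <- C - (u'Cv) uv'` on the cross-covariance. Because it
  deflates the covariance rather than the data, there are no deflated data
  matrices to project and it cannot be combined with hold-out evaluation;
  `run_framework` refuses the combination, and the operation is provided
  for covariance-only workflows.

### Standardisation

All features are z-scored. Two placements are provided:

* `global` (default): one-shot standardisation of the full dataset before
  the run; every later stage (grid search, permutation test, deflation)
  operates on those fixed coordinates.
* `per_split`: statistics come from each training portion
  (subsample-train for the grid search, pool for the permutation stage)
  and are applied to the corresponding test/hold-out portions — no
  statistics ever flow from test or hold-out samples into a fit.

Global is the default for two reasons. First, it is the conventional
pipeline for this analysis (features are centered and scaled once before
any modelling). Second, and more importantly, SPLS maximises
*covariance*, so sequential extraction relies on deflated directions
staying shrunken: re-standardising after each deflation (which the
per-split placement implies) rescales the residual columns back to unit
variance and resurrects part of the removed effect, which the next
permutation round then flags as a spurious additional effect. We measured
exactly this on single-effect synthetic data: spurious second effects in
roughly half the runs under per-split placement versus about one in
twenty under global placement, with identical weight estimates for the
first effect. The cost of the global mode is that feature means and
variances are estimated on all samples, including hold-outs; only those
two per-feature moments leak, not any association between the views,
and the permutation null is computed under the identical standardisation,
so the hold-out test remains calibrated (verified under the null in the
test suite).

In per-split mode, deflation still has to act in the coordinates the
weights were estimated in: the working matrices are standardised with the
selected split's pool statistics, deflated there, and mapped back to the
original scale before the next effect's split plan is drawn.

The population SD (divisor `n`) is used; a zero-variance training feature
is left centered with a unit divisor and a logged warning.

Whether hold-out data should be deflated with the selected pair or
re-derived is genuinely open; we deflate *all* working data with the
selected pair, since the correlations for effect `h+1` must be computed on
data with effect `h` removed, and draw a fresh split plan per effect.

### Randomness and reproducibility

Every random draw flows from `master_seed` through `numpy.SeedSequence`:
split plans use a per-effect derived seed, and permutation `b` of split
`s` uses a seed derived from `(master_seed, effect, split)` spawned per
permutation, so runs are bit-reproducible and safe to shard by
`(split, permutation)`. p-values are rounded to 4 decimal places in the
delimited report tables only; decisions always use unrounded values.

### Computational cost

Per effect the framework performs
`n_splits * (grid_size * K + 1 + B)` model fits
(`10 * (1600*100 + 1 + 10000) = 1,700,010` at reference settings), versus
`(B + 1) * n_outer * (grid_size * n_inner + 1)` for a nested
cross-validation with permutation-wide re-tuning
(`1001 * 5 * 8001 = 40,045,005` with 5x5 folds and 1000 permutations) —
about 4%. `count_framework_fits` / `count_nested_cv_fits` compute both,
and an instrumented `FitCounter` verifies the formula against actual runs.

## Synthetic data

`simulate` builds `X = sum_h a_h t_h u_h*' + E`, `Y = sum_h a_h t_h v_h*' + F`
with standard-normal latent scores `t_h`, unit-norm sparse weights on (by
default) disjoint supports with magnitudes uniform on [0.8, 1.2] and random
signs, strictly decreasing strengths `a_h` (default geometric decay from
4.0), and independent Gaussian noise (default SD 1). `H = 0` gives
independent views (the null regime). `binary_y` dichotomises Y at
per-feature medians into {1, 2}, mimicking right/wrong item coding.

Desk-scale defaults are `n=120, p=500, q=30` with 10 of 500 and 5 of 30
active features — large enough to exercise sparsity, small enough for
minute-scale tests. The generator does **not** emulate spatial
autocorrelation of voxel maps, site/scanner effects, item difficulty
curves, or non-Gaussian tails; passing tests show the machinery behaves
correctly under the model's own assumptions, not that real data satisfy
them.

Problem sizes in the test suite are scaled to keep the full run at
minute scale: support-recovery uses 20 seeds of the default-size generator
with K=20, B=200 and a 5x5 grid; the null calibration uses 200 datasets
at `n=60, p=30, q=8` with B=99; the solver/SVD equivalence uses 20 random
`30 x (10, 8)` instances.

## Support identifiability and grid resolution

A unit-l2 vector with `||w||1 = c` has at least `ceil(c^2)` nonzero
entries. Consequently the support sizes a grid search can produce are
bounded below by the squared budgets on the grid: a coarse 5-point grid on
`[1, sqrt(500)]` steps from `c_u = 1` (1 feature) straight to
`c_u ≈ 6.34` (at least 41 features), so a planted 10-feature support can
never be matched closely at that resolution, even at high SNR — the
selected budget either undershoots or binds with extra small noise
entries. Support-faithful recovery of an `s`-sparse weight needs a grid
point near `sqrt(s)`; the default 40-point grid (spacing ≈ 0.55 for
p=500) provides one. Recovery with oracle budgets (`c = ||u*||1`) is
exact at high SNR; the acceptance suite measures both.

Grid resolution also feeds back into sequential extraction through
**deflation leakage**: deflating with an imperfectly estimated pair
leaves a residual of the true effect proportional to `sin` of the angle
between the estimated and true weights, in both views. At coarse grid
resolution the wide-view weight carries many small off-support entries
(alignment ≈ 0.93 in the measured regime), and the residual association
is strong enough that the next round's permutation test — behaving
exactly as designed — often declares a spurious "second effect" on
single-effect data. At the default 40-point resolution the estimate is
sharp enough for the residual to fall below detectability.

## Known limitations

* The alternating scheme is a heuristic for a nonconvex problem: it
  converges to a fixed point, not a certified global optimum.
* Ten Bonferroni-corrected splits make the omnibus rule strict; on small
  samples the test is conservative (false negatives more likely than
  false positives). With B permutations the smallest achievable p is
  `1/(B+1)`, so B must exceed `S/fwer - 1` for a rejection to be possible
  at all.
* Hold-out sets at 10% of small n yield noisy hold-out correlations; this
  is the motivation for using 10 splits rather than one.
* `per_split` standardisation combined with deflation mixes coordinate
  systems (weights from standardised data deflate raw working matrices);
  the `global` mode avoids this at the price of a one-shot standardisation
  computed on all samples.
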