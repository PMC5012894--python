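"""Multiple hold-out learning and validation framework.

The procedure, per associative effect:

1. Carve out 10% of the samples as a hold-out set; split the remaining
   train/test pool K=100 times into 80% training / 20% testing subsamples.
2. Grid search: for every sparsity combination (c_u, c_v) on a 40x40 grid
   spanning [1, sqrt(p)] x [1, sqrt(q)], fit SPLS on each training
   subsample, project the testing subsample and average the absolute
   Pearson correlation of the projections over the K subsamples (the same
   subsamples for every combination); keep the combination with the
   highest average.
3. Train on the whole pool with the selected budgets, project the hold-out
   data onto the weights and record the absolute hold-out correlation rho.
   Build a null distribution by permuting the rows of one view of the pool
   B times, refitting with the same budgets and re-projecting the intact
   hold-out data; the p-value is (1 + #{rho_b >= rho}) / (B + 1).
4. Repeat steps 1-3 for 10 random hold-out carve-outs. The omnibus null
   hypothesis ("no split shows an effect") is rejected if any of the 10
   p-values falls at or below the Bonferroni-corrected level
   alpha = FWER / 10 = 0.005.
5. If rejected, the significant pair with the lowest p-value (ties broken
   by the higher hold-out correlation) deflates all data, and the search
   continues for the next effect; otherwise the framework stops.

With plain PLS there are no hyper-parameters, so step 2 is skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.model_selection import ShuffleSplit

from .core import (
    DegenerateInputError,
    InvalidStateError,
    SparsityPair,
    WeightPair,
    _pls_rank1_cov,
    _spls_cov,
    _init_v,
    cross_covariance,
)
from .data import TwoViewDataset
from .deflation import pls_deflate, projection_deflate

logger = logging.getLogger(__name__)

__all__ = [
    "FitCounter",
    "FrameworkConfig",
    "SplitPlan",
    "GridSearchResult",
    "PermutationOutcome",
    "SplitRecord",
    "EffectRecord",
    "standardize",
    "make_split_plan",
    "sparsity_grid",
    "test_correlation",
    "grid_search",
    "permutation_p_value",
    "permutation_test",
    "omnibus_decision",
    "select_best_pair",
    "run_framework",
    "count_framework_fits",
    "count_nested_cv_fits",
]


class FitCounter:
    """Counts model fits; used to audit the framework's computational cost."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, k: int = 1) -> None:
        self.count += k


@dataclass
class FrameworkConfig:
    """Flat, serialisable configuration of the full framework."""

    method: str = "spls"  # "spls" or "pls"
    deflation: str = "projection"  # "projection" or "pls"
    n_holdout_splits: int = 10
    holdout_frac: float = 0.10
    K: int = 100
    train_frac: float = 0.80
    grid_points_u: int = 40
    grid_points_v: int = 40
    B: int = 10000
    fwer: float = 0.05
    max_effects: int = 3
    permute_view: str = "y"  # which view's rows are shuffled in the null
    standardize_mode: str = "global"  # "global" or "per_split"
    master_seed: int = 0
    tol: float = 1e-6
    max_iter: int = 500

    def validate(self) -> None:
        if self.method not in ("spls", "pls"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.deflation == "hotelling":
            raise ValueError(
                "Hotelling deflation acts on the cross-covariance matrix, not the "
                "data, so it cannot be combined with hold-out evaluation"
            )
        if self.deflation not in ("projection", "pls"):
            raise ValueError(f"unknown deflation method {self.deflation!r}")
        if self.permute_view not in ("x", "y"):
            raise ValueError("permute_view must be 'x' or 'y'")
        if self.standardize_mode not in ("per_split", "global"):
            raise ValueError("standardize_mode must be 'per_split' or 'global'")
        if not (0.0 < self.holdout_frac < 1.0 and 0.0 < self.train_frac < 1.0):
            raise ValueError("holdout_frac and train_frac must lie in (0, 1)")
        for name in ("n_holdout_splits", "K", "grid_points_u", "grid_points_v", "B"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.max_effects < 0:
            raise ValueError("max_effects must be non-negative")
        if not (0.0 < self.fwer < 1.0):
            raise ValueError("fwer must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitPlan:
    """Reproducible index sets for hold-out carve-outs and subsamples.

    ``holdout_splits[s]`` is a pair of absolute row-index arrays
    ``(pool_idx, holdout_idx)`` partitioning the samples;
    ``subsamples[s][k]`` is a pair ``(train_idx, test_idx)`` of positions
    *within* the pool of split ``s``. The same K subsamples are reused for
    every hyper-parameter combination.
    """

    holdout_splits: list[tuple[np.ndarray, np.ndarray]]
    subsamples: list[list[tuple[np.ndarray, np.ndarray]]]
    master_seed: int


@dataclass
class GridSearchResult:
    grid: list[SparsityPair]
    mean_abs_corr: np.ndarray
    selected: SparsityPair
    selected_index: int


@dataclass
class PermutationOutcome:
    """Hold-out correlation, its permutation null, and the resulting p-value."""

    rho: float
    rho_null: np.ndarray
    p_value: float
    B: int


@dataclass
class SplitRecord:
    """Results of one hold-out split for one effect."""

    grid_result: GridSearchResult | None
    pair: WeightPair
    outcome: PermutationOutcome


@dataclass
class EffectRecord:
    """Aggregated per-effect results across all hold-out splits."""

    effect_index: int
    per_split: list[SplitRecord]
    omnibus_rejected: bool
    alpha: float
    selected_split: int | None = None
    selected_pair: WeightPair | None = None

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.outcome.p_value for r in self.per_split])

    @property
    def holdout_correlations(self) -> np.ndarray:
        return np.array([r.outcome.rho for r in self.per_split])


def standardize(train: np.ndarray, *apply_to: np.ndarray) -> list[np.ndarray]:
    """Column-wise z-scoring with statistics estimated on ``train`` only.

    Each matrix in ``apply_to`` is transformed with the training means and
    standard deviations (population SD, i.e. divisor n), so training
    columns come out with mean 0 and SD 1 while disjoint test data keep
    whatever shift the training statistics imply — no leakage. A
    zero-variance training column is left centered with a unit divisor and
    a logged warning.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("standardize needs at least 2 training rows")
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd <= 1e-15
    if zero.any():
        logger.warning(
            "%d zero-variance feature(s) left centered with unit divisor", int(zero.sum())
        )
        sd = np.where(zero, 1.0, sd)
    return [(np.asarray(M, dtype=float) - mu) / sd for M in apply_to]


def make_split_plan(
    n: int,
    n_holdout_splits: int = 10,
    holdout_frac: float = 0.10,
    K: int = 100,
    train_frac: float = 0.80,
    master_seed: int = 0,
) -> SplitPlan:
    """Draw the hold-out carve-outs and per-pool subsamples, reproducibly.

    Set sizes are ``round(frac * n)`` (Python round-half-to-even); the
    complement fills the other member of each pair, so every pair is
    disjoint and covers its pool.
    """
    n_hold = int(round(holdout_frac * n))
    n_pool = n - n_hold
    n_test = int(round((1.0 - train_frac) * n_pool))
    n_train = n_pool - n_test
    if min(n_hold, n_test, n_train) < 2:
        raise ValueError(
            f"n={n} is too small for holdout_frac={holdout_frac}, train_frac={train_frac}: "
            f"every index set needs at least 2 samples"
        )
    ss = np.random.SeedSequence(master_seed)
    states = ss.generate_state(1 + n_holdout_splits)
    outer = ShuffleSplit(
        n_splits=n_holdout_splits, test_size=n_hold, random_state=int(states[0])
    )
    holdout_splits: list[tuple[np.ndarray, np.ndarray]] = []
    subsamples: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for s, (pool_idx, hold_idx) in enumerate(outer.split(np.empty((n, 1)))):
        pool_idx = np.sort(pool_idx)
        hold_idx = np.sort(hold_idx)
        holdout_splits.append((pool_idx, hold_idx))
        inner = ShuffleSplit(n_splits=K, test_size=n_test, random_state=int(states[1 + s]))
        subsamples.append(
            [
                (np.sort(tr), np.sort(te))
                for tr, te in inner.split(np.empty((n_pool, 1)))
            ]
        )
    return SplitPlan(holdout_splits=holdout_splits, subsamples=subsamples, master_seed=master_seed)


def sparsity_grid(
    p: int, q: int, n_points_u: int = 40, n_points_v: int = 40
) -> list[SparsityPair]:
    """Equidistant sparsity grid over [1, sqrt(p)] x [1, sqrt(q)].

    sqrt(dim) is the largest l1 norm a unit-l2 vector can attain, so the
    upper grid edge leaves the constraint inactive. The default 40x40 grid
    enumerates 1600 combinations, in row-major order (c_u outer, c_v inner).
    """
    cu = np.linspace(1.0, math.sqrt(p), n_points_u)
    cv = np.linspace(1.0, math.sqrt(q), n_points_v)
    return [SparsityPair(float(a), float(b)) for a in cu for b in cv]


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson correlation|, defined as 0 when either vector is constant."""
    a = a - a.mean()
    b = b - b.mean()
    va = float(a @ a)
    vb = float(b @ b)
    if va <= 1e-24 or vb <= 1e-24:
        return 0.0
    return abs(float(a @ b) / math.sqrt(va * vb))


def _fit_pair(
    X: np.ndarray,
    Y: np.ndarray,
    sparsity: SparsityPair | None,
    tol: float,
    max_iter: int,
) -> WeightPair:
    C = cross_covariance(X, Y)
    if sparsity is None:
        return _pls_rank1_cov(C)
    return _spls_cov(C, sparsity, tol=tol, max_iter=max_iter)


def test_correlation(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    test_X: np.ndarray,
    test_Y: np.ndarray,
    sparsity: SparsityPair | None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Fit on the training portion, project the testing portion, return |corr|.

    Inputs are expected to be already standardised (with training-derived
    statistics). ``sparsity=None`` fits plain PLS. A degenerate test
    projection (zero variance in either view) yields 0 by convention.
    """
    test_X = np.asarray(test_X, dtype=float)
    if test_X.shape[0] < 3:
        raise ValueError("test_correlation needs at least 3 test samples")
    pair = _fit_pair(train_X, train_Y, sparsity, tol, max_iter)
    return _abs_corr(test_X @ pair.u, np.asarray(test_Y, float) @ pair.v)


test_correlation.__test__ = False  # not a test, despite the name pytest sees


def grid_search(
    pool_X: np.ndarray,
    pool_Y: np.ndarray,
    plan_subsamples: list[tuple[np.ndarray, np.ndarray]],
    grid: list[SparsityPair],
    standardize_splits: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
    counter: FitCounter | None = None,
) -> GridSearchResult:
    """Average the subsample test correlation over K splits for every grid point.

    The same subsamples are used for every combination, and within a
    subsample the cross-covariance matrix and its SVD initialisation are
    shared across combinations. Degenerate fits contribute 0 with a logged
    warning. Ties on the mean correlation are broken towards the smaller
    ``c_u + c_v`` (the sparser model), then the lowest grid index.
    """
    if not grid:
        raise ValueError("the sparsity grid must be non-empty")
    pool_X = np.asarray(pool_X, dtype=float)
    pool_Y = np.asarray(pool_Y, dtype=float)
    sums = np.zeros(len(grid))
    K = len(plan_subsamples)
    for tr, te in plan_subsamples:
        Xtr, Ytr, Xte, Yte = pool_X[tr], pool_Y[tr], pool_X[te], pool_Y[te]
        if standardize_splits:
            Xtr, Xte = standardize(Xtr, Xtr, Xte)
            Ytr, Yte = standardize(Ytr, Ytr, Yte)
        C = Xtr.T @ Ytr
        if counter is not None:
            counter.add(len(grid))
        if not np.any(C):
            logger.warning("degenerate subsample (zero cross-covariance); rho_k = 0")
            continue
        v0 = _init_v(C)
        for g, sp in enumerate(grid):
            try:
                pair = _spls_cov(C, sp, tol=tol, max_iter=max_iter, v0=v0)
            except DegenerateInputError:
                logger.warning("degenerate SPLS fit at (%.3g, %.3g); rho_k = 0", sp.c_u, sp.c_v)
                continue
            sums[g] += _abs_corr(Xte @ pair.u, Yte @ pair.v)
    means = sums / K
    best = 0
    for g in range(1, len(grid)):
        if means[g] > means[best]:
            best = g
        elif means[g] == means[best]:
            if grid[g].c_u + grid[g].c_v < grid[best].c_u + grid[best].c_v:
                best = g
    return GridSearchResult(
        grid=list(grid), mean_abs_corr=means, selected=grid[best], selected_index=best
    )


def permutation_p_value(rho: float, rho_null: np.ndarray) -> float:
    """p = (1 + #{rho_b >= rho}) / (B + 1); always in [1/(B+1), 1]."""
    rho_null = np.asarray(rho_null, dtype=float)
    return (1.0 + int(np.sum(rho_null >= rho))) / (rho_null.size + 1.0)


def permutation_test(
    traintest_X: np.ndarray,
    traintest_Y: np.ndarray,
    holdout_X: np.ndarray,
    holdout_Y: np.ndarray,
    sparsity: SparsityPair | None,
    B: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    permute_view: str = "y",
    fitted_pair: WeightPair | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    counter: FitCounter | None = None,
) -> PermutationOutcome:
    """Hold-out permutation test of one weight-vector pair.

    The unpermuted model (fitted on the full train/test pool with the given
    budgets) is projected onto the hold-out data to give rho. For each of
    the B permutations, the rows of one view of the *pool* are shuffled —
    destroying the between-view association while leaving each view's own
    structure intact — the model is refitted with the same budgets, and the
    intact hold-out data are projected to give rho_b. Degenerate fits
    contribute rho_b = 0. Inputs are expected to be already standardised.

    Per-permutation seeds are spawned from ``seed``, so the test is
    reproducible and safe to shard by permutation index.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    traintest_X = np.asarray(traintest_X, dtype=float)
    traintest_Y = np.asarray(traintest_Y, dtype=float)
    holdout_X = np.asarray(holdout_X, dtype=float)
    holdout_Y = np.asarray(holdout_Y, dtype=float)
    if fitted_pair is None:
        fitted_pair = _fit_pair(traintest_X, traintest_Y, sparsity, tol, max_iter)
        if counter is not None:
            counter.add()
    rho = _abs_corr(holdout_X @ fitted_pair.u, holdout_Y @ fitted_pair.v)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(B)
    n = traintest_X.shape[0]
    rho_null = np.zeros(B)
    for b in range(B):
        perm = np.random.default_rng(children[b]).permutation(n)
        if permute_view == "y":
            C = traintest_X.T @ traintest_Y[perm]
        elif permute_view == "x":
            C = traintest_X[perm].T @ traintest_Y
        else:
            raise ValueError("permute_view must be 'x' or 'y'")
        if counter is not None:
            counter.add()
        try:
            if sparsity is None:
                pair_b = _pls_rank1_cov(C)
            else:
                pair_b = _spls_cov(C, sparsity, tol=tol, max_iter=max_iter)
        except DegenerateInputError:
            continue  # rho_null[b] stays 0
        rho_null[b] = _abs_corr(holdout_X @ pair_b.u, holdout_Y @ pair_b.v)
        if (b + 1) % 1000 == 0:
            logger.info("permutation %d/%d done", b + 1, B)
    return PermutationOutcome(
        rho=rho, rho_null=rho_null, p_value=permutation_p_value(rho, rho_null), B=B
    )


def omnibus_decision(p_values, fwer: float = 0.05) -> tuple[bool, float]:
    """Bonferroni-corrected omnibus decision over the per-split p-values.

    With S splits, alpha = fwer / S and the omnibus null ("every split's
    null holds") is rejected iff min(p) <= alpha.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("omnibus_decision needs at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    alpha = fwer / p.size
    return bool(p.min() <= alpha), alpha


def select_best_pair(records: list[SplitRecord], alpha: float) -> tuple[int, WeightPair]:
    """Pick the significant split with the lowest p-value.

    Exact p ties are broken by the larger hold-out correlation; remaining
    ties by the lowest split index. Raises :class:`InvalidStateError` if no
    split is significant (the omnibus hypothesis was not rejected).
    """
    best = None
    for i, rec in enumerate(records):
        p, rho = rec.outcome.p_value, rec.outcome.rho
        if p > alpha:
            continue
        if best is None:
            best = i
        else:
            bp, brho = records[best].outcome.p_value, records[best].outcome.rho
            if p < bp or (p == bp and rho > brho):
                best = i
    if best is None:
        raise InvalidStateError("no split is significant; the omnibus hypothesis holds")
    return best, records[best].pair


def _derived_seed(*parts: int) -> int:
    """Deterministic 31-bit seed from a tuple of non-negative integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_framework(
    data: TwoViewDataset,
    config: FrameworkConfig,
    counter: FitCounter | None = None,
) -> list[EffectRecord]:
    """Run the full multiple hold-out procedure on a two-view dataset.

    Effects are extracted sequentially: after an omnibus rejection the
    selected pair deflates *all* working data (train/test pools and future
    hold-outs alike, since a fresh split plan is drawn per effect) and the
    procedure repeats; it stops at the first non-rejection or after
    ``config.max_effects`` effects. Identical configuration and master seed
    give bit-identical results.
    """
    config.validate()
    X = np.array(data.X, dtype=float)
    Y = np.array(data.Y, dtype=float)
    n, p, q = data.n, data.p, data.q
    if config.standardize_mode == "global":
        (X,) = standardize(X, X)
        (Y,) = standardize(Y, Y)
    per_split = config.standardize_mode == "per_split"
    grid = (
        sparsity_grid(p, q, config.grid_points_u, config.grid_points_v)
        if config.method == "spls"
        else None
    )
    records_out: list[EffectRecord] = []
    for h in range(1, config.max_effects + 1):
        plan = make_split_plan(
            n,
            n_holdout_splits=config.n_holdout_splits,
            holdout_frac=config.holdout_frac,
            K=config.K,
            train_frac=config.train_frac,
            master_seed=_derived_seed(config.master_seed, h),
        )
        split_records: list[SplitRecord] = []
        for s, (pool_idx, hold_idx) in enumerate(plan.holdout_splits):
            Xp, Yp, Xh, Yh = X[pool_idx], Y[pool_idx], X[hold_idx], Y[hold_idx]
            gs = None
            sparsity = None
            if config.method == "spls":
                gs = grid_search(
                    Xp,
                    Yp,
                    plan.subsamples[s],
                    grid,
                    standardize_splits=per_split,
                    tol=config.tol,
                    max_iter=config.max_iter,
                    counter=counter,
                )
                sparsity = gs.selected
            if per_split:
                Xp, Xh = standardize(Xp, Xp, Xh)
                Yp, Yh = standardize(Yp, Yp, Yh)
            pair = _fit_pair(Xp, Yp, sparsity, config.tol, config.max_iter)
            pair.effect_index = h
            if counter is not None:
                counter.add()
            outcome = permutation_test(
                Xp,
                Yp,
                Xh,
                Yh,
                sparsity,
                B=config.B,
                seed=_derived_seed(config.master_seed, h, s),
                permute_view=config.permute_view,
                fitted_pair=pair,
                tol=config.tol,
                max_iter=config.max_iter,
                counter=counter,
            )
            split_records.append(SplitRecord(grid_result=gs, pair=pair, outcome=outcome))
            logger.info(
                "effect %d split %d: %srho=%.4f p=%.4f",
                h,
                s + 1,
                (f"(c_u={sparsity.c_u:.3g}, c_v={sparsity.c_v:.3g}) " if sparsity else ""),
                outcome.rho,
                outcome.p_value,
            )
        rejected, alpha = omnibus_decision(
            [r.outcome.p_value for r in split_records], fwer=config.fwer
        )
        sel_idx: int | None = None
        sel_pair: WeightPair | None = None
        if rejected:
            sel_idx, sel_pair = select_best_pair(split_records, alpha)
        records_out.append(
            EffectRecord(
                effect_index=h,
                per_split=split_records,
                omnibus_rejected=rejected,
                alpha=alpha,
                selected_split=sel_idx,
                selected_pair=sel_pair,
            )
        )
        logger.info("effect %d: omnibus %s", h, "REJECTED" if rejected else "not rejected")
        if not rejected:
            break
        X, Y = _deflate_all(
            X, Y, sel_pair, config, plan.holdout_splits[sel_idx][0], per_split
        )
    return records_out


def _deflate_all(
    X: np.ndarray,
    Y: np.ndarray,
    pair: WeightPair,
    config: FrameworkConfig,
    pool_idx: np.ndarray,
    per_split: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the selected effect from all working data.

    The weights live in the standardised coordinates they were estimated
    in, so deflation must act there too: in per-split mode the working
    matrices are standardised with the selected split's pool statistics,
    deflated, and mapped back to the original scale; in global mode the
    working matrices are already in estimation coordinates.
    """
    if per_split:
        mu_x, sd_x = _train_stats(X[pool_idx])
        mu_y, sd_y = _train_stats(Y[pool_idx])
        Xs = (X - mu_x) / sd_x
        Ys = (Y - mu_y) / sd_y
    else:
        Xs, Ys = X, Y
    if config.deflation == "projection":
        Xs = projection_deflate(Xs, pair.u)
        Ys = projection_deflate(Ys, pair.v)
    else:
        Xs, Ys = pls_deflate(Xs, Ys, pair.u, pair.v)
    if per_split:
        return Xs * sd_x + mu_x, Ys * sd_y + mu_y
    return Xs, Ys


def _train_stats(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    return mu, np.where(sd <= 1e-15, 1.0, sd)


def count_framework_fits(n_splits: int, grid_size: int, K: int, B: int) -> int:
    """Number of model fits the multiple hold-out framework performs per effect.

    Per hold-out split: ``grid_size * K`` grid evaluations, one unpermuted
    fit on the full pool, and ``B`` permutation refits.
    """
    for v in (n_splits, grid_size, K, B):
        if v < 0:
            raise ValueError("all counts must be non-negative")
    return n_splits * (grid_size * K + 1 + B)


def count_nested_cv_fits(n_outer: int, n_inner: int, grid_size: int, B: int) -> int:
    """Number of fits a nested cross-validation scheme would need.

    For the unpermuted run and each of the B permutations, every outer fold
    performs a full inner grid search (``grid_size * n_inner`` fits) plus
    one outer-fold fit.
    """
    for v in (n_outer, n_inner, grid_size, B):
        if v < 0:
            raise ValueError("all counts must be non-negative")
    return (B + 1) * n_outer * (grid_size * n_inner + 1)
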