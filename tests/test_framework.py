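"""Tests of the multiple hold-out learning and validation machinery."""

import numpy as np
import pytest

from mhspls import (
    FitCounter,
    FrameworkConfig,
    InvalidStateError,
    PermutationOutcome,
    SimulationSpec,
    SparsityPair,
    SplitRecord,
    WeightPair,
    count_framework_fits,
    count_nested_cv_fits,
    grid_search,
    make_split_plan,
    omnibus_decision,
    permutation_p_value,
    permutation_test,
    run_framework,
    select_best_pair,
    simulate,
    sparsity_grid,
    standardize,
    test_correlation,
)


# ---------------------------------------------------------------- standardize
def test_standardize_centers_and_scales_training_data():
    train = np.array([[1.0], [3.0]])
    (out,) = standardize(train, train)
    np.testing.assert_allclose(out, [[-1.0], [1.0]])


def test_standardize_does_not_leak_into_test_data(rng):
    train = rng.standard_normal((30, 4)) + 2.0
    test = rng.standard_normal((10, 4)) + 5.0
    tr, te = standardize(train, train, test)
    np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(tr.std(axis=0), 1.0, atol=1e-10)
    assert np.abs(te.mean(axis=0)).min() > 0.5  # shifted by the train stats


def test_standardize_constant_column_yields_zeros_with_warning(caplog):
    train = np.column_stack([np.ones(5), np.arange(5.0)])
    with caplog.at_level("WARNING", logger="mhspls.framework"):
        (out,) = standardize(train, train)
    np.testing.assert_allclose(out[:, 0], 0.0)
    assert any("zero-variance" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------- split plan
def test_split_plan_sizes_follow_printed_fractions():
    plan = make_split_plan(100, master_seed=0)
    assert len(plan.holdout_splits) == 10
    for pool, hold in plan.holdout_splits:
        assert hold.size == 10 and pool.size == 90
        assert np.intersect1d(pool, hold).size == 0
        assert np.array_equal(np.sort(np.concatenate([pool, hold])), np.arange(100))
    for subs in plan.subsamples:
        assert len(subs) == 100
        for tr, te in subs:
            assert te.size == 18 and tr.size == 72  # 20% of the 90-sample pool
            assert np.intersect1d(tr, te).size == 0
            assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(90))


def test_split_plan_is_seed_reproducible():
    a = make_split_plan(60, n_holdout_splits=3, K=5, master_seed=7)
    b = make_split_plan(60, n_holdout_splits=3, K=5, master_seed=7)
    for (pa, ha), (pb, hb) in zip(a.holdout_splits, b.holdout_splits):
        assert np.array_equal(pa, pb) and np.array_equal(ha, hb)
    for sa, sb in zip(a.subsamples, b.subsamples):
        for (ta, ea), (tb, eb) in zip(sa, sb):
            assert np.array_equal(ta, tb) and np.array_equal(ea, eb)


def test_split_plans_differ_across_seeds():
    holds = {
        tuple(make_split_plan(80, n_holdout_splits=1, K=1, master_seed=s).holdout_splits[0][1])
        for s in range(10)
    }
    assert len(holds) > 1


def test_split_plan_rejects_too_small_n():
    with pytest.raises(ValueError, match="too small"):
        make_split_plan(8, master_seed=0)


# ---------------------------------------------------------------- test correlation
def test_identical_single_feature_views_correlate_perfectly(rng):
    t = rng.standard_normal(20)[:, None]
    (ts,) = standardize(t, t)
    rho = test_correlation(ts[:12], ts[:12], ts[12:], ts[12:], SparsityPair(1.0, 1.0))
    assert rho == pytest.approx(1.0)


def test_degenerate_test_projection_gives_zero(rng):
    train_X = rng.standard_normal((12, 3))
    train_Y = rng.standard_normal((12, 2))
    test_X = np.ones((5, 3))  # constant projection
    test_Y = rng.standard_normal((5, 2))
    rho = test_correlation(train_X, train_Y, test_X, test_Y, SparsityPair(1.0, 1.0))
    assert rho == 0.0


def test_too_few_test_samples_error(rng):
    X = rng.standard_normal((10, 3))
    Y = rng.standard_normal((10, 2))
    with pytest.raises(ValueError, match="3 test samples"):
        test_correlation(X, Y, X[:2], Y[:2], SparsityPair(1.0, 1.0))


# ---------------------------------------------------------------- grid search
def test_grid_default_is_40_by_40_spanning_admissible_range():
    grid = sparsity_grid(500, 30)
    assert len(grid) == 1600
    cus = {g.c_u for g in grid}
    cvs = {g.c_v for g in grid}
    assert min(cus) == 1.0 and max(cus) == pytest.approx(np.sqrt(500))
    assert min(cvs) == 1.0 and max(cvs) == pytest.approx(np.sqrt(30))
    assert len(cus) == 40 and len(cvs) == 40


def test_single_combination_grid_selects_it(rng):
    data, _ = simulate(SimulationSpec(n=40, p=8, q=4, support_x=3, support_y=2, strengths=(3.0,), seed=0))
    plan = make_split_plan(40, n_holdout_splits=1, K=4, master_seed=1)
    pool, _ = plan.holdout_splits[0]
    only = SparsityPair(1.7, 1.4)
    res = grid_search(data.X[pool], data.Y[pool], plan.subsamples[0], [only])
    assert res.selected == only and res.selected_index == 0


def test_grid_search_matches_public_test_correlation(rng):
    """The optimised grid loop must agree with composing standardize +
    test_correlation by hand for every subsample."""
    data, _ = simulate(SimulationSpec(n=40, p=8, q=4, support_x=3, support_y=2, strengths=(3.0,), seed=2))
    plan = make_split_plan(40, n_holdout_splits=1, K=5, master_seed=3)
    pool, _ = plan.holdout_splits[0]
    Xp, Yp = data.X[pool], data.Y[pool]
    grid = [SparsityPair(1.5, 1.2), SparsityPair(2.2, 1.8)]
    res = grid_search(Xp, Yp, plan.subsamples[0], grid)
    for g, sp in enumerate(grid):
        rhos = []
        for tr, te in plan.subsamples[0]:
            Xtr, Xte = standardize(Xp[tr], Xp[tr], Xp[te])
            Ytr, Yte = standardize(Yp[tr], Yp[tr], Yp[te])
            rhos.append(test_correlation(Xtr, Ytr, Xte, Yte, sp))
        assert res.mean_abs_corr[g] == pytest.approx(np.mean(rhos), abs=1e-12)


def test_grid_search_selection_is_order_invariant(rng):
    data, _ = simulate(SimulationSpec(n=50, p=10, q=5, support_x=4, support_y=2, strengths=(4.0,), seed=4))
    plan = make_split_plan(50, n_holdout_splits=1, K=6, master_seed=5)
    pool, _ = plan.holdout_splits[0]
    grid = sparsity_grid(10, 5, 4, 3)
    fwd = grid_search(data.X[pool], data.Y[pool], plan.subsamples[0], grid)
    rev = grid_search(data.X[pool], data.Y[pool], plan.subsamples[0], grid[::-1])
    assert fwd.selected == rev.selected


# ---------------------------------------------------------------- permutation test
def test_permutation_p_value_arithmetic():
    assert permutation_p_value(0.5, np.array([0.6, 0.1, 0.2, 0.3])) == pytest.approx(0.4)
    assert permutation_p_value(0.5, np.full(10, 0.9)) == pytest.approx(1.0)
    assert permutation_p_value(0.9, np.zeros(10000)) == pytest.approx(1.0 / 10001)


def test_permutation_test_floor_on_strong_effect():
    """A strong planted effect beats every permutation, so p hits the
    1/(B+1) floor."""
    spec = SimulationSpec(
        n=60, p=20, q=6, support_x=5, support_y=3, strengths=(10.0,), noise_sd=0.3, seed=3
    )
    data, _ = simulate(spec)
    plan = make_split_plan(60, n_holdout_splits=1, K=1, master_seed=0)
    pool, hold = plan.holdout_splits[0]
    Xp, Xh = standardize(data.X[pool], data.X[pool], data.X[hold])
    Yp, Yh = standardize(data.Y[pool], data.Y[pool], data.Y[hold])
    out = permutation_test(Xp, Yp, Xh, Yh, SparsityPair(2.2, 1.7), B=20, seed=5)
    assert out.p_value == pytest.approx(1.0 / 21)
    assert out.rho > out.rho_null.max()


def test_permutation_test_is_seed_reproducible_and_bounded(rng):
    X = rng.standard_normal((30, 6))
    Y = rng.standard_normal((30, 4))
    (Xs,) = standardize(X[:24], X[:24])
    (Ys,) = standardize(Y[:24], Y[:24])
    args = (Xs, Ys, X[24:], Y[24:], SparsityPair(1.5, 1.3))
    a = permutation_test(*args, B=30, seed=11)
    b = permutation_test(*args, B=30, seed=11)
    assert a.p_value == b.p_value
    assert np.array_equal(a.rho_null, b.rho_null)
    assert 1.0 / 31 <= a.p_value <= 1.0
    c = permutation_test(*args, B=30, seed=12, permute_view="x")
    assert 1.0 / 31 <= c.p_value <= 1.0


# ---------------------------------------------------------------- omnibus + selection
def test_omnibus_alpha_is_fwer_over_splits():
    rejected, alpha = omnibus_decision([0.5] * 10, fwer=0.05)
    assert alpha == pytest.approx(0.005)
    assert not rejected


def test_omnibus_rejects_iff_any_p_at_most_alpha():
    rejected, alpha = omnibus_decision([0.0007, 0.01, 0.9] + [0.5] * 7)
    assert rejected and alpha == pytest.approx(0.005)
    assert omnibus_decision([0.0051] + [0.9] * 9)[0] is False


def test_omnibus_input_validation():
    with pytest.raises(ValueError):
        omnibus_decision([])
    with pytest.raises(ValueError):
        omnibus_decision([0.0, 0.5])


def _records(ps, rhos):
    out = []
    for p, rho in zip(ps, rhos):
        pair = WeightPair(u=np.array([1.0]), v=np.array([1.0]))
        out.append(
            SplitRecord(
                grid_result=None,
                pair=pair,
                outcome=PermutationOutcome(rho=rho, rho_null=np.zeros(1), p_value=p, B=1),
            )
        )
    return out


def test_select_best_pair_rules():
    # unique minimum p
    idx, _ = select_best_pair(_records([0.002, 0.001, 0.004], [0.3, 0.2, 0.5]), alpha=0.005)
    assert idx == 1
    # p tie broken by the higher hold-out correlation
    idx, _ = select_best_pair(_records([0.001, 0.001], [0.2, 0.4]), alpha=0.005)
    assert idx == 1
    # full tie broken by the lowest split index
    idx, _ = select_best_pair(_records([0.001, 0.001], [0.4, 0.4]), alpha=0.005)
    assert idx == 0


def test_select_best_pair_requires_a_significant_split():
    with pytest.raises(InvalidStateError):
        select_best_pair(_records([0.5, 0.6], [0.1, 0.2]), alpha=0.005)


# ---------------------------------------------------------------- fit counting
def test_fit_count_formulas():
    assert count_framework_fits(10, 1600, 100, 10000) == 1_700_010
    assert count_framework_fits(1, 1, 1, 0) == 2
    assert count_nested_cv_fits(5, 5, 1600, 1000) == 40_045_005
    assert count_nested_cv_fits(1, 1, 1, 0) == 2


def test_fit_count_matches_instrumented_dry_run():
    """count_framework_fits must tally exactly what run_framework executes."""
    data, _ = simulate(SimulationSpec(n=40, p=8, q=4, n_effects=0, seed=9))
    cfg = FrameworkConfig(
        n_holdout_splits=2, K=5, B=7, grid_points_u=3, grid_points_v=2,
        max_effects=1, master_seed=1,
    )
    counter = FitCounter()
    run_framework(data, cfg, counter=counter)
    assert counter.count == count_framework_fits(2, 3 * 2, 5, 7)

    counter = FitCounter()
    cfg_pls = FrameworkConfig(
        method="pls", n_holdout_splits=2, K=5, B=7, max_effects=1, master_seed=1
    )
    run_framework(data, cfg_pls, counter=counter)
    assert counter.count == count_framework_fits(2, 0, 5, 7)  # no grid stage


# ---------------------------------------------------------------- run_framework
def test_run_framework_zero_max_effects_returns_empty():
    data, _ = simulate(SimulationSpec(n=40, p=8, q=4, n_effects=0, seed=0))
    assert run_framework(data, FrameworkConfig(max_effects=0)) == []


def test_run_framework_is_bit_reproducible():
    data, _ = simulate(
        SimulationSpec(n=50, p=20, q=6, support_x=5, support_y=3, strengths=(6.0,), seed=11)
    )
    cfg = FrameworkConfig(
        n_holdout_splits=2, K=5, B=79, grid_points_u=4, grid_points_v=3,
        max_effects=2, master_seed=99,
    )
    a = run_framework(data, cfg)
    b = run_framework(data, cfg)
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.p_values, rb.p_values)
        assert ra.omnibus_rejected == rb.omnibus_rejected
        if ra.selected_pair is not None:
            assert np.array_equal(ra.selected_pair.u, rb.selected_pair.u)
            assert np.array_equal(ra.selected_pair.v, rb.selected_pair.v)


def test_run_framework_stops_on_null_data():
    data, _ = simulate(SimulationSpec(n=60, p=10, q=5, n_effects=0, seed=21))
    cfg = FrameworkConfig(
        n_holdout_splits=2, K=5, B=19, grid_points_u=3, grid_points_v=2,
        max_effects=3, master_seed=2,
    )
    records = run_framework(data, cfg)
    assert len(records) == 1  # stopped at the first non-rejection
    assert not records[0].omnibus_rejected
    assert records[0].selected_pair is None


def test_run_framework_pls_method_skips_grid_search():
    data, _ = simulate(SimulationSpec(n=40, p=8, q=4, n_effects=0, seed=5))
    cfg = FrameworkConfig(
        method="pls", n_holdout_splits=2, K=5, B=9, max_effects=1, master_seed=3
    )
    records = run_framework(data, cfg)
    assert all(sr.grid_result is None for sr in records[0].per_split)
    assert all(sr.pair.sparsity is None for sr in records[0].per_split)


def test_run_framework_finds_two_planted_effects():
    data, truths = simulate(
        SimulationSpec(
            n=80, p=40, q=12, n_effects=2, support_x=6, support_y=4,
            strengths=(6.0, 4.0), noise_sd=0.5, seed=17,
        )
    )
    cfg = FrameworkConfig(
        n_holdout_splits=2, K=10, B=79, grid_points_u=5, grid_points_v=4,
        max_effects=2, master_seed=4,
    )
    records = run_framework(data, cfg)
    assert len(records) == 2
    assert records[0].omnibus_rejected and records[1].omnibus_rejected
    # the first extracted effect is the stronger planted one
    f1 = abs(records[0].selected_pair.v @ truths[0].v)
    assert f1 > 0.8


def test_run_framework_per_split_mode_extracts_and_deflates():
    """The leakage-free per-split standardisation mode runs end to end,
    including its scale-aware deflation step, and stays reproducible."""
    data, truths = simulate(
        SimulationSpec(n=60, p=20, q=6, support_x=5, support_y=3,
                       strengths=(8.0,), noise_sd=0.5, seed=31)
    )
    cfg = FrameworkConfig(
        n_holdout_splits=2, K=5, B=79, grid_points_u=4, grid_points_v=3,
        max_effects=2, master_seed=13, standardize_mode="per_split",
    )
    a = run_framework(data, cfg)
    b = run_framework(data, cfg)
    assert a[0].omnibus_rejected  # the strong effect is found
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.p_values, rb.p_values)
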