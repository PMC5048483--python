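import numpy as np
import pytest

from mimfa import (
    Configuration,
    benchmark,
    iterative_mfa_impute,
    mfa,
    mvi_mfa,
    procrustes_align,
    rv_between_configurations,
)
from mimfa.evaluation import aggregate_reports
from mimfa.synthetic import MissingnessScenario

from conftest import small_two_table_set
from test_statis import random_config


# --------------------------------------------------------------- baselines
def test_mvi_on_complete_data_is_plain_mfa(two_tables):
    assert rv_between_configurations(mvi_mfa(two_tables, d=2), mfa(two_tables, d=2)) \
        == pytest.approx(1.0, abs=1e-12)


def test_mvi_imputes_observed_column_means():
    ds = small_two_table_set(seed=3, I=8, p=(3, 2), missing=[(0, 1)])
    from mimfa.evaluation import _mean_fill

    filled = _mean_fill(ds)
    t = ds.tables[0]
    expected = t.values[t.observed_mask].mean(axis=0)
    assert np.allclose(filled.tables[0].values[1], expected)
    obs = t.observed_mask
    assert np.array_equal(filled.tables[0].values[obs], t.values[obs])


def test_iterative_on_complete_data_is_plain_mfa(two_tables):
    cfg = iterative_mfa_impute(two_tables, ncp=2, d=2)
    assert rv_between_configurations(cfg, mfa(two_tables, d=2)) == pytest.approx(1.0, abs=1e-12)


def test_iterative_ncp0_equals_mean_imputation():
    ds = small_two_table_set(seed=5, I=9, p=(4, 3), missing=[(0, 2), (1, 6)])
    a = iterative_mfa_impute(ds, ncp=0, d=2)
    b = mvi_mfa(ds, d=2)
    assert rv_between_configurations(a, b) == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(np.abs(a.scores), np.abs(b.scores), atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_em_objective_nonincreasing(seed):
    """With preprocessing frozen and no shrinkage the loop is textbook EM:
    the observed-cell fit never worsens across iterations."""
    import warnings

    ds = small_two_table_set(seed=seed, I=12, p=(5, 4), missing=[(0, 1), (0, 7), (1, 4)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # tight tol may not converge
        _, history = iterative_mfa_impute(
            ds, ncp=2, d=2, shrinkage=False, freeze_preprocess=True,
            return_history=True, max_iter=40, tol=1e-10,
        )
    assert len(history) >= 2
    diffs = np.diff(history)
    assert (diffs <= 1e-8 * max(history)).all()


def test_iterative_nonconvergence_warns():
    ds = small_two_table_set(seed=7, I=10, p=(4, 4), missing=[(0, 0), (1, 5)])
    with pytest.warns(RuntimeWarning, match="did not converge"):
        iterative_mfa_impute(ds, ncp=2, d=2, max_iter=1, tol=1e-14)


# --------------------------------------------------------------- Procrustes
def similarity_transform(scores, angle, scale, shift, reflect=False):
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    if reflect:
        R = R @ np.diag([1.0, -1.0])
    return scale * scores @ R + shift


@pytest.mark.parametrize("reflect", [False, True])
def test_procrustes_exact_recovery(reflect):
    target = random_config(9, I=7)
    moved = similarity_transform(target.scores, angle=0.8, scale=2.3,
                                 shift=np.array([1.0, -2.0]), reflect=reflect)
    fit = procrustes_align(moved, target)
    assert fit.residual <= 1e-10
    assert np.allclose(fit.aligned_scores, target.scores, atol=1e-8)


def grid_procrustes(X, Y, n_angles=6284):
    """Brute-force oracle: dense grid over rotation angle and reflection,
    closed-form scale, centred data."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    best = np.inf
    nx = (Xc**2).sum()
    for reflect in (False, True):
        for ang in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            if reflect:
                R = R @ np.diag([1.0, -1.0])
            s = max((Xc @ R * Yc).sum() / nx, 0.0)
            best = min(best, ((s * Xc @ R - Yc) ** 2).sum())
    return best


def test_procrustes_matches_rotation_grid_oracle():
    rng = np.random.default_rng(31)
    a = random_config(31, I=6)
    b = random_config(32, I=6)
    fit = procrustes_align(a, b)
    oracle = grid_procrustes(a.scores, b.scores)
    # the grid oracle is an upper bound at 1e-3 rad resolution
    assert fit.residual <= oracle + 1e-9
    assert fit.residual == pytest.approx(oracle, rel=1e-4)


def test_procrustes_shape_mismatch():
    with pytest.raises(ValueError):
        procrustes_align(random_config(1, I=6), random_config(2, I=7))


# ----------------------------------------------------------------------- RV
def test_rv_invariances_and_alignment_neutrality():
    cfg = random_config(40, I=9)
    assert rv_between_configurations(cfg, cfg) == pytest.approx(1.0)
    rotated = similarity_transform(cfg.scores, angle=1.1, scale=1.0, shift=np.zeros(2))
    assert rv_between_configurations(cfg, rotated) == pytest.approx(1.0, abs=1e-10)
    # Procrustes alignment (similarity transform) leaves RV unchanged
    other = random_config(41, I=9)
    before = rv_between_configurations(cfg, other)
    fit = procrustes_align(cfg, other)
    aligned = fit.aligned_scores - fit.aligned_scores.mean(axis=0)
    assert rv_between_configurations(aligned, other) == pytest.approx(before, abs=1e-10)


# ---------------------------------------------------------------- benchmark
def test_zero_missingness_scenario_reports_rv_one(two_tables):
    reports = benchmark(two_tables, [MissingnessScenario((0, 0), name="none")],
                        replicates=2, M=3, d=2, seed=0)
    assert len(reports) == 6
    assert all(r.rv_to_true == pytest.approx(1.0, abs=1e-10) for r in reports)
    assert all(np.allclose(r.divergences, 0.0, atol=1e-8) for r in reports)


def test_benchmark_reproducible_and_aggregable(liver):
    scen = [MissingnessScenario((1, 0), name="low")]
    kw = dict(replicates=2, M=5, d=2, seed=3, methods=("MI", "MVI"))
    r1 = benchmark(liver, scen, **kw)
    r2 = benchmark(liver, scen, **kw)
    assert [r.rv_to_true for r in r1] == [r.rv_to_true for r in r2]
    agg = aggregate_reports(r1)
    assert set(agg["method"]) == {"MI", "MVI"}
    assert ((agg["mean"] >= 0) & (agg["mean"] <= 1)).all()


def test_benchmark_rejects_incomplete_truth_and_infeasible_scenario(liver):
    ds = small_two_table_set(seed=1, missing=[(0, 0)])
    with pytest.raises(ValueError, match="complete"):
        benchmark(ds, [MissingnessScenario((1, 0))], replicates=1, M=2, d=2, seed=0)
    with pytest.raises(ValueError, match="trt1"):
        benchmark(liver, [MissingnessScenario((9, 0))], replicates=1, M=2, d=2, seed=0)
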