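import numpy as np
import pytest

from reshwoa import benchmarks as B
from reshwoa.optimizers import (
    OptimizerConfig,
    Population,
    a_schedule,
    dr_init,
    intermediate_recombination,
    repeat_runs,
    run_reshwoa,
    run_woa,
    uniform_init,
    woa_update,
)


def cfg(**kw):
    base = dict(dim=2, lb=-10.0, ub=10.0, n_agents=10, max_iter=50, seed=0)
    base.update(kw)
    return OptimizerConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        cfg(rho=11, mu=10)
    with pytest.raises(ValueError):
        cfg(lb=5.0, ub=5.0)
    with pytest.raises(ValueError):
        cfg(lb=[0.0, 0.0, 0.0])  # wrong length for dim=2
    with pytest.raises(ValueError):
        cfg(init_mode="chaotic")


def test_a_schedule_linear_and_endpoints():
    T = 500
    assert a_schedule(0, T) == 2.0
    assert a_schedule(T, T) == 0.0
    ts = np.arange(T + 1)
    vals = np.array([a_schedule(t, T) for t in ts])
    assert np.allclose(vals, 2.0 * (1.0 - ts / T))
    assert np.all(np.diff(vals) < 0)


def test_uniform_init_seeded_and_in_bounds():
    c = cfg(n_agents=100)
    p1 = uniform_init(c).positions
    p2 = uniform_init(c).positions
    assert np.array_equal(p1, p2)
    assert np.all((p1 >= c.lb) & (p1 <= c.ub))
    # near-degenerate bounds collapse onto lb
    tight = cfg(lb=3.0, ub=3.0 + 1e-12)
    assert np.allclose(uniform_init(tight).positions, 3.0, atol=1e-11)


def test_uniform_init_marginal_mean():
    c = OptimizerConfig(dim=1, lb=0.0, ub=1.0, n_agents=10_000, max_iter=1, seed=4)
    assert uniform_init(c).positions.mean() == pytest.approx(0.5, abs=0.02)


def test_dr_membership_exhaustive_small_pool():
    """Every offspring coordinate must be one of that column's pool values."""
    c = OptimizerConfig(dim=4, lb=0.0, ub=1.0, n_agents=6, max_iter=1,
                        mu=6, lambda_=12, rho=3, seed=9)
    rng = np.random.default_rng(c.seed)
    pool = np.random.default_rng(c.seed).random((c.mu, c.dim))  # replay the pool draw
    pop = dr_init(c, rng=rng, return_all=True)
    assert pop.positions.shape == (12, 4)
    for row in pop.positions:
        for j, v in enumerate(row):
            assert np.any(np.isclose(pool[:, j], v)), "offspring coordinate not from pool"


def test_dr_single_parent_copies_whole_rows():
    c = OptimizerConfig(dim=5, lb=0.0, ub=1.0, n_agents=8, max_iter=1,
                        mu=4, lambda_=8, rho=1, seed=2)
    pool = np.random.default_rng(c.seed).random((c.mu, c.dim))
    pop = dr_init(c, rng=np.random.default_rng(c.seed))
    for row in pop.positions:
        assert any(np.allclose(row, parent) for parent in pool)


def test_dr_preserves_uniform_marginals():
    """With rho = mu = lambda = n_agents, per-coordinate resampling of a
    uniform pool keeps each coordinate's marginal uniform (KS test)."""
    from scipy.stats import kstest

    n = 1000
    c = OptimizerConfig(dim=2, lb=0.0, ub=1.0, n_agents=n, max_iter=1,
                        mu=n, lambda_=n, rho=n, seed=17)
    pop = dr_init(c)
    for j in range(c.dim):
        assert kstest(pop.positions[:, j], "uniform").pvalue > 0.01


def test_dr_init_scaled_to_bounds():
    c = cfg(lb=[-5.0, 2.0], ub=[5.0, 4.0], n_agents=30, lambda_=30)
    pos = dr_init(c).positions
    assert pos.shape == (30, 2)
    assert np.all(pos[:, 0] >= -5) and np.all(pos[:, 0] <= 5)
    assert np.all(pos[:, 1] >= 2) and np.all(pos[:, 1] <= 4)


def test_intermediate_recombination_is_parent_mean():
    parents = np.array([[0.0, 2.0], [2.0, 4.0], [4.0, 0.0]])
    assert np.allclose(intermediate_recombination(parents), [2.0, 2.0])


def test_woa_update_hand_trace():
    """Recompute one update step scalar-by-scalar from the logged draws."""
    n, dim = 3, 2
    rng = np.random.default_rng(123)
    positions = np.array([[1.0, -2.0], [0.5, 0.5], [-3.0, 4.0]])
    best = np.array([0.1, -0.1])
    lb, ub = np.full(dim, -10.0), np.full(dim, 10.0)
    a, b = 1.2, 1.0

    out = woa_update(positions.copy(), best, a, lb, ub, rng, spiral_b=b)

    replay = np.random.default_rng(123)
    r1 = replay.random(n)
    r2 = replay.random(n)
    p = replay.random(n)
    l = replay.uniform(-1.0, 1.0, n)
    rand_idx = replay.integers(0, n, (n, dim))
    for i in range(n):
        A = 2 * a * r1[i] - a
        C = 2 * r2[i]
        if p[i] >= 0.5:
            expected = (
                np.abs(best - positions[i]) * (np.exp(b * l[i]) * np.cos(2 * np.pi * l[i]))
                + best
            )
        elif abs(A) < 1:
            expected = best - A * np.abs(C * best - positions[i])
        else:
            ref = positions[rand_idx[i], np.arange(dim)]
            expected = ref - A * np.abs(C * ref - positions[i])
        expected = np.clip(expected, lb, ub)
        assert np.allclose(out[i], expected, rtol=1e-12, atol=1e-12), f"agent {i} mismatch"


def test_woa_update_collapse_cases():
    n, dim = 6, 3
    positions = np.tile(np.array([1.0, 2.0, 3.0]), (n, 1))
    best = positions[0].copy()
    lb, ub = np.full(dim, -10.0), np.full(dim, 10.0)
    # X == X*: spiral distance is 0 and, at a=0, A=0 makes encircling exact
    out = woa_update(positions.copy(), best, 0.0, lb, ub, np.random.default_rng(0))
    assert np.allclose(out, best, rtol=0, atol=0)


def test_positions_stay_in_bounds():
    rng = np.random.default_rng(3)
    positions = rng.uniform(-5, 5, (20, 4))
    best = positions[0].copy()
    lb, ub = np.full(4, -5.0), np.full(4, 5.0)
    for a in (2.0, 1.0, 0.5):
        positions = woa_update(positions, best, a, lb, ub, rng)
        assert np.all(positions >= lb) and np.all(positions <= ub)


def test_run_constant_objective_flat_curve():
    res = run_woa(lambda x: 0.0, cfg())
    assert res.best_score == 0.0
    assert np.all(res.convergence_curve == 0.0)
    res2 = run_reshwoa(lambda x: 0.0, cfg(init_mode="discrete_recombination"))
    assert res2.best_score == 0.0


def test_sphere_2d_convergence_rate():
    """WOA contracts onto the elite as a -> 0: near-exact optimum on 2-D sphere."""
    obj = B.make_objective("F1")
    hits = 0
    for seed in range(20):
        c = OptimizerConfig(dim=2, lb=-100.0, ub=100.0, n_agents=30, max_iter=100, seed=seed)
        if run_woa(obj, c).best_score < 1e-6:
            hits += 1
    assert hits >= 19  # >= 95% of 20 runs


@pytest.mark.parametrize("runner", [run_woa, run_reshwoa])
def test_convergence_curve_non_increasing_and_consistent(runner):
    obj = B.make_objective("F9")
    c = OptimizerConfig(dim=5, lb=-5.12, ub=5.12, n_agents=15, max_iter=80, seed=5)
    res = runner(obj, c)
    assert np.all(np.diff(res.convergence_curve) <= 0)
    assert res.best_score == res.convergence_curve[-1]
    assert obj(res.best_position) == pytest.approx(res.best_score)


@pytest.mark.parametrize("runner", [run_woa, run_reshwoa])
def test_seed_determinism(runner):
    obj = B.make_objective("F10")
    c = OptimizerConfig(dim=4, lb=-32.0, ub=32.0, n_agents=12, max_iter=40, seed=21)
    r1, r2 = runner(obj, c), runner(obj, c)
    assert np.array_equal(r1.best_position, r2.best_position)
    assert r1.best_score == r2.best_score
    assert np.array_equal(r1.convergence_curve, r2.convergence_curve)


def test_elite_invariance_with_seeded_minimizer():
    """If the initial population contains the global minimizer, the best score
    can never exceed the global minimum (strict-improvement elite)."""
    obj = B.make_objective("F9")
    c = OptimizerConfig(dim=3, lb=-5.12, ub=5.12, n_agents=8, max_iter=30, seed=1)
    init = uniform_init(c, np.random.default_rng(c.seed))
    init.positions[0] = 0.0  # the global minimizer
    res = run_woa(obj, c, initial_population=Population(init.positions))
    assert res.best_score <= B.global_minimum("F9", 3)


def test_nonfinite_objective_aborts():
    with pytest.raises(ValueError, match="non-finite"):
        run_woa(lambda x: float("nan"), cfg(max_iter=2))


def test_dr_subset_best_seeds_with_elite_offspring():
    obj = B.make_objective("F1")
    c_first = cfg(init_mode="discrete_recombination", lambda_=50, n_agents=5, seed=3)
    c_best = cfg(init_mode="discrete_recombination", lambda_=50, n_agents=5, seed=3,
                 dr_subset="best")
    init_best = dr_init(c_best, np.random.default_rng(3), return_all=True)
    scores = np.sort([obj(p) for p in init_best.positions])
    res = run_reshwoa(obj, c_best)
    assert res.convergence_curve[0] <= scores[0]


def test_repeat_runs_aggregation():
    s = repeat_runs(lambda x: 0.0, cfg(max_iter=3), 1, algorithm="WOA")
    assert s.std == 0.0 and s.avg == 0.0 and s.n_runs == 1
    s = repeat_runs(lambda x: 0.0, cfg(max_iter=3), 4, algorithm="RESHWOA")
    assert s.avg == 0.0 and s.std == 0.0
    with pytest.raises(ValueError):
        repeat_runs(lambda x: 0.0, cfg(), 2, algorithm="PSO")
    with pytest.raises(ValueError):
        repeat_runs(None, cfg(), 2)


def test_repeat_runs_per_run_seeding_matches_single_runs():
    obj = B.make_objective("F1")
    c = cfg(max_iter=20, seed=100)
    summary = repeat_runs(obj, c, 3, algorithm="WOA")
    singles = [run_woa(obj, cfg(max_iter=20, seed=100 + k)).best_score for k in range(3)]
    assert np.allclose(summary.best_scores, singles)
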