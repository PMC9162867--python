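import math

import numpy as np
import pytest

from leukoswarm.optimizers import (
    ALGORITHMS,
    ObjectiveSpec,
    OptimizerConfig,
    abc_neighbor,
    abo_update,
    cso_chase,
    ica_empire_powers,
    ica_initial_powers,
    optimize,
    sso_female_move,
    sso_vibration,
    sso_weights,
)


def sphere(dim=2, half_width=5.0):
    return ObjectiveSpec(
        fitness=lambda x: float((np.asarray(x) ** 2).sum()),
        lower=[-half_width] * dim,
        upper=[half_width] * dim,
    )


# ---------------------------------------------------------------------------
# hand-arithmetic oracles for the update rules
# ---------------------------------------------------------------------------


def test_abo_update_hand_case():
    # N=2, D=1: f' = f + lq1(bz - v) + lq2(bq - v); v' = v + f' + jitter
    v = np.array([[1.0], [3.0]])
    f = np.array([[0.5], [-0.5]])
    bq = np.array([[0.0], [2.0]])
    bz = np.array([[0.0]])
    jit = np.array([[0.5], [-0.5]])
    f_new, v_new = abo_update(v, f, bq, bz, lq1=0.5, lq2=0.5, jitter=jit)
    # buffalo 0: f' = 0.5 + 0.5(0-1) + 0.5(0-1) = -0.5 ; v' = 1 - 0.5 + 0.5 = 1
    # buffalo 1: f' = -0.5 + 0.5(0-3) + 0.5(2-3) = -2.5 ; v' = 3 - 2.5 - 0.5 = 0
    np.testing.assert_allclose(f_new, [[-0.5], [-2.5]], atol=1e-12)
    np.testing.assert_allclose(v_new, [[1.0], [0.0]], atol=1e-12)


def test_abo_zero_learning_factors_leave_momentum_only():
    v = np.array([[2.0]])
    f = np.array([[0.25]])
    f_new, v_new = abo_update(v, f, v, v, lq1=0.0, lq2=0.0, jitter=0.5)
    assert f_new[0, 0] == 0.25
    assert v_new[0, 0] == pytest.approx(2.75)


def test_abo_at_both_bests_random_walks_only():
    v = np.array([[1.5]])
    f = np.array([[0.0]])
    f_new, v_new = abo_update(v, f, v, v, lq1=0.7, lq2=0.3, jitter=-0.5)
    assert f_new[0, 0] == 0.0
    assert v_new[0, 0] == pytest.approx(1.0)


def test_abc_neighbor_hand_case():
    # w = y_n + phi (y_n - y_m)
    assert abc_neighbor(np.array([2.0]), np.array([5.0]), np.array([0.5]))[0] == \
        pytest.approx(2.0 + 0.5 * (2.0 - 5.0))


def test_abc_dominant_source_has_highest_selection_probability():
    from leukoswarm.optimizers import _abc_selection_probs

    costs = np.array([5.0, 1.0, 4.0])  # source 1 strictly dominates
    probs = _abc_selection_probs(costs)
    assert probs[1] > probs[0] and probs[1] > probs[2]
    flat = _abc_selection_probs(np.array([2.0, 2.0, 2.0]))
    np.testing.assert_allclose(flat, [1 / 3] * 3)


def test_cso_chase_hand_case_and_fixed_points():
    a, target = np.array([1.0, 2.0]), np.array([3.0, 0.0])
    moved = cso_chase(a, target, step=0.5, rand=0.4)
    np.testing.assert_allclose(moved, a + 0.2 * (target - a), atol=1e-12)
    np.testing.assert_allclose(cso_chase(a, target, 0.0, 0.9), a)  # step=0
    np.testing.assert_allclose(cso_chase(a, a, 0.8, 0.9), a)  # at the optimum


def test_ica_initial_powers_symmetry_and_empire_cost_arithmetic():
    # equal imperialist costs -> equal powers
    np.testing.assert_allclose(ica_initial_powers(np.array([2.0, 2.0])), [0.5, 0.5])
    # zeta = 0 -> empire total cost equals imperialist cost exactly
    at, _, _ = ica_empire_powers(np.array([1.0, 3.0]), np.array([9.0, 9.0]), zeta=0.0)
    np.testing.assert_allclose(at, [1.0, 3.0], atol=1e-12)
    # 3 empires, hand-set costs, zeta = 0.1
    t = np.array([1.0, 2.0, 4.0])
    means = np.array([10.0, 20.0, 5.0])
    at, nat, ep = ica_empire_powers(t, means, zeta=0.1)
    np.testing.assert_allclose(at, [2.0, 4.0, 4.5], atol=1e-12)
    np.testing.assert_allclose(nat, [2.5, 0.5, 0.0], atol=1e-12)
    np.testing.assert_allclose(ep, [2.5 / 3.0, 0.5 / 3.0, 0.0], atol=1e-12)


def test_sso_weights_and_vibration_conventions():
    w = sso_weights(np.array([3.0, 1.0, 5.0]))  # minimization costs
    np.testing.assert_allclose(w, [0.5, 1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(sso_weights(np.array([2.0, 2.0])), [1.0, 1.0])
    assert sso_vibration(0.7, 0.0) == pytest.approx(0.7)  # e^0 = 1 at d=0
    assert sso_vibration(1.0, 2.0) == pytest.approx(math.exp(-4.0))


def test_sso_female_move_hand_case():
    fa, a_n, a_h = np.array([1.0]), np.array([2.0]), np.array([0.0])
    v_n, v_h = 0.5, 0.25
    out = sso_female_move(fa, a_n, v_n, a_h, v_h, alpha=0.2, beta=0.4,
                          delta=0.6, rand=0.9, attract=True)
    expect = 1.0 + 0.2 * 0.5 * (2.0 - 1.0) + 0.4 * 0.25 * (0.0 - 1.0) + 0.6 * 0.4
    assert out[0] == pytest.approx(expect, abs=1e-12)
    out_rep = sso_female_move(fa, a_n, v_n, a_h, v_h, 0.2, 0.4, 0.6, 0.9, False)
    expect_rep = 1.0 - 0.1 * 1.0 + 0.1 * 1.0 + 0.24
    assert out_rep[0] == pytest.approx(expect_rep, abs=1e-12)


def test_sso_flat_landscape_reduces_to_jitter():
    # best == worst -> all weights 1, vibrations w*e^{-d^2} stay finite and
    # the attraction terms cancel only through the (a - fa) factors
    fa = np.array([1.0])
    out = sso_female_move(fa, fa, 1.0, fa, 1.0, 0.3, 0.3, 0.5, 0.25, True)
    assert out[0] == pytest.approx(1.0 + 0.5 * (0.25 - 0.5))


# ---------------------------------------------------------------------------
# shared optimize() contracts
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("algo", ALGORITHMS)
def test_seed_determinism_bit_identical(algo):
    cfg = OptimizerConfig(algorithm=algo, population=12, iterations=30, seed=9)
    r1 = optimize(sphere(), cfg)
    r2 = optimize(sphere(), cfg)
    np.testing.assert_array_equal(r1.history, r2.history)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)


@pytest.mark.parametrize("algo", ALGORITHMS)
def test_elitism_bounds_and_convergence(algo):
    vals = []
    for seed in range(5):
        cfg = OptimizerConfig(algorithm=algo, population=20, iterations=100, seed=seed)
        r = optimize(sphere(), cfg)
        assert np.all(np.diff(r.history) <= 1e-15)  # monotone best
        assert np.all(r.best_position >= -5) and np.all(r.best_position <= 5)
        assert r.history[-1] == r.best_fitness
        vals.append(r.best_fitness)
    assert np.median(vals) <= 1e-2


@pytest.mark.parametrize("algo", ALGORITHMS)
def test_zero_iterations_returns_best_of_initial_population(algo):
    cfg = OptimizerConfig(algorithm=algo, population=15, iterations=0, seed=2)
    r = optimize(sphere(), cfg)
    rng = np.random.default_rng(2)
    init = -5 + rng.random((15, 2)) * 10
    assert r.best_fitness == pytest.approx(min((init**2).sum(axis=1)))
    assert r.evaluations == 15


@pytest.mark.parametrize("algo", ALGORITHMS)
def test_maximize_direction(algo):
    obj = ObjectiveSpec(
        fitness=lambda x: -float((np.asarray(x) ** 2).sum()),
        lower=[-3, -3], upper=[3, 3], direction="maximize",
    )
    r = optimize(obj, OptimizerConfig(algorithm=algo, population=15,
                                      iterations=60, seed=1))
    assert np.all(np.diff(r.history) >= -1e-15)  # nondecreasing for maximize
    assert r.best_fitness <= 0 and r.best_fitness > -1.0


def test_population_mean_approaches_known_minimum():
    # 1-D quadratic: median final best over seeds must beat the initial draw
    obj = ObjectiveSpec(fitness=lambda x: float((x[0] - 1.3) ** 2),
                        lower=[-10], upper=[10])
    for algo in ALGORITHMS:
        finals, initials = [], []
        for seed in range(5):
            cfg0 = OptimizerConfig(algorithm=algo, population=10, iterations=0, seed=seed)
            cfg = OptimizerConfig(algorithm=algo, population=10, iterations=100, seed=seed)
            initials.append(optimize(obj, cfg0).best_fitness)
            finals.append(optimize(obj, cfg).best_fitness)
        assert np.median(finals) < np.median(initials)


def test_variant_modes_run_and_stay_in_bounds():
    cfg = OptimizerConfig(algorithm="ABO", population=10, iterations=40, seed=0)
    cfg.abo.jitter = "uniform"
    r = optimize(sphere(), cfg)
    assert np.all(np.abs(r.best_position) <= 5.0)
    cfg2 = OptimizerConfig(algorithm="CSO", population=10, iterations=40, seed=0)
    cfg2.cso.ruthless_mode = "zero"
    r2 = optimize(sphere(), cfg2)
    # the zero vector is the sphere optimum, so the ruthless phase finds it
    assert r2.best_fitness <= 1e-6


def test_config_validation():
    with pytest.raises(ValueError):
        optimize(sphere(), OptimizerConfig(algorithm="PSO"))
    with pytest.raises(ValueError):
        optimize(sphere(), OptimizerConfig(population=2))
    cfg = OptimizerConfig(algorithm="ICA", population=8)
    cfg.ica.n_imperialists = 8
    with pytest.raises(ValueError):
        optimize(sphere(), cfg)
    cfg2 = OptimizerConfig(algorithm="CSO")
    cfg2.cso.visual = -1.0
    with pytest.raises(ValueError):
        optimize(sphere(), cfg2)
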