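"""Tests for progeny prediction and allocation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from matealloc.markerfx import MarkerEffects, gebv
from matealloc.mating import (
    MatingGrid,
    allocate,
    gains,
    predict_mating,
    preselect_boars,
    progeny_genotype_probs,
)
from tests.conftest import make_effects


def test_progeny_probs_trivial_pairs():
    assert progeny_genotype_probs(2.0, 2.0) == (1.0, 0.0, 0.0)
    assert progeny_genotype_probs(2.0, 0.0) == (0.0, 1.0, 0.0)
    assert progeny_genotype_probs(1.0, 1.0) == (0.25, 0.5, 0.25)
    assert progeny_genotype_probs(1.0, 0.0) == (0.0, 0.5, 0.5)
    assert progeny_genotype_probs(np.nan, 1.0) is None


def test_predict_mating_all_AA():
    # both parents AA everywhere: g = sum a_k, u = sum (2 - 2p) alpha
    from matealloc.genotypes import GenotypeMatrix

    m = 7
    counts = np.full((1, m), 2.0)
    p = np.linspace(0.2, 0.6, m)
    sires = GenotypeMatrix(counts.copy(), ["b1"], [f"s{j}" for j in range(m)])
    dams = GenotypeMatrix(counts.copy(), ["d1"], [f"s{j}" for j in range(m)])
    sires.freeze_freqs(p)
    dams.freeze_freqs(p)
    rng = np.random.default_rng(1)
    fx = MarkerEffects(
        snp_ids=list(sires.snp_ids), a=rng.normal(0, 1, m),
        d_star=rng.normal(0, 1, m), b_hat=0.5, p=p, sigma2_a=1.0, sigma2_d=1.0,
    )
    grid = predict_mating(sires, dams, fx)
    assert grid.g_hat[0, 0] == pytest.approx(np.sum(fx.a), abs=1e-10)
    assert grid.u_hat[0, 0] == pytest.approx(np.sum((2 - 2 * p) * fx.alpha), abs=1e-10)


def test_parental_average_identity(founders_small):
    fx = make_effects(founders_small, seed=5, b=10.0)
    boars = founders_small.subset(
        animals=founders_small.rows_for(
            [a for a in founders_small.animal_ids if a.startswith("B")]
        ),
        keep_freqs=True,
    )
    sows = founders_small.subset(
        animals=founders_small.rows_for(
            [a for a in founders_small.animal_ids if a.startswith("S")]
        ),
        keep_freqs=True,
    )
    grid = predict_mating(boars, sows, fx)
    gb = gebv(boars, fx.alpha, fx.p).to_numpy()
    gs = gebv(sows, fx.alpha, fx.p).to_numpy()
    np.testing.assert_allclose(grid.u_hat, (gb[:, None] + gs[None, :]) / 2.0, atol=1e-10)


def test_preselect_boars():
    s = pd.Series([3.0, -1.0, 2.0, 0.5], index=["b1", "b2", "b3", "b4"])
    assert set(preselect_boars(s, n_keep=4)) == set(s.index)  # identity
    assert preselect_boars(s, n_keep=2, direction="lower_better") == ["b2", "b4"]
    assert preselect_boars(s, n_keep=2, direction="higher_better") == ["b1", "b3"]
    rng = np.random.default_rng(0)
    picked = preselect_boars(s, n_keep=2, random_rng=rng)
    assert len(picked) == 2 and set(picked) <= set(s.index)


def _brute_force(values, n_matings, capacity, maximize=True):
    nb, ns = values.shape
    best = None
    for sows_used in itertools.combinations(range(ns), n_matings):
        for assign in itertools.product(range(nb), repeat=n_matings):
            counts = np.bincount(assign, minlength=nb)
            if counts.max() > capacity:
                continue
            val = sum(values[b, s] for b, s in zip(assign, sows_used))
            if best is None or (val > best if maximize else val < best):
                best = val
    return best


def test_allocate_toy_grid():
    vals = np.array([[3.0, 2.0, 1.0], [2.0, 4.0, 1.0]])
    grid = MatingGrid(["b1", "b2"], ["s1", "s2", "s3"], vals, vals)
    plan = allocate(grid, "g", n_matings=2, boar_capacity=1, direction="higher_better")
    assert set(plan.pairs) == {("b1", "s1"), ("b2", "s2")}
    assert plan.objective_value == pytest.approx(7.0)


def test_allocate_matches_brute_force():
    rng = np.random.default_rng(11)
    for trial in range(6):
        nb, ns = rng.integers(2, 5), rng.integers(3, 7)
        cap = int(rng.integers(1, 4))
        vals = rng.normal(0, 1, (nb, ns))
        n_mat = int(min(ns, nb * cap, rng.integers(2, 6)))
        grid = MatingGrid([f"b{i}" for i in range(nb)], [f"s{j}" for j in range(ns)],
                          vals, vals)
        for direction, maximize in (("higher_better", True), ("lower_better", False)):
            plan = allocate(grid, "g", n_matings=n_mat, boar_capacity=cap,
                            direction=direction)
            best = _brute_force(vals, n_mat, cap, maximize=maximize)
            assert plan.objective_value == pytest.approx(best, abs=1e-9)


def test_allocate_equal_values_feasible():
    vals = np.full((3, 5), 2.5)
    grid = MatingGrid([f"b{i}" for i in range(3)], [f"s{j}" for j in range(5)],
                      vals, vals)
    plan = allocate(grid, "g", n_matings=4, boar_capacity=2)
    assert plan.objective_value == pytest.approx(4 * 2.5)
    assert plan.boar_usage().max() <= 2
    assert len({s for _, s in plan.pairs}) == 4


def test_allocate_single_boar_greedy_case():
    vals = np.array([[5.0, 1.0, 4.0, 2.0, 3.0]])
    grid = MatingGrid(["b1"], [f"s{j}" for j in range(5)], vals, vals)
    plan = allocate(grid, "g", n_matings=3, boar_capacity=5, direction="higher_better")
    assert {s for _, s in plan.pairs} == {"s0", "s2", "s4"}


def test_allocate_infeasible_raises():
    vals = np.zeros((2, 3))
    grid = MatingGrid(["b1", "b2"], ["s1", "s2", "s3"], vals, vals)
    with pytest.raises(ValueError):
        allocate(grid, "g", n_matings=4, boar_capacity=5)
    with pytest.raises(ValueError):
        allocate(grid, "g", n_matings=3, boar_capacity=1)


def test_gains_arithmetic():
    vals = np.array([[3.0, 2.0, 1.0], [2.0, 4.0, 1.0]])
    grid = MatingGrid(["b1", "b2"], ["s1", "s2", "s3"], vals, vals)
    plan = allocate(grid, "g", n_matings=2, boar_capacity=1, direction="higher_better")
    plan = gains(plan, grid, sigma2_A=4.0)
    expected = (3.0 + 4.0) / 2 - vals.mean()
    assert plan.delta_G == pytest.approx(expected)
    assert plan.delta_G_sd == pytest.approx(expected / 2.0)
    # plan covering every pair -> zero gain
    full = MatingGrid(["b1"], ["s1", "s2"], np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
    p2 = allocate(full, "g", n_matings=2, boar_capacity=2)
    p2 = gains(p2, full, 1.0)
    assert p2.delta_G == pytest.approx(0.0)
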