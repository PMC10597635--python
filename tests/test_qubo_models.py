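import itertools

import numpy as np
import pytest

import annealclust as ac
from annealclust.errors import BQMError
from conftest import random_graph, single_edge


def all_states(n):
    return np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.uint8)


def brute_cut(g, x):
    """Independent cut-weight computation (plain loops, no package helpers)."""
    total = 0.0
    for (i, j), w in g.weights.items():
        if x[i] != x[j]:
            total += w
    return total


def test_single_edge_mincut_coefficients():
    bqm = ac.build_mincut_bqm(single_edge(), ac.MinCutParams(gamma=0.5))
    assert bqm.linear == {0: pytest.approx(0.5), 1: pytest.approx(0.5)}
    assert bqm.quadratic == {(0, 1): pytest.approx(-1.0)}
    assert bqm.offset == 0.0


def test_gamma_zero_reduces_to_weighted_cut_objective():
    g = ac.SNNGraph(4, {(0, 1): 0.5, (1, 2): 0.25, (0, 3): 1.0})
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=0.0))
    assert bqm.linear[0] == pytest.approx(1.5)  # weighted degree
    assert bqm.linear[1] == pytest.approx(0.75)
    assert set(bqm.quadratic) == set(g.weights)
    for (i, j), w in g.weights.items():
        assert bqm.quadratic[(i, j)] == pytest.approx(-2 * w)


def test_edgeless_graph_keeps_only_constraint_terms():
    g = ac.SNNGraph(3, {})
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=1.0))
    assert all(bqm.linear[i] == pytest.approx(-2.0) for i in range(3))
    assert bqm.quadratic == {
        (0, 1): pytest.approx(2.0),
        (0, 2): pytest.approx(2.0),
        (1, 2): pytest.approx(2.0),
    }


def test_mincut_edge_penalty_truth_table():
    """One unit edge at gamma=0: penalty 1 iff the endpoints disagree."""
    bqm = ac.build_mincut_bqm(single_edge(), ac.MinCutParams(gamma=0.0))
    expected = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 0.0}
    for state, penalty in expected.items():
        assert bqm.energy(np.array(state)) == pytest.approx(penalty)


def test_mvc_edge_penalty_truth_table():
    """One edge: the cover term 1 - x_i - x_j + x_i x_j is 1 only when both
    endpoints are unselected (the edge is uncovered)."""
    gamma = 2.0
    bqm = ac.build_mvc_bqm(single_edge(), ac.MvcParams(gamma=gamma))
    # full energies include the vertex-count term: 2, 1, 1, 2
    energies = {(0, 0): 2.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}
    for state, e in energies.items():
        assert bqm.energy(np.array(state)) == pytest.approx(e)
        # edge term alone, unscaled: (energy - #selected) / gamma
        uncovered = (e - sum(state)) / gamma
        assert uncovered == pytest.approx(1.0 if state == (0, 0) else 0.0)


def test_mvc_star_coefficients():
    star = ac.SNNGraph(4, {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0})
    bqm = ac.build_mvc_bqm(star, ac.MvcParams(gamma=1.0))
    assert bqm.linear[0] == pytest.approx(-2.0)  # 1 - gamma * deg(center)
    assert all(bqm.linear[i] == pytest.approx(0.0) for i in (1, 2, 3))
    assert bqm.offset == pytest.approx(3.0)


def test_mvc_all_zeros_energy_is_gamma_times_edges():
    g = random_graph(np.random.default_rng(3), 8)
    bqm = ac.build_mvc_bqm(g, ac.MvcParams(gamma=1.7))
    assert bqm.energy(np.zeros(8, dtype=int)) == pytest.approx(1.7 * len(g.weights))


@pytest.mark.parametrize("trial", range(20))
def test_mincut_energy_equals_cut_plus_balance_penalty(trial):
    """E(x) = cut(x) + gamma (sum x - n/2)^2 - gamma n^2/4, all states."""
    rng = np.random.default_rng(100 + trial)
    n = int(rng.integers(2, 11))
    g = random_graph(rng, n)
    gamma = float(rng.uniform(0.0, 2.0))
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=gamma))
    for x in all_states(n):
        s = x.sum()
        expected = brute_cut(g, x) + gamma * (s - n / 2) ** 2 - gamma * n**2 / 4
        assert bqm.energy(x) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("trial", range(10))
def test_mincut_complement_symmetry(trial):
    rng = np.random.default_rng(200 + trial)
    n = int(rng.integers(2, 11))
    g = random_graph(rng, n)
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=float(rng.uniform(0, 2))))
    states = all_states(n)
    np.testing.assert_allclose(
        bqm.energies(states), bqm.energies(1 - states), atol=1e-9
    )


@pytest.mark.parametrize("trial", range(10))
def test_mvc_energy_counts_cover_size_and_uncovered_edges(trial):
    rng = np.random.default_rng(300 + trial)
    n = int(rng.integers(2, 11))
    g = random_graph(rng, n)
    gamma = float(rng.uniform(0.5, 3.0))
    bqm = ac.build_mvc_bqm(g, ac.MvcParams(gamma=gamma))
    for x in all_states(n):
        uncovered = sum(1 for (i, j) in g.weights if x[i] == 0 and x[j] == 0)
        assert bqm.energy(x) == pytest.approx(x.sum() + gamma * uncovered, abs=1e-9)


def test_mvc_ground_states_are_minimum_covers_at_large_gamma():
    rng = np.random.default_rng(17)
    for _ in range(5):
        n = int(rng.integers(3, 10))
        g = random_graph(rng, n)
        bqm = ac.build_mvc_bqm(g, ac.MvcParams(gamma=float(n + 1)))
        states = all_states(n)
        energies = bqm.energies(states)
        ground = states[np.argmin(energies)]
        assert all(ground[i] or ground[j] for (i, j) in g.weights)
        best_cover = min(
            int(x.sum())
            for x in states
            if all(x[i] or x[j] for (i, j) in g.weights)
        )
        assert int(ground.sum()) == best_cover


def test_balance_penalty_grows_with_gamma():
    """The energy gap paid by a less balanced state over a more balanced one
    never shrinks as gamma increases."""
    g = random_graph(np.random.default_rng(9), 8)
    unbal = np.array([1, 1, 1, 1, 1, 1, 1, 0], dtype=np.uint8)
    bal = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.uint8)
    gaps = []
    for gamma in (0.0, 0.5, 1.0, 2.0, 5.0):
        bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=gamma))
        gaps.append(bqm.energy(unbal) - bqm.energy(bal))
    assert all(b >= a - 1e-12 for a, b in zip(gaps, gaps[1:]))


def test_unweighted_flag_recovers_unit_edge_objective():
    g = ac.SNNGraph(3, {(0, 1): 0.25, (1, 2): 0.5})
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=0.0, weighted=False))
    x = np.array([0, 1, 0])
    assert bqm.energy(x) == pytest.approx(2.0)  # both edges cut, unit weight each


def test_bqm_json_round_trip():
    g = random_graph(np.random.default_rng(4), 6)
    bqm = ac.build_mincut_bqm(g, ac.MinCutParams(gamma=0.3))
    back = ac.BinaryQuadraticModel.from_json(bqm.to_json())
    assert back.n_vars == bqm.n_vars
    assert back.linear == pytest.approx(bqm.linear)
    assert back.quadratic == pytest.approx(bqm.quadratic)
    assert back.offset == pytest.approx(bqm.offset)


def test_parameter_validation():
    with pytest.raises(BQMError):
        ac.MinCutParams(gamma=-0.1)
    with pytest.raises(BQMError):
        ac.MvcParams(gamma=0.0)
    with pytest.raises(BQMError):
        ac.build_mvc_bqm(ac.SNNGraph(3, {}), ac.MvcParams(gamma=1.0))
    bqm = ac.build_mincut_bqm(single_edge(), ac.MinCutParams(gamma=0.0))
    with pytest.raises(BQMError):
        bqm.energy(np.array([0, 2]))
    with pytest.raises(BQMError):
        bqm.energy(np.array([0, 1, 0]))
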