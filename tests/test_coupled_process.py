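"""Coupled-process layer: transition algebra, stationarity, simulation."""

import numpy as np
import pytest

from iti import (
    FiniteDistribution,
    JointTable,
    ValidationError,
    check_markov_structure,
    empirical_lagged_joint,
    joint_transition,
    lagged_joint,
    simulate,
    stationary_distribution,
    three_time_joint,
)
from iti.coupled_process import THREE_TIME_VARS
from iti.discrete_info import conditional_mutual_information
from iti.fixtures import random_coupled_process

from ._oracles import naive_stationary
from .conftest import deterministic_pair_process, uniform_env_process


def test_joint_transition_identity_kernels_is_identity():
    proc = deterministic_pair_process(lambda s, e: s, lambda s, e: e)
    assert np.array_equal(joint_transition(proc), np.eye(4))


def test_joint_transition_uniform_kernels():
    phi = np.full((2, 2, 2), 0.5)
    proc = uniform_env_process(phi)
    assert np.allclose(joint_transition(proc), 0.25, atol=0)


def test_joint_transition_rows_stochastic_random():
    for seed in range(20):
        T = joint_transition(random_coupled_process(3, 2, seed))
        assert np.max(np.abs(T.sum(axis=1) - 1.0)) < 1e-12


def test_stationary_symmetric_flip_matrix():
    pi = stationary_distribution(np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert np.allclose(pi.probs, [0.5, 0.5], atol=1e-12)


def test_stationary_two_state_balance():
    # exit probabilities p=0.2, q=0.6 balance at pi = (0.75, 0.25)
    T = np.array([[0.8, 0.2], [0.6, 0.4]])
    pi = stationary_distribution(T)
    assert np.allclose(pi.probs, [0.75, 0.25], atol=1e-12)


def test_stationary_residual_and_oracle_agreement():
    rng = np.random.default_rng(11)
    for _ in range(20):
        T = rng.random((4, 4)) + 1e-3
        T /= T.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
        assert np.max(np.abs(pi.probs @ T - pi.probs)) < 1e-10
        assert np.allclose(pi.probs, naive_stationary(T), atol=1e-9)


def test_stationary_reducible_chain_asks_for_mu():
    with pytest.raises(ValidationError, match="mu"):
        stationary_distribution(np.eye(3))


def test_lagged_joint_identity_kernels_with_explicit_base():
    proc = deterministic_pair_process(lambda s, e: s, lambda s, e: e)
    mu = FiniteDistribution(proc.pair_labels, (0.1, 0.2, 0.3, 0.4))
    lj = lagged_joint(proc, mu)
    cells = lj.joint.cells
    for ie in range(2):
        for s in range(2):
            assert cells[s, ie, s, ie] == pytest.approx(mu.probs[ie * 2 + s])
    assert cells.sum() == pytest.approx(1.0)
    assert np.count_nonzero(cells) == 4


def test_lagged_joint_product_form_independence():
    """The phi*psi factorisation forces I(S_next; E_next | S_n, E_n) = 0."""
    for seed in range(30):
        proc = random_coupled_process(2, 3, seed)
        lj = lagged_joint(proc)
        assert (
            conditional_mutual_information(
                lj.joint, "S_next", "E_next", ("S_n", "E_n")
            )
            < 1e-9
        )


def test_lagged_joint_stationary_marginals_match():
    proc = random_coupled_process(3, 2, 5)
    lj = lagged_joint(proc, "stationary")
    now = lj.joint.marginal_cells(("E_n", "S_n")).ravel()
    nxt = lj.joint.marginal_cells(("E_next", "S_next")).ravel()
    assert np.max(np.abs(now - nxt)) < 1e-9
    assert np.max(np.abs(now - lj.base.probs)) < 1e-9


def test_simulation_is_reproducible():
    proc = random_coupled_process(2, 2, 3)
    a = simulate(proc, 500, seed=42)
    b = simulate(proc, 500, seed=42)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, simulate(proc, 500, seed=43))


def test_simulation_deterministic_kernels_follow_orbit():
    proc = deterministic_pair_process(lambda s, e: e, lambda s, e: 1 - e)
    mu = FiniteDistribution(proc.pair_labels, (1.0, 0.0, 0.0, 0.0))  # start (0,0)
    traj = simulate(proc, 6, seed=0, base=mu)
    # orbit: (0,0) -> (0,1) -> (1,0) -> (0,1) -> (1,0) ...
    expected = [(0, 0), (0, 1), (1, 0), (0, 1), (1, 0), (0, 1)]
    assert [tuple(r) for r in traj] == expected


def test_simulation_uniform_frequencies_within_three_se():
    proc = uniform_env_process(np.full((2, 2, 2), 0.5))
    traj = simulate(proc, 100_000, seed=9)
    p = 0.25
    se = np.sqrt(p * (1 - p) / len(traj))
    for s in range(2):
        for e in range(2):
            freq = np.mean((traj[:, 0] == s) & (traj[:, 1] == e))
            assert abs(freq - p) < 3 * se


def test_empirical_lagged_joint_small_cases():
    lj = empirical_lagged_joint(np.array([[0, 1], [1, 0]]), 2, 2)
    assert lj.joint.cells[0, 1, 1, 0] == 1.0
    alternating = np.array([[0, 0], [1, 1]] * 50)
    lj = empirical_lagged_joint(alternating, 2, 2)
    nz = {idx: v for idx, v in np.ndenumerate(lj.joint.cells) if v > 0}
    assert nz == {(0, 0, 1, 1): pytest.approx(50 / 99), (1, 1, 0, 0): pytest.approx(49 / 99)}


def test_empirical_lagged_joint_flags_position_of_bad_symbol():
    with pytest.raises(ValidationError, match="position 2"):
        empirical_lagged_joint(np.array([[0, 0], [1, 1], [2, 0]]), 2, 2)


def test_empirical_converges_to_model_lagged_joint():
    proc = random_coupled_process(2, 2, 21)
    truth = lagged_joint(proc).joint.cells
    tv = []
    for T in (1_000, 10_000, 100_000):
        emp = empirical_lagged_joint(simulate(proc, T, seed=77), 2, 2)
        tv.append(0.5 * np.abs(emp.joint.cells - truth).sum())
    assert tv[0] > tv[1] > tv[2]
    assert tv[2] < 0.01


def test_markov_structure_residuals_vanish_for_model_joints():
    for seed in (0, 1):
        res = check_markov_structure(three_time_joint(random_coupled_process(2, 2, seed)))
        assert res["markov_residual"] < 1e-9
        assert res["product_form_residual"] < 1e-9


def test_markov_structure_detects_hidden_confounder():
    """If S_3 and E_3 share an extra coin the product form must fail."""
    cells = np.zeros((2, 2, 2, 2, 2, 2))
    for idx in np.ndindex(2, 2, 2, 2):
        for coin in range(2):
            cells[idx + (coin, coin)] += (1 / 16) * 0.5
    res = check_markov_structure(JointTable(THREE_TIME_VARS, cells))
    assert res["product_form_residual"] == pytest.approx(1.0, abs=1e-9)


def test_markov_structure_deterministic_orbit_exact_zero():
    proc = deterministic_pair_process(lambda s, e: 1 - s, lambda s, e: e)
    mu = FiniteDistribution(proc.pair_labels, (0.25,) * 4)
    res = check_markov_structure(three_time_joint(proc, mu))
    assert res["markov_residual"] == 0.0
    assert res["product_form_residual"] == 0.0
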