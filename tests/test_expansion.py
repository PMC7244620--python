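"""Boundary expansion: blocking exactness, identities, monotone growth."""

import numpy as np
import pytest

from iti import (
    FactoredProcess,
    Kernel,
    Partition,
    StateSpace,
    ValidationError,
    block_measures,
    coarse_grain,
    expanded_measures,
    expansion_identities,
    full_transition,
    greedy_expand,
    joint_transition,
    profile,
    to_coupled_process,
    unit_lagged_joint,
)
from iti.fixtures import random_binary_params, random_factored_process


def _pair_as_factored(params) -> FactoredProcess:
    """The two-spin model expressed as a 2-unit factored chain
    (unit 0 = system spin, unit 1 = environment spin)."""
    proc = to_coupled_process(params)
    phi, psi = proc.phi.table, proc.psi.table  # phi[e,s,s'], psi[s,e,e']
    k0 = np.transpose(phi, (1, 0, 2))  # [s, e, s']
    k1 = psi  # [s, e, e']
    units = (StateSpace("u0", (+1, -1)), StateSpace("u1", (+1, -1)))
    return FactoredProcess(units, (k0, k1))


def test_partition_validation():
    with pytest.raises(ValidationError, match="overlap"):
        Partition((0,), (0,), (1,))
    with pytest.raises(ValidationError, match="empty"):
        Partition((), (0,), (1,))
    with pytest.raises(ValidationError, match="cover"):
        Partition((0,), (1,), ()).validate_against(random_factored_process(3, 0))


def test_coarse_grain_rejects_degenerate_blocking():
    fp = random_factored_process(3, 1)
    with pytest.raises(ValidationError):
        coarse_grain(fp, ())
    with pytest.raises(ValidationError):
        coarse_grain(fp, (0, 1, 2))


def test_binary_pair_blocking_reproduces_worked_example():
    """Viewing the two-spin model as a 2-unit factored chain and blocking
    unit 0 as the system must reproduce the worked example exactly."""
    params = random_binary_params(3)
    fp = _pair_as_factored(params)
    blocked = coarse_grain(fp, (0,))
    direct = to_coupled_process(params)
    assert np.max(np.abs(joint_transition(blocked) - joint_transition(direct))) < 1e-12
    ref = profile(direct)
    m = block_measures(fp, (0,))
    assert m["A"] == pytest.approx(ref.A, abs=1e-10)
    assert m["A_star"] == pytest.approx(ref.A_star, abs=1e-10)
    assert m["nC"] == pytest.approx(ref.nC, abs=1e-10)


def test_full_transition_rows_stochastic_any_blocking():
    fp = random_factored_process(3, 7)
    assert np.max(np.abs(full_transition(fp).sum(axis=1) - 1.0)) < 1e-12
    for sys in ((0,), (1,), (0, 2)):
        T = joint_transition(coarse_grain(fp, sys))
        assert np.max(np.abs(T.sum(axis=1) - 1.0)) < 1e-12


def test_blocked_process_measures_equal_block_marginals():
    """Measures via the blocked CoupledProcess equal measures computed on
    block-marginals of the full chain's lagged joint."""
    fp = random_factored_process(3, 13)
    for sys in ((0,), (0, 1), (2,)):
        blocked = profile(coarse_grain(fp, sys))
        direct = block_measures(fp, sys)
        for key in ("A", "A_star", "nC"):
            assert getattr(blocked, key if key != "A_star" else "A_star") == (
                pytest.approx(direct[key], abs=1e-9)
            )


def test_independent_delta_unit_changes_nothing():
    """Internalising a unit that is independent noise leaves A and A*
    unchanged (every correction term vanishes)."""
    rng = np.random.default_rng(0)
    # units 0,1 coupled to each other only; unit 2 isolated iid noise
    k01 = rng.random((2, 2, 2)) + 1e-3
    k01 /= k01.sum(axis=-1, keepdims=True)
    k0 = np.repeat(k01[:, :, None, :], 2, axis=2)  # ignores unit 2
    k1 = np.transpose(k0, (1, 0, 2, 3))
    k2 = np.broadcast_to(np.array([0.6, 0.4]), (2, 2, 2, 2)).copy()
    units = tuple(StateSpace(f"u{i}", (0, 1)) for i in range(3))
    fp = FactoredProcess(units, (k0, k1, k2))
    res = expanded_measures(fp, Partition((0,), (2,), (1,)))
    assert res["A_after"] == pytest.approx(res["A_before"], abs=1e-9)
    assert res["A_star_after"] == pytest.approx(res["A_star_before"], abs=1e-9)


def test_internalizing_copying_unit_reduces_environmental_drive():
    """A unit that copies the system each step is an environmental channel;
    absorbing it cannot increase nC."""
    rng = np.random.default_rng(4)
    k0 = rng.random((2, 2, 2, 2)) + 1e-3  # system unit, driven by all
    k0 /= k0.sum(axis=-1, keepdims=True)
    k1 = np.zeros((2, 2, 2, 2))  # delta unit: copies unit 0 (tiny noise)
    for s in range(2):
        k1[s, :, :, s] = 0.99
        k1[s, :, :, 1 - s] = 0.01
    k2 = rng.random((2, 2, 2, 2)) + 1e-3
    k2 /= k2.sum(axis=-1, keepdims=True)
    units = tuple(StateSpace(f"u{i}", (0, 1)) for i in range(3))
    fp = FactoredProcess(units, (k0, k1, k2))
    res = expanded_measures(fp, Partition((0,), (1,), (2,)))
    assert res["nC_after"] <= res["nC_before"] + 1e-9


def test_expansion_identities_and_monotonicity_battery():
    """The three expansion identities hold to rounding and A, A* never
    decrease, on 200 seeded random 3-unit chains."""
    for seed in range(200):
        fp = random_factored_process(3, seed)
        part = Partition((0,), (1,), (2,))
        res = expansion_identities(fp, part)
        assert max(res.values()) < 1e-8
        m = expanded_measures(fp, part)
        assert m["A_after"] >= m["A_before"] - 1e-9
        assert m["A_star_after"] >= m["A_star_before"] - 1e-9


def test_greedy_lambda_zero_expands_fully():
    for seed in (0, 5, 9):
        fp = random_factored_process(4, seed)
        trace = greedy_expand(fp, (0,), measure="A_star", lam=0.0)
        assert len(trace) == 3  # every environment unit gets internalised
        assert trace[-1]["system"] == (0, 1, 2, 3)


def test_greedy_huge_lambda_never_starts():
    fp = random_factored_process(3, 2)
    assert greedy_expand(fp, (0,), lam=1e6) == []


def test_greedy_moderate_lambda_takes_partner_and_stops():
    """With one strongly coupled pair plus an isolated noise unit, a
    moderate size penalty internalises the partner and then stops."""
    # unit 1 copies unit 0; unit 2 is isolated iid noise
    k0 = np.zeros((2, 2, 2, 2))
    for s in range(2):  # near-deterministic self-copy, slight pull from u1
        for u1 in range(2):
            p_keep = 0.93 if u1 == s else 0.87
            k0[s, u1, :, s] = p_keep
            k0[s, u1, :, 1 - s] = 1 - p_keep
    k1 = np.zeros((2, 2, 2, 2))
    for s in range(2):
        k1[s, :, :, s] = 0.95
        k1[s, :, :, 1 - s] = 0.05
    k2 = np.broadcast_to(np.array([0.5, 0.5]), (2, 2, 2, 2)).copy()
    units = tuple(StateSpace(f"u{i}", (0, 1)) for i in range(3))
    fp = FactoredProcess(units, (k0, k1, k2))
    trace = greedy_expand(fp, (0,), measure="A_star", lam=0.02)
    assert [rec["unit"] for rec in trace] == [1]
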