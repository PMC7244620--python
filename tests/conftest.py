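import numpy as np
import pytest

from iti import (
    CoupledProcess,
    FiniteDistribution,
    JointTable,
    Kernel,
    LaggedJoint,
    StateSpace,
)


@pytest.fixture
def xor_joint() -> JointTable:
    """Target = XOR of two independent fair bits: variables (T, X, Y)."""
    cells = np.zeros((2, 2, 2))
    for x in range(2):
        for y in range(2):
            cells[x ^ y, x, y] = 0.25
    return JointTable(("T", "X", "Y"), cells)


@pytest.fixture
def copy_joint() -> JointTable:
    """One fair bit duplicated into target and both sources."""
    cells = np.zeros((2, 2, 2))
    cells[0, 0, 0] = cells[1, 1, 1] = 0.5
    return JointTable(("T", "X", "Y"), cells)


@pytest.fixture
def independent_joint() -> JointTable:
    """Target independent of both sources (all three fair, product)."""
    return JointTable(("T", "X", "Y"), np.full((2, 2, 2), 0.125))


def make_lagged(cells: np.ndarray, labels=None) -> LaggedJoint:
    """Wrap a raw (S_n, E_n, S_next, E_next) array as a LaggedJoint."""
    nS, nE = cells.shape[0], cells.shape[1]
    lab = labels or {}
    jt = JointTable(("S_n", "E_n", "S_next", "E_next"), cells, lab)
    base = FiniteDistribution(
        tuple((s, e) for e in jt.labels["E_n"] for s in jt.labels["S_n"]),
        jt.marginal_cells(("E_n", "S_n")).reshape(nE * nS),
    )
    return LaggedJoint(jt, base)


def deterministic_pair_process(
    s_map, e_map, nS: int = 2, nE: int = 2
) -> CoupledProcess:
    """A coupled process whose kernels are deterministic maps
    ``s' = s_map(s, e)`` and ``e' = e_map(s, e)`` on integer states."""
    S = StateSpace("S", tuple(range(nS)))
    E = StateSpace("E", tuple(range(nE)))
    phi = np.zeros((nE, nS, nS))
    psi = np.zeros((nS, nE, nE))
    for e in range(nE):
        for s in range(nS):
            phi[e, s, s_map(s, e)] = 1.0
            psi[s, e, e_map(s, e)] = 1.0
    return CoupledProcess(S, E, Kernel((E, S), S, phi), Kernel((S, E), E, psi))


def uniform_env_process(phi_table: np.ndarray) -> CoupledProcess:
    """Binary process with the given system kernel and an iid-uniform
    environment."""
    S = StateSpace("S", (0, 1))
    E = StateSpace("E", (0, 1))
    psi = np.full((2, 2, 2), 0.5)
    return CoupledProcess(S, E, Kernel((E, S), S, phi_table), Kernel((S, E), E, psi))
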