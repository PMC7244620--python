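"""The coupled system-environment stochastic process.

A *system* S and its *environment* E evolve synchronously on finite state
sets.  The next system state is drawn from the kernel ``phi(e, s; s')`` and
the next environment state, from the same time-n pair, via
``psi(s, e; e')``, so one step of the joint chain factorises as

    P(s', e' | s, e) = phi(e, s; s') * psi(s, e; e').

This product form is itself a conditional-independence statement,
``I(S_{n+1}; E_{n+1} | S_n, E_n) = 0``, which :func:`check_markov_structure`
verifies numerically alongside the first-order Markov property.

Joint states ``(s, e)`` are enumerated with the environment as the slow
index: pair index ``= e_index * |S| + s_index``.  For two binary units with
labels ``(+1, -1)`` this yields the ordering (+1,+1), (-1,+1), (+1,-1),
(-1,-1) used by the worked example's printed transition matrix.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .discrete_info import (
    FiniteDistribution,
    JointTable,
    ValidationError,
    conditional_mutual_information,
)
from .tolerances import TOL

__all__ = [
    "StateSpace",
    "Kernel",
    "CoupledProcess",
    "LaggedJoint",
    "joint_transition",
    "stationary_distribution",
    "lagged_joint",
    "simulate",
    "empirical_lagged_joint",
    "three_time_joint",
    "check_markov_structure",
]

LAGGED_VARS = ("S_n", "E_n", "S_next", "E_next")


@dataclass(frozen=True)
class StateSpace:
    """A named finite state set with ordered labels."""

    name: str
    labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 1:
            raise ValidationError(f"state space {self.name!r} is empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"state space {self.name!r} has duplicate labels")

    @property
    def n(self) -> int:
        return len(self.labels)


class Kernel:
    """A conditional probability table ``p(next | conditioning tuple)``.

    ``table`` has one leading axis per conditioning space (in ``given``
    order) and a trailing axis over ``over``; every row must be a
    probability distribution.
    """

    def __init__(self, given: Sequence[StateSpace], over: StateSpace, table: np.ndarray):
        given = tuple(given)
        table = np.asarray(table, dtype=float)
        expected = tuple(g.n for g in given) + (over.n,)
        if table.shape != expected:
            raise ValidationError(
                f"kernel over {over.name!r}: table shape {table.shape} != {expected}"
            )
        if np.any(table < 0.0):
            idx = tuple(int(i) for i in np.argwhere(table < 0.0)[0])
            raise ValidationError(f"kernel over {over.name!r}: negative entry at {idx}")
        sums = table.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > TOL.prob_atol)
        if bad.size:
            idx = tuple(int(i) for i in bad[0])
            raise ValidationError(
                f"kernel over {over.name!r}: row {idx} sums to {sums[idx]!r}, not 1"
            )
        self.given = given
        self.over = over
        self.table = table


@dataclass
class CoupledProcess:
    """A system-environment pair with kernels phi (system) and psi
    (environment) and an optional initial distribution ``mu`` over joint
    states (pair order: environment slow, system fast)."""

    S: StateSpace
    E: StateSpace
    phi: Kernel  # given (E, S), over S
    psi: Kernel  # given (S, E), over E
    mu: FiniteDistribution | None = None

    def __post_init__(self):
        if self.phi.table.shape != (self.E.n, self.S.n, self.S.n):
            raise ValidationError(
                f"phi shape {self.phi.table.shape} inconsistent with |E|={self.E.n}, |S|={self.S.n}"
            )
        if self.psi.table.shape != (self.S.n, self.E.n, self.E.n):
            raise ValidationError(
                f"psi shape {self.psi.table.shape} inconsistent with |S|={self.S.n}, |E|={self.E.n}"
            )
        if self.mu is not None and len(self.mu) != self.S.n * self.E.n:
            raise ValidationError(
                f"mu has {len(self.mu)} outcomes, expected {self.S.n * self.E.n}"
            )

    @property
    def pair_labels(self) -> tuple:
        return tuple((s, e) for e in self.E.labels for s in self.S.labels)


@dataclass
class LaggedJoint:
    """Joint distribution of (S_n, E_n, S_{n+1}, E_{n+1}) under a stated
    time-n distribution ``base`` over joint pairs."""

    joint: JointTable
    base: FiniteDistribution
    base_label: str = "custom"

    def __post_init__(self):
        if tuple(self.joint.variables) != LAGGED_VARS:
            raise ValidationError(
                f"lagged joint variables must be {LAGGED_VARS}, got {self.joint.variables}"
            )
        nS, nE = self.joint.shape[0], self.joint.shape[1]
        marg = self.joint.marginal_cells(("E_n", "S_n")).reshape(nE * nS)
        if np.max(np.abs(marg - self.base.probs)) > TOL.prob_atol:
            raise ValidationError("time-n marginal of lagged joint differs from base")


def joint_transition(proc: CoupledProcess) -> np.ndarray:
    """Row-stochastic matrix of the joint chain on S x E.

    Entry ``[(s,e), (s',e')] = phi(e,s;s') * psi(s,e;e')`` with pair index
    ``e*|S| + s``.
    """
    P, Q = proc.phi.table, proc.psi.table  # P[e,s,s'], Q[s,e,e']
    n = proc.S.n * proc.E.n
    A = np.einsum("est,seu->esut", P, Q)  # (e, s, e', s')
    return A.reshape(n, n)


def stationary_distribution(
    T: np.ndarray, labels: Sequence | None = None
) -> FiniteDistribution:
    """The stationary distribution pi of a row-stochastic matrix.

    Solved via the null space of ``T' - I``; if the fixed point is not
    unique (reducible chain) an error asks the caller to supply an explicit
    time-n distribution.  The returned pi satisfies
    ``max|pi T - pi| < TOL.stationary_atol``.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValidationError(f"transition matrix must be square, got {T.shape}")
    if np.max(np.abs(T.sum(axis=1) - 1.0)) > TOL.prob_atol:
        raise ValidationError("transition matrix is not row-stochastic")
    ns = scipy.linalg.null_space(T.T - np.eye(T.shape[0]), rcond=1e-12)
    if ns.shape[1] != 1:
        raise ValidationError(
            f"stationary distribution is not unique ({ns.shape[1]} fixed points); "
            "supply the time-n distribution mu explicitly"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-12):
        raise ValidationError(
            "fixed point has negative mass; supply mu explicitly"
        )
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    # polish by power iteration until the fixed-point residual meets tolerance
    for _ in range(10_000):
        if np.max(np.abs(pi @ T - pi)) < TOL.stationary_atol:
            break
        pi = pi @ T
        pi = pi / pi.sum()
    else:  # pragma: no cover - defensive
        raise ValidationError("stationary solver failed to reach residual tolerance")
    if labels is None:
        labels = range(len(pi))
    return FiniteDistribution(labels, pi)


def _resolve_base(
    proc: CoupledProcess, base: str | FiniteDistribution
) -> tuple[FiniteDistribution, str]:
    if isinstance(base, FiniteDistribution):
        if len(base) != proc.S.n * proc.E.n:
            raise ValidationError("base distribution has the wrong number of outcomes")
        return base, "custom"
    if base == "stationary":
        pi = stationary_distribution(joint_transition(proc), proc.pair_labels)
        return pi, "stationary"
    if base == "mu":
        if proc.mu is None:
            raise ValidationError("process has no mu; pass a distribution explicitly")
        return proc.mu, "mu"
    raise ValidationError(f"unknown base {base!r}; use 'stationary', 'mu' or a distribution")


def lagged_joint(
    proc: CoupledProcess, base: str | FiniteDistribution = "stationary"
) -> LaggedJoint:
    """The one-step lagged joint P(S_n, E_n, S_{n+1}, E_{n+1}).

    ``base`` selects the time-n distribution: the stationary distribution
    of the joint chain (default), the process's own ``mu``, or any explicit
    distribution over joint pairs.
    """
    mu, label = _resolve_base(proc, base)
    nS, nE = proc.S.n, proc.E.n
    B = mu.probs.reshape(nE, nS)  # [e, s]
    cells = np.einsum("es,est,seu->setu", B, proc.phi.table, proc.psi.table)
    jt = JointTable(
        LAGGED_VARS,
        cells,
        {
            "S_n": proc.S.labels,
            "E_n": proc.E.labels,
            "S_next": proc.S.labels,
            "E_next": proc.E.labels,
        },
    )
    return LaggedJoint(jt, mu, label)


def simulate(
    proc: CoupledProcess,
    steps: int,
    seed: int,
    base: str | FiniteDistribution = "stationary",
) -> np.ndarray:
    """Sample a trajectory of ``steps`` (s, e) index pairs.

    The initial pair is drawn from ``base``; each subsequent step draws the
    system state from phi and then the environment state from psi, both
    reading the same time-n pair (synchronous update).  Reproducible for a
    fixed seed.
    """
    if steps < 1:
        raise ValidationError("steps must be >= 1")
    mu, _ = _resolve_base(proc, base)
    rng = np.random.default_rng(seed)
    nS = proc.S.n
    pair = int(rng.choice(len(mu), p=mu.probs))
    s, e = pair % nS, pair // nS
    def _cum(row: np.ndarray) -> list[float]:
        c = list(np.cumsum(row))
        c[-1] = 1.0  # guard against rounding shortfall at the top
        return c

    cum_phi = [[_cum(proc.phi.table[ee, ss]) for ss in range(nS)]
               for ee in range(proc.E.n)]
    cum_psi = [[_cum(proc.psi.table[ss, ee]) for ee in range(proc.E.n)]
               for ss in range(nS)]
    u = rng.random((steps - 1, 2))
    out = np.empty((steps, 2), dtype=np.int64)
    out[0] = s, e
    for t in range(steps - 1):
        s_next = bisect_left(cum_phi[e][s], u[t, 0])
        e_next = bisect_left(cum_psi[s][e], u[t, 1])
        s, e = s_next, e_next
        out[t + 1] = s, e
    return out


def empirical_lagged_joint(
    trajectory: np.ndarray, nS: int, nE: int,
    labels_S: Sequence | None = None, labels_E: Sequence | None = None,
) -> LaggedJoint:
    """Plug-in lagged joint from consecutive pairs of a trajectory.

    Each of the ``T - 1`` consecutive (state, next state) pairs contributes
    mass ``1/(T-1)``; the base is the empirical time-n marginal.
    """
    traj = np.asarray(trajectory, dtype=np.int64)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValidationError("trajectory must be an array of (s, e) index pairs")
    if traj.shape[0] < 2:
        raise ValidationError("trajectory must have at least 2 time steps")
    for col, size, name in ((0, nS, "system"), (1, nE, "environment")):
        bad = np.flatnonzero((traj[:, col] < 0) | (traj[:, col] >= size))
        if bad.size:
            t = int(bad[0])
            raise ValidationError(
                f"{name} state {traj[t, col]} out of alphabet at position {t}"
            )
    T = traj.shape[0]
    cells = np.zeros((nS, nE, nS, nE))
    np.add.at(cells, (traj[:-1, 0], traj[:-1, 1], traj[1:, 0], traj[1:, 1]), 1.0)
    cells /= T - 1
    lS = tuple(labels_S) if labels_S is not None else tuple(range(nS))
    lE = tuple(labels_E) if labels_E is not None else tuple(range(nE))
    jt = JointTable(
        LAGGED_VARS, cells,
        {"S_n": lS, "E_n": lE, "S_next": lS, "E_next": lE},
    )
    base = FiniteDistribution(
        tuple((s, e) for e in lE for s in lS),
        jt.marginal_cells(("E_n", "S_n")).reshape(nS * nE),
    )
    return LaggedJoint(jt, base, "empirical")


THREE_TIME_VARS = ("S_1", "E_1", "S_2", "E_2", "S_3", "E_3")


def three_time_joint(
    proc: CoupledProcess, base: str | FiniteDistribution = "stationary"
) -> JointTable:
    """Joint distribution over three consecutive times (S,E)_1..3."""
    mu, _ = _resolve_base(proc, base)
    nS, nE = proc.S.n, proc.E.n
    B = mu.probs.reshape(nE, nS)
    P, Q = proc.phi.table, proc.psi.table
    cells = np.einsum("es,est,seu,utv,tuw->setuvw", B, P, Q, P, Q)
    labels = {v: (proc.S.labels if v.startswith("S") else proc.E.labels)
              for v in THREE_TIME_VARS}
    return JointTable(THREE_TIME_VARS, cells, labels)


def check_markov_structure(joint: JointTable) -> dict[str, float]:
    """Residuals of the conditional independences implied by the causal
    structure of the coupled process, on a three-time joint.

    Returns ``markov_residual`` = I((S,E)_3; (S,E)_1 | (S,E)_2) and
    ``product_form_residual`` = I(S_3; E_3 | S_2, E_2).  Both vanish (to
    rounding) for any joint generated by kernels; a hidden common cause of
    S_3 and E_3 shows up in the product-form residual.
    """
    if tuple(joint.variables) != THREE_TIME_VARS:
        raise ValidationError(
            f"expected variables {THREE_TIME_VARS}, got {joint.variables}"
        )
    markov = conditional_mutual_information(
        joint, ("S_3", "E_3"), ("S_1", "E_1"), ("S_2", "E_2")
    )
    product = conditional_mutual_information(joint, "S_3", "E_3", ("S_2", "E_2"))
    return {"markov_residual": markov, "product_form_residual": product}
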