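"""Boundary expansion: moving variables from the environment into the system.

The substrate is a :class:`FactoredProcess` — a set of finite-state units,
each updated synchronously by its own kernel conditioned on the *full*
previous state of all units.  Any split of the units into a system block
and an environment block is then an exact coupled process (no information
is lost by blocking, because the conditioning state is retained in full).

Given a partition into the current system S, a candidate block DeltaS to
internalise, and the remaining environment E', the measures after the move
relate to the measures before it by exact chain-rule algebra:

    nC'  = nC - I(S+; dS | S) + I(dS+; E' | dS, S+, S)
    A*'  = A* + I(dS+; S | S+) + I(S+ dS+; dS | S)
    A'   = A  + I(S+ dS+; dS | E') + I(dS+; S | E' dS S+)
         = A  + I(S+; dS | E') + I(dS+; S dS | E' S+)

(``+`` marks time n+1 blocks).  Every correction term on A and A* is a
conditional mutual information, hence non-negative: under expansion both
autonomy measures can only grow or stay constant.  They therefore cannot
by themselves locate a boundary; :func:`greedy_expand` adds a size
regulariser to make the growth terminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coupled_process import (
    CoupledProcess,
    Kernel,
    StateSpace,
    stationary_distribution,
)
from .discrete_info import (
    FiniteDistribution,
    JointTable,
    ValidationError,
    conditional_mutual_information as cmi,
    mutual_information as mi,
)
from .tolerances import TOL

__all__ = [
    "FactoredProcess",
    "Partition",
    "full_transition",
    "unit_lagged_joint",
    "coarse_grain",
    "block_measures",
    "expanded_measures",
    "expansion_identities",
    "greedy_expand",
]

#: default cap on unit count (product space stays <= 2^5 for binary units)
MAX_UNITS = 5


@dataclass
class FactoredProcess:
    """Synchronously updated units on a product state space.

    ``kernels[u]`` has shape ``(*sizes, sizes[u])``: the distribution of
    unit u's next state given the full current state.  One step of the
    product chain multiplies the unit kernels.
    """

    units: tuple[StateSpace, ...]
    kernels: tuple[np.ndarray, ...]

    def __post_init__(self):
        self.units = tuple(self.units)
        if not self.units:
            raise ValidationError("factored process needs at least one unit")
        if len(self.units) > MAX_UNITS:
            raise ValidationError(
                f"{len(self.units)} units exceeds the cap of {MAX_UNITS}"
            )
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            raise ValidationError("unit names are not unique")
        sizes = self.sizes
        kernels = []
        for i, (u, k) in enumerate(zip(self.units, self.kernels)):
            k = np.asarray(k, dtype=float)
            if k.shape != sizes + (u.n,):
                raise ValidationError(
                    f"kernel of unit {u.name!r} has shape {k.shape}, "
                    f"expected {sizes + (u.n,)}"
                )
            if np.any(k < 0.0) or np.max(np.abs(k.sum(axis=-1) - 1.0)) > TOL.prob_atol:
                raise ValidationError(f"kernel of unit {u.name!r} is not row-stochastic")
            kernels.append(k)
        self.kernels = tuple(kernels)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(u.n for u in self.units)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.sizes))


@dataclass(frozen=True)
class Partition:
    """Disjoint unit-index sets covering all units; ``system`` non-empty."""

    system: tuple[int, ...]
    delta: tuple[int, ...]
    environment: tuple[int, ...]

    def __post_init__(self):
        sys_, dl, env = (tuple(sorted(self.system)), tuple(sorted(self.delta)),
                         tuple(sorted(self.environment)))
        object.__setattr__(self, "system", sys_)
        object.__setattr__(self, "delta", dl)
        object.__setattr__(self, "environment", env)
        all_ = sys_ + dl + env
        if len(set(all_)) != len(all_):
            raise ValidationError("partition blocks overlap")
        if not sys_:
            raise ValidationError("system block is empty")

    def validate_against(self, fp: FactoredProcess) -> None:
        if set(self.system + self.delta + self.environment) != set(range(len(fp.units))):
            raise ValidationError("partition does not cover all units exactly")


def full_transition(fp: FactoredProcess) -> np.ndarray:
    """Row-stochastic matrix of the product chain; state index is the
    C-order ravel of per-unit indices (unit 0 slowest)."""
    N = fp.n_states
    T = np.ones((N, 1))
    for k in fp.kernels:
        T = (T[:, :, None] * k.reshape(N, 1, -1)).reshape(N, -1)
    return T


def _var(unit: StateSpace, time: str) -> str:
    return f"{unit.name}_{time}"


def unit_lagged_joint(
    fp: FactoredProcess, base: FiniteDistribution | str = "stationary"
) -> JointTable:
    """Lagged joint over all unit variables at times n and n+1.

    Variables are named ``<unit>_n`` and ``<unit>_next``; the time-n
    distribution is the stationary distribution of the product chain
    unless an explicit one is given.
    """
    T = full_transition(fp)
    if isinstance(base, str):
        if base != "stationary":
            raise ValidationError(f"unknown base {base!r}")
        pi = stationary_distribution(T).probs
    else:
        if len(base) != fp.n_states:
            raise ValidationError("base distribution size mismatch")
        pi = base.probs
    cells = (pi[:, None] * T).reshape(fp.sizes + fp.sizes)
    variables = [_var(u, "n") for u in fp.units] + [_var(u, "next") for u in fp.units]
    labels = {_var(u, t): u.labels for u in fp.units for t in ("n", "next")}
    return JointTable(variables, cells, labels)


def coarse_grain(fp: FactoredProcess, sys: Sequence[int]) -> CoupledProcess:
    """Block the product chain into a system (the named units) and an
    environment (the rest), as an exact :class:`CoupledProcess`.

    The blocking is exact because each unit kernel conditions on the full
    state, which the pair (system block, environment block) retains.
    """
    sys = tuple(sorted(set(sys)))
    env = tuple(i for i in range(len(fp.units)) if i not in sys)
    if not sys or not env:
        raise ValidationError("system must be a non-empty proper subset of units")
    if any(i < 0 or i >= len(fp.units) for i in sys):
        raise ValidationError(f"unit indices out of range: {sys}")

    def block_space(idx: tuple[int, ...], name: str) -> StateSpace:
        labels = [()]
        for i in idx:
            labels = [l + (x,) for l in labels for x in fp.units[i].labels]
        return StateSpace(name, tuple(labels))

    S = block_space(sys, "S")
    E = block_space(env, "E")
    sizes = fp.sizes
    nS, nE = S.n, E.n

    def block_kernel(block: tuple[int, ...], n_out: int) -> np.ndarray:
        # out[e, s, block'] for phi ordering; caller transposes as needed
        out = np.zeros((nE, nS, n_out))
        for ie in range(nE):
            e_multi = np.unravel_index(ie, tuple(sizes[i] for i in env)) if env else ()
            for is_ in range(nS):
                s_multi = np.unravel_index(is_, tuple(sizes[i] for i in sys))
                full = [0] * len(fp.units)
                for pos, i in enumerate(sys):
                    full[i] = int(s_multi[pos])
                for pos, i in enumerate(env):
                    full[i] = int(e_multi[pos])
                full_t = tuple(full)
                probs = np.ones(1)
                for i in block:
                    probs = np.outer(probs, fp.kernels[i][full_t]).ravel()
                out[ie, is_] = probs
        return out

    phi = Kernel((E, S), S, block_kernel(sys, nS))
    psi_es = block_kernel(env, nE)  # [e, s, e'] -> need [s, e, e']
    psi = Kernel((S, E), E, np.transpose(psi_es, (1, 0, 2)))
    return CoupledProcess(S, E, phi, psi)


def _vars(fp: FactoredProcess, idx: Sequence[int], time: str) -> tuple[str, ...]:
    return tuple(_var(fp.units[i], time) for i in idx)


def block_measures(
    fp: FactoredProcess,
    sys: Sequence[int],
    lj: JointTable | None = None,
) -> dict[str, float]:
    """A, A*, nC and Total_MI for the given system block, computed as
    block-marginals of the full-chain lagged joint (stationary base)."""
    sys = tuple(sorted(set(sys)))
    env = tuple(i for i in range(len(fp.units)) if i not in sys)
    if not sys:
        raise ValidationError("system block is empty")
    if lj is None:
        lj = unit_lagged_joint(fp)
    Sn, Sx = _vars(fp, sys, "n"), _vars(fp, sys, "next")
    En = _vars(fp, env, "n")
    a_star = mi(lj, Sx, Sn)
    if not env:  # whole process is the system: nothing left to condition on
        return {"A": a_star, "A_star": a_star, "nC": 0.0, "total_MI": a_star}
    return {
        "A": cmi(lj, Sx, Sn, En),
        "A_star": a_star,
        "nC": cmi(lj, Sx, En, Sn),
        "total_MI": mi(lj, Sx, Sn + En),
    }


def expanded_measures(fp: FactoredProcess, part: Partition) -> dict[str, float]:
    """Measures before and after internalising the ``delta`` block.

    Both are evaluated at the stationary distribution of the same full
    chain, so the before/after comparison isolates the boundary move.
    """
    part.validate_against(fp)
    lj = unit_lagged_joint(fp)
    before = block_measures(fp, part.system, lj)
    after = block_measures(fp, part.system + part.delta, lj)
    return {
        "A_before": before["A"], "A_after": after["A"],
        "A_star_before": before["A_star"], "A_star_after": after["A_star"],
        "nC_before": before["nC"], "nC_after": after["nC"],
    }


def expansion_identities(fp: FactoredProcess, part: Partition) -> dict[str, float]:
    """Residuals of the three boundary-expansion identities (and of the
    two printed forms of the A expansion against each other).

    Each side is computed independently by direct summation over the full
    lagged joint; all residuals are exact chain-rule identities and should
    vanish to rounding.
    """
    part.validate_against(fp)
    if not part.delta or not part.environment:
        raise ValidationError("identities need non-empty delta and environment blocks")
    lj = unit_lagged_joint(fp)
    Sn, Sx = _vars(fp, part.system, "n"), _vars(fp, part.system, "next")
    Dn, Dx = _vars(fp, part.delta, "n"), _vars(fp, part.delta, "next")
    En = _vars(fp, part.environment, "n")

    nC = cmi(lj, Sx, Dn + En, Sn)
    nC_exp = cmi(lj, Sx + Dx, En, Dn + Sn)
    nC_rhs = nC - cmi(lj, Sx, Dn, Sn) + cmi(lj, Dx, En, Dn + Sx + Sn)

    A_star = mi(lj, Sx, Sn)
    A_star_exp = mi(lj, Sx + Dx, Sn + Dn)
    A_star_rhs = A_star + cmi(lj, Dx, Sn, Sx) + cmi(lj, Sx + Dx, Dn, Sn)

    A = cmi(lj, Sx, Sn, Dn + En)
    A_exp = cmi(lj, Sx + Dx, Sn + Dn, En)
    A_rhs_1 = A + cmi(lj, Sx + Dx, Dn, En) + cmi(lj, Dx, Sn, En + Dn + Sx)
    A_rhs_2 = A + cmi(lj, Sx, Dn, En) + cmi(lj, Dx, Sn + Dn, En + Sx)

    return {
        "nC_identity": abs(nC_exp - nC_rhs),
        "A_star_identity": abs(A_star_exp - A_star_rhs),
        "A_identity_form1": abs(A_exp - A_rhs_1),
        "A_identity_form2": abs(A_exp - A_rhs_2),
        "A_forms_agree": abs(A_rhs_1 - A_rhs_2),
    }


def greedy_expand(
    fp: FactoredProcess,
    seed_sys: Sequence[int],
    measure: str = "A_star",
    lam: float = 0.0,
) -> list[dict[str, float]]:
    """Grow the system greedily under a size regulariser.

    At each step the single environment unit with the largest penalised
    gain ``delta(measure) - lam * log2(|unit alphabet|)`` is internalised;
    expansion stops when the best penalised gain falls below zero (beyond
    rounding: the threshold is -1e-9, so at ``lam = 0`` the non-negative
    monotone gains never stop the expansion early) or the environment is
    exhausted.  Ties break to the lowest unit index (an arbitrary,
    documented rule).

    Returns a trace: one record per accepted step with the internalised
    unit, the updated measures and the penalised gain.
    """
    if measure not in ("A", "A_star"):
        raise ValidationError(f"measure must be 'A' or 'A_star', got {measure!r}")
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    sys = tuple(sorted(set(seed_sys)))
    if not sys or any(i < 0 or i >= len(fp.units) for i in sys):
        raise ValidationError(f"invalid seed system {seed_sys!r}")
    lj = unit_lagged_joint(fp)
    trace: list[dict[str, float]] = []
    current = block_measures(fp, sys, lj)[measure]
    step = 0
    while True:
        env = [i for i in range(len(fp.units)) if i not in sys]
        if not env:
            break  # environment exhausted
        best = None
        for u in env:
            val = block_measures(fp, sys + (u,), lj)[measure]
            gain = (val - current) - lam * np.log2(fp.units[u].n)
            if best is None or gain > best[0] + 1e-12:
                best = (gain, u, val)
        gain, u, val = best
        if gain < -1e-9:
            break
        sys = tuple(sorted(sys + (u,)))
        current = val
        step += 1
        m = block_measures(fp, sys, lj)
        trace.append({
            "step": step, "unit": u, "penalized_gain": float(gain),
            "A": m["A"], "A_star": m["A_star"], "nC": m["nC"],
            "system": sys,
        })
    return trace
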