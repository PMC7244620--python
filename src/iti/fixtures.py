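"""Seeded generators of random model instances.

All kernels are *strictly positive* (every entry at least ``MIN_MASS``
before row normalisation), which makes the joint chain irreducible and
aperiodic and so guarantees a unique stationary distribution — the
regularity every downstream measure assumes by default.  Generators are
deterministic functions of their seed.
"""

from __future__ import annotations

import numpy as np

from .binary_example import BinaryModelParams
from .coupled_process import CoupledProcess, Kernel, StateSpace
from .discrete_info import JointTable, ValidationError
from .expansion import MAX_UNITS, FactoredProcess

__all__ = [
    "random_joint_table",
    "random_coupled_process",
    "random_binary_params",
    "random_factored_process",
    "generate_fixture",
]

#: minimum unnormalised cell/kernel mass (keeps chains strictly positive)
MIN_MASS = 1e-3

#: size caps for generated fixtures
MAX_STATES = 32


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_joint_table(
    shape: tuple[int, ...], seed: int, variables: list[str] | None = None
) -> JointTable:
    """A strictly positive random joint distribution of the given shape."""
    rng = _rng(seed)
    cells = rng.random(shape) + MIN_MASS
    cells /= cells.sum()
    if variables is None:
        variables = [f"X{i}" for i in range(len(shape))]
    return JointTable(variables, cells)


def _random_kernel(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    t = rng.random(shape) + MIN_MASS
    return t / t.sum(axis=-1, keepdims=True)


def random_coupled_process(n_sys: int, n_env: int, seed: int) -> CoupledProcess:
    """A coupled process with strictly positive random kernels."""
    if not (1 <= n_sys * n_env <= MAX_STATES):
        raise ValidationError(
            f"joint state count {n_sys * n_env} outside [1, {MAX_STATES}]"
        )
    rng = _rng(seed)
    S = StateSpace("S", tuple(range(n_sys)))
    E = StateSpace("E", tuple(range(n_env)))
    phi = Kernel((E, S), S, _random_kernel(rng, (n_env, n_sys, n_sys)))
    psi = Kernel((S, E), E, _random_kernel(rng, (n_sys, n_env, n_env)))
    return CoupledProcess(S, E, phi, psi)


def random_binary_params(seed: int, scale: float = 2.0) -> BinaryModelParams:
    """Random logistic couplings, uniform on [-scale, scale], zero biases."""
    rng = _rng(seed)
    a, b, g, ae, be, ge = rng.uniform(-scale, scale, size=6)
    return BinaryModelParams(
        alpha_S=a, beta_S=b, gamma_S=g, alpha_E=ae, beta_E=be, gamma_E=ge
    )


def random_factored_process(
    n_units: int, seed: int, sizes: tuple[int, ...] | None = None
) -> FactoredProcess:
    """A factored chain of ``n_units`` units (binary by default) with
    strictly positive random unit kernels."""
    if not (1 <= n_units <= MAX_UNITS):
        raise ValidationError(f"n_units must be in [1, {MAX_UNITS}]")
    if sizes is None:
        sizes = (2,) * n_units
    if len(sizes) != n_units:
        raise ValidationError("sizes must have one entry per unit")
    rng = _rng(seed)
    units = tuple(StateSpace(f"u{i}", tuple(range(k))) for i, k in enumerate(sizes))
    kernels = tuple(_random_kernel(rng, tuple(sizes) + (k,)) for k in sizes)
    return FactoredProcess(units, kernels)


def generate_fixture(kind: str, seed: int, **size_params):
    """Generate a random model by kind: ``random_kernels`` (pair process),
    ``binary_params`` or ``factored_chain``."""
    if kind == "random_kernels":
        return random_coupled_process(
            int(size_params.get("n_sys", 2)), int(size_params.get("n_env", 2)), seed
        )
    if kind == "binary_params":
        return random_binary_params(seed, float(size_params.get("scale", 2.0)))
    if kind == "factored_chain":
        return random_factored_process(int(size_params.get("n_units", 3)), seed)
    raise ValidationError(
        f"unknown fixture kind {kind!r}; "
        "use random_kernels, binary_params or factored_chain"
    )
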