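"""Exact Shannon information measures on finite discrete distributions.

Everything in this module is a plain finite sum computed in base-2
logarithms, so all results are in **bits**.  The conventions are the
standard ones:

* ``0 * log2(0) := 0`` — sums run over the support only;
* entropies and (conditional) mutual informations that come out negative
  by an amount smaller than the rounding tolerance are clamped to zero;
  anything more negative indicates a genuine inconsistency and raises.

The two containers, :class:`FiniteDistribution` for a single variable and
:class:`JointTable` for a named multivariate table, are the substrate for
every measure the rest of the package computes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .tolerances import TOL

__all__ = [
    "ValidationError",
    "InfoConsistencyError",
    "FiniteDistribution",
    "JointTable",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "conditional_mutual_information",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant (normalisation, sign,
    duplicate labels, unknown variable)."""


class InfoConsistencyError(ArithmeticError):
    """An information quantity came out negative beyond rounding tolerance."""


def _clamp_info(value: float, *, what: str = "information value") -> float:
    if value < -TOL.neg_clamp:
        raise InfoConsistencyError(
            f"{what} is {value!r} bits, below the -{TOL.neg_clamp} rounding floor"
        )
    return 0.0 if value < 0.0 else float(value) + 0.0  # normalises -0.0


def _entropy_of_cells(cells: np.ndarray) -> float:
    p = cells[cells > 0.0]
    if p.size == 0:
        return 0.0
    return _clamp_info(float(-(p * np.log2(p)).sum()), what="entropy")


class FiniteDistribution:
    """A probability distribution over a finite, ordered set of outcomes.

    Parameters
    ----------
    outcomes
        Ordered outcome labels; must be unique (hashable).
    probs
        Non-negative reals of the same length summing to one within
        :data:`~iti.tolerances.TOL` ``.prob_atol``.
    """

    __slots__ = ("outcomes", "probs")

    def __init__(self, outcomes: Iterable, probs: Iterable[float]):
        outcomes = tuple(outcomes)
        probs = np.asarray(list(probs), dtype=float)
        if probs.ndim != 1 or len(outcomes) != probs.size:
            raise ValidationError(
                f"outcomes ({len(outcomes)}) and probs ({probs.size}) differ in length"
            )
        if len(set(outcomes)) != len(outcomes):
            raise ValidationError("outcome labels are not unique")
        neg = np.flatnonzero(probs < 0.0)
        if neg.size:
            i = int(neg[0])
            raise ValidationError(
                f"negative probability {probs[i]!r} at index {i} (outcome {outcomes[i]!r})"
            )
        total = float(probs.sum())
        if abs(total - 1.0) > TOL.prob_atol:
            raise ValidationError(f"probabilities sum to {total!r}, not 1")
        self.outcomes = outcomes
        self.probs = probs

    def __len__(self) -> int:
        return len(self.outcomes)

    def __getitem__(self, outcome) -> float:
        return float(self.probs[self.outcomes.index(outcome)])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        pairs = ", ".join(f"{o!r}: {p:.6g}" for o, p in zip(self.outcomes, self.probs))
        return f"FiniteDistribution({{{pairs}}})"


class JointTable:
    """A joint distribution over named finite variables.

    The table is a dense ``numpy`` array with one axis per variable, in the
    order given by ``variables``.  Outcome labels per variable default to
    ``0..k-1`` and may be supplied via ``labels``.
    """

    def __init__(
        self,
        variables: Sequence[str],
        cells: np.ndarray,
        labels: dict[str, Sequence] | None = None,
    ):
        variables = tuple(variables)
        if len(set(variables)) != len(variables):
            raise ValidationError("variable names are not unique")
        cells = np.asarray(cells, dtype=float)
        if cells.ndim != len(variables):
            raise ValidationError(
                f"cells have {cells.ndim} axes but {len(variables)} variables were named"
            )
        if np.any(cells < 0.0):
            idx = tuple(int(i) for i in np.argwhere(cells < 0.0)[0])
            raise ValidationError(f"negative cell {cells[idx]!r} at index {idx}")
        total = float(cells.sum())
        if abs(total - 1.0) > TOL.prob_atol:
            raise ValidationError(f"cells sum to {total!r}, not 1")
        self.variables = variables
        self.cells = cells
        if labels is None:
            labels = {}
        self.labels = {
            v: tuple(labels.get(v, range(cells.shape[i])))
            for i, v in enumerate(variables)
        }
        for i, v in enumerate(variables):
            if len(self.labels[v]) != cells.shape[i]:
                raise ValidationError(
                    f"variable {v!r} has {cells.shape[i]} states but "
                    f"{len(self.labels[v])} labels"
                )
            if len(set(self.labels[v])) != len(self.labels[v]):
                raise ValidationError(f"labels of variable {v!r} are not unique")

    # -- structure ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.cells.shape

    def axes(self, vars: Sequence[str] | str) -> tuple[int, ...]:
        """Axis indices for the named variables (raises ``KeyError`` on
        unknown names)."""
        if isinstance(vars, str):
            vars = (vars,)
        out = []
        for v in vars:
            if v not in self.variables:
                raise KeyError(f"unknown variable {v!r}; have {self.variables}")
            out.append(self.variables.index(v))
        return tuple(out)

    def marginal_cells(self, vars: Sequence[str] | str) -> np.ndarray:
        """Marginal probability array over ``vars``, axes in the requested
        order."""
        keep = self.axes(vars)
        if not keep:
            raise ValidationError("marginal over an empty variable set")
        drop = tuple(a for a in range(self.cells.ndim) if a not in keep)
        m = self.cells.sum(axis=drop) if drop else self.cells
        # remaining axes are in table order; permute to requested order
        remaining = [a for a in range(self.cells.ndim) if a in keep]
        perm = [remaining.index(a) for a in keep]
        return np.transpose(m, perm)

    def marginal(self, vars: Sequence[str] | str) -> "JointTable":
        if isinstance(vars, str):
            vars = (vars,)
        return JointTable(
            vars, self.marginal_cells(vars), {v: self.labels[v] for v in vars}
        )

    def distribution(self, var: str) -> FiniteDistribution:
        """Single-variable marginal as a :class:`FiniteDistribution`."""
        return FiniteDistribution(self.labels[var], self.marginal_cells(var))

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        """Long-format TSV: one row per cell (all cells, including zeros),
        columns are the variable labels followed by the probability.

        Probabilities are written with ``repr`` so a read/write round trip
        reproduces the text exactly.
        """
        lines = ["\t".join([*self.variables, "p"])]
        for idx in np.ndindex(*self.shape):
            row = [str(self.labels[v][i]) for v, i in zip(self.variables, idx)]
            row.append(repr(float(self.cells[idx])))
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "JointTable":
        """Parse the long-format TSV written by :meth:`to_tsv`.

        Outcome labels are read back as strings, ordered by first
        appearance per variable.
        """
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise ValidationError("empty joint-table TSV")
        header = lines[0].split("\t")
        if header[-1] != "p":
            raise ValidationError("last TSV column must be 'p'")
        variables = header[:-1]
        labels: dict[str, list[str]] = {v: [] for v in variables}
        rows = []
        for ln_no, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            if len(parts) != len(header):
                raise ValidationError(f"line {ln_no}: expected {len(header)} columns")
            for v, val in zip(variables, parts):
                if val not in labels[v]:
                    labels[v].append(val)
            rows.append((parts[:-1], float(parts[-1])))
        shape = tuple(len(labels[v]) for v in variables)
        cells = np.zeros(shape)
        for vals, p in rows:
            idx = tuple(labels[v].index(val) for v, val in zip(variables, vals))
            cells[idx] = p
        return cls(variables, cells, labels)


# -- measures --------------------------------------------------------------


def entropy(dist: FiniteDistribution) -> float:
    """Shannon entropy ``H = -sum p log2 p`` in bits."""
    return _entropy_of_cells(dist.probs)


def joint_entropy(joint: JointTable, vars: Sequence[str] | str) -> float:
    """Entropy of the marginal of ``joint`` over ``vars``, in bits."""
    return _entropy_of_cells(joint.marginal_cells(vars))


def _as_tuple(x: Sequence[str] | str) -> tuple[str, ...]:
    return (x,) if isinstance(x, str) else tuple(x)


def _check_disjoint(*groups: tuple[str, ...]) -> None:
    seen: set[str] = set()
    for g in groups:
        overlap = seen.intersection(g)
        if overlap:
            raise ValidationError(f"variable groups overlap on {sorted(overlap)}")
        seen.update(g)


def conditional_entropy(
    joint: JointTable, X: Sequence[str] | str, given: Sequence[str] | str
) -> float:
    """``H(X | given) = H(X, given) - H(given)`` in bits."""
    X, Z = _as_tuple(X), _as_tuple(given)
    _check_disjoint(X, Z)
    return _clamp_info(
        joint_entropy(joint, X + Z) - joint_entropy(joint, Z),
        what="conditional entropy",
    )


def mutual_information(
    joint: JointTable, X: Sequence[str] | str, Y: Sequence[str] | str
) -> float:
    """``I(X;Y) = H(X) + H(Y) - H(X,Y)`` in bits; symmetric and >= 0."""
    X, Y = _as_tuple(X), _as_tuple(Y)
    _check_disjoint(X, Y)
    value = (
        joint_entropy(joint, X) + joint_entropy(joint, Y) - joint_entropy(joint, X + Y)
    )
    return _clamp_info(value, what="mutual information")


def conditional_mutual_information(
    joint: JointTable,
    X: Sequence[str] | str,
    Y: Sequence[str] | str,
    Z: Sequence[str] | str,
) -> float:
    """``I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)`` in bits.

    With an empty ``Z`` this reduces to :func:`mutual_information`.
    """
    X, Y, Z = _as_tuple(X), _as_tuple(Y), _as_tuple(Z)
    if not Z:
        return mutual_information(joint, X, Y)
    _check_disjoint(X, Y, Z)
    value = (
        joint_entropy(joint, X + Z)
        + joint_entropy(joint, Y + Z)
        - joint_entropy(joint, X + Y + Z)
        - joint_entropy(joint, Z)
    )
    return _clamp_info(value, what="conditional mutual information")
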