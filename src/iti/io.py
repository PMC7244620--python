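"""Model and trajectory file formats.

Models are structured YAML documents (schema ``iti-model/1``) of three
kinds:

* ``pair`` — a coupled process: two state spaces plus the phi and psi
  kernel tables (row-major over the conditioning tuple, environment index
  slowest for phi, system index slowest for psi) and an optional ``mu``;
* ``factored`` — a list of units, each with a kernel conditioned on the
  full product state (rows in C order over unit indices);
* ``binary`` — the eight couplings of the two-spin logistic example.

Trajectories are TSV: one time step per row, whitespace/tab-separated
0-based integer state codes, one column per variable; ``#`` lines are
comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .binary_example import BinaryModelParams
from .coupled_process import CoupledProcess, FiniteDistribution, Kernel, StateSpace
from .discrete_info import ValidationError
from .expansion import FactoredProcess

__all__ = ["load_model", "save_model", "load_trajectory", "save_trajectory"]

SCHEMA = "iti-model/1"

Model = Union[CoupledProcess, FactoredProcess, BinaryModelParams]


class ModelFormatError(ValidationError):
    """A model file fails schema validation; the message names the
    offending key (parse errors carry the YAML line number)."""


def _require(doc: dict, key: str, ctx: str):
    if key not in doc:
        raise ModelFormatError(f"{ctx}: missing required key {key!r}")
    return doc[key]


def _state_space(doc, ctx: str) -> StateSpace:
    if not isinstance(doc, dict):
        raise ModelFormatError(f"{ctx}: expected a mapping with name/labels")
    labels = [tuple(l) if isinstance(l, list) else l
              for l in _require(doc, "labels", ctx)]
    return StateSpace(str(_require(doc, "name", ctx)), tuple(labels))


def load_model(path: str | Path) -> Model:
    """Load and validate a model file; the return type depends on its
    ``kind``."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # YAML errors carry line/column marks
        raise ModelFormatError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelFormatError(f"{path}: model file must be a YAML mapping")
    if doc.get("schema") != SCHEMA:
        raise ModelFormatError(
            f"{path}: key 'schema' must be {SCHEMA!r}, got {doc.get('schema')!r}"
        )
    kind = _require(doc, "kind", str(path))
    if kind == "pair":
        return _load_pair(doc, str(path))
    if kind == "factored":
        return _load_factored(doc, str(path))
    if kind == "binary":
        params = _require(doc, "params", str(path))
        if not isinstance(params, dict):
            raise ModelFormatError(f"{path}: key 'params' must be a mapping")
        known = set(BinaryModelParams.__dataclass_fields__)
        unknown = set(params) - known
        if unknown:
            raise ModelFormatError(f"{path}: unknown coupling keys {sorted(unknown)}")
        return BinaryModelParams(**{k: float(v) for k, v in params.items()})
    raise ModelFormatError(f"{path}: unknown kind {kind!r}")


def _load_pair(doc: dict, ctx: str) -> CoupledProcess:
    S = _state_space(_require(doc, "system", ctx), f"{ctx}: system")
    E = _state_space(_require(doc, "environment", ctx), f"{ctx}: environment")
    phi = np.asarray(_require(doc, "phi", ctx), dtype=float)
    psi = np.asarray(_require(doc, "psi", ctx), dtype=float)
    try:
        phi_k = Kernel((E, S), S, phi.reshape(E.n, S.n, S.n))
        psi_k = Kernel((S, E), E, psi.reshape(S.n, E.n, E.n))
    except (ValueError, ValidationError) as exc:
        raise ModelFormatError(f"{ctx}: kernel tables invalid: {exc}") from exc
    mu = None
    if doc.get("mu") is not None:
        probs = np.asarray(doc["mu"], dtype=float)
        labels = tuple((s, e) for e in E.labels for s in S.labels)
        try:
            mu = FiniteDistribution(labels, probs)
        except ValidationError as exc:
            raise ModelFormatError(f"{ctx}: key 'mu' invalid: {exc}") from exc
    return CoupledProcess(S, E, phi_k, psi_k, mu)


def _load_factored(doc: dict, ctx: str) -> FactoredProcess:
    units = [_state_space(u, f"{ctx}: units[{i}]")
             for i, u in enumerate(_require(doc, "units", ctx))]
    sizes = tuple(u.n for u in units)
    kernels = []
    raw = _require(doc, "kernels", ctx)
    if len(raw) != len(units):
        raise ModelFormatError(
            f"{ctx}: {len(raw)} kernels for {len(units)} units"
        )
    for i, (u, k) in enumerate(zip(units, raw)):
        try:
            kernels.append(np.asarray(k, dtype=float).reshape(sizes + (u.n,)))
        except ValueError as exc:
            raise ModelFormatError(f"{ctx}: kernels[{i}] has wrong size: {exc}") from exc
    return FactoredProcess(tuple(units), tuple(kernels))


def _dump_space(sp: StateSpace) -> dict:
    return {"name": sp.name,
            "labels": [list(l) if isinstance(l, tuple) else l for l in sp.labels]}


def save_model(model: Model, path: str | Path) -> None:
    """Write a model as schema-validated YAML (deterministic key order)."""
    if isinstance(model, CoupledProcess):
        doc = {
            "schema": SCHEMA,
            "kind": "pair",
            "system": _dump_space(model.S),
            "environment": _dump_space(model.E),
            "phi": model.phi.table.reshape(model.E.n * model.S.n, model.S.n).tolist(),
            "psi": model.psi.table.reshape(model.S.n * model.E.n, model.E.n).tolist(),
            "mu": None if model.mu is None else model.mu.probs.tolist(),
        }
    elif isinstance(model, FactoredProcess):
        doc = {
            "schema": SCHEMA,
            "kind": "factored",
            "units": [_dump_space(u) for u in model.units],
            "kernels": [k.reshape(model.n_states, u.n).tolist()
                        for u, k in zip(model.units, model.kernels)],
        }
    elif isinstance(model, BinaryModelParams):
        doc = {
            "schema": SCHEMA,
            "kind": "binary",
            "params": {k: float(getattr(model, k))
                       for k in BinaryModelParams.__dataclass_fields__},
        }
    else:
        raise ValidationError(f"cannot serialise model of type {type(model).__name__}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_trajectory(path: str | Path) -> np.ndarray:
    """Read a trajectory TSV into an integer array (time, variables)."""
    rows = []
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rows.append([int(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln_no}: non-integer state code") from exc
        if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
            raise ValidationError(f"{path}:{ln_no}: ragged row")
    if not rows:
        raise ValidationError(f"{path}: empty trajectory")
    return np.asarray(rows, dtype=np.int64)


def save_trajectory(traj: np.ndarray, path: str | Path) -> None:
    lines = ["\t".join(str(int(x)) for x in row) for row in np.asarray(traj)]
    Path(path).write_text("\n".join(lines) + "\n")
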