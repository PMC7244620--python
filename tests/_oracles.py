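"""Brute-force reference implementations used only to check the package.

Everything here works by explicit summation over raw probability arrays
with plain Python loops, independently of the package's vectorised code
paths.
"""

from __future__ import annotations

import math

import numpy as np


def naive_entropy(probs) -> float:
    h = 0.0
    for p in np.asarray(probs).ravel():
        if p > 0.0:
            h -= p * math.log2(p)
    return h


def _group_marginal(cells: np.ndarray, axes: tuple[int, ...]) -> dict:
    """Marginal over the given axes as a dict keyed by index tuples."""
    out: dict[tuple, float] = {}
    for idx in np.ndindex(*cells.shape):
        key = tuple(idx[a] for a in axes)
        out[key] = out.get(key, 0.0) + float(cells[idx])
    return out


def naive_cmi(cells: np.ndarray, X: tuple[int, ...], Y: tuple[int, ...],
              Z: tuple[int, ...] = ()) -> float:
    """I(X;Y|Z) by direct summation of p log2(p(x,y|z)/(p(x|z)p(y|z)))."""
    pxyz = _group_marginal(cells, X + Y + Z)
    pxz = _group_marginal(cells, X + Z)
    pyz = _group_marginal(cells, Y + Z)
    pz = _group_marginal(cells, Z) if Z else {(): 1.0}
    total = 0.0
    for key, p in pxyz.items():
        if p <= 0.0:
            continue
        x, y, z = key[: len(X)], key[len(X): len(X) + len(Y)], key[len(X) + len(Y):]
        total += p * math.log2(p * pz[z] / (pxz[x + z] * pyz[y + z]))
    return total


def naive_mi(cells: np.ndarray, X: tuple[int, ...], Y: tuple[int, ...]) -> float:
    return naive_cmi(cells, X, Y, ())


def naive_imin_pid(cells: np.ndarray) -> dict[str, float]:
    """Williams-Beer decomposition of a (target, src1, src2) array by
    explicit specific-information minima."""
    nt, n1, n2 = cells.shape
    p_t = [sum(cells[t, a, b] for a in range(n1) for b in range(n2)) for t in range(nt)]
    si = 0.0
    for t in range(nt):
        if p_t[t] <= 0.0:
            continue
        specs = []
        for src in (1, 2):
            spec = 0.0
            n_a = n1 if src == 1 else n2
            for a in range(n_a):
                if src == 1:
                    p_ta = sum(cells[t, a, b] for b in range(n2))
                    p_a = sum(cells[tt, a, b] for tt in range(nt) for b in range(n2))
                else:
                    p_ta = sum(cells[t, b, a] for b in range(n1))
                    p_a = sum(cells[tt, b, a] for tt in range(nt) for b in range(n1))
                if p_ta > 0.0:
                    spec += (p_ta / p_t[t]) * math.log2(p_ta / (p_a * p_t[t]))
            specs.append(spec)
        si += p_t[t] * min(specs)
    i_ts = naive_mi(cells, (0,), (1,))
    i_te = naive_mi(cells, (0,), (2,))
    i_tot = naive_mi(cells, (0,), (1, 2))
    ui_sys = i_ts - si
    ui_env = i_te - si
    return {
        "si": si,
        "ui_sys": ui_sys,
        "ui_env": ui_env,
        "ci": i_tot - si - ui_sys - ui_env,
    }


def naive_stationary(T: np.ndarray) -> np.ndarray:
    """Fixed point via eigen-decomposition (a different route from the
    package's null-space + power-iteration solver)."""
    w, v = np.linalg.eig(np.asarray(T, dtype=float).T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()
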