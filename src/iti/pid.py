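"""Partial information decomposition (PID) for one target and two sources.

The mutual information ``I(T; X, Y)`` is split into four non-negative
parts — shared (redundant) information SI, complementary (synergistic)
information CI, and the unique informations of each source — tied to the
plain (conditional) mutual informations by the four consistency equations

    I(T;X)   = SI + UI_x        I(T;Y)   = SI + UI_y
    I(T;X|Y) = CI + UI_x        I(T;Y|X) = CI + UI_y

which also imply ``I(T;X,Y) = SI + CI + UI_x + UI_y``.

How to split is famously under-determined; the default (and currently only
built-in) measure is the Williams-Beer ``I_min``: redundancy is the
expectation over target states of the minimum *specific information* the
two sources each carry about that state.  The combination ``SI - CI``
(co-information) is measure-independent, and all headline individuality
measures elsewhere in this package are built from plain MI/CMI only, so
the choice here affects only the four-term report itself.  Alternative
measures can be registered as additional strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discrete_info import (
    JointTable,
    ValidationError,
    conditional_mutual_information,
    mutual_information,
)
from .tolerances import TOL

__all__ = ["PIDResult", "pid_decompose", "pid_consistency", "PID_METHODS"]


@dataclass(frozen=True)
class PIDResult:
    """The four partial-information terms, in bits."""

    si: float
    ci: float
    ui_sys: float  # unique to source 1 with respect to source 2
    ui_env: float  # unique to source 2 with respect to source 1
    method: str

    def total(self) -> float:
        return self.si + self.ci + self.ui_sys + self.ui_env


def _imin_redundancy(cells: np.ndarray) -> float:
    """Williams-Beer redundancy over a (target, src1, src2) cell array.

    For each target state t with p(t) > 0, the specific information of a
    source A is ``sum_a p(a|t) log2( p(t|a) / p(t) )``; redundancy is the
    p(t)-weighted minimum of the two sources' specific informations.
    """
    p_t = cells.sum(axis=(1, 2))
    red = 0.0
    for t in range(cells.shape[0]):
        if p_t[t] <= 0.0:
            continue  # zero-probability target states carry zero weight
        specific = []
        for drop in (2, 1):  # marginalise out the other source
            p_ta = cells[t].sum(axis=drop - 1)  # p(t, a)
            p_a = cells.sum(axis=(0, drop))  # p(a)
            mask = p_ta > 0.0
            spec = float(
                np.sum(
                    (p_ta[mask] / p_t[t])
                    * np.log2(p_ta[mask] / (p_a[mask] * p_t[t]))
                )
            )
            specific.append(spec)
        red += p_t[t] * min(specific)
    return red


#: registered decomposition strategies: name -> redundancy functional on a
#: (target, src1, src2) probability array
PID_METHODS = {"imin": _imin_redundancy}


def pid_decompose(
    joint: JointTable,
    target: str,
    source1: str,
    source2: str,
    method: str = "imin",
) -> PIDResult:
    """Decompose ``I(target; source1, source2)`` into SI, CI and the two
    unique terms.

    The redundancy SI comes from the selected strategy; CI and the unique
    terms then follow from the consistency equations.
    """
    if method not in PID_METHODS:
        raise ValidationError(
            f"unsupported PID method {method!r}; supported: {sorted(PID_METHODS)}"
        )
    m = joint.marginal((target, source1, source2))
    si = PID_METHODS[method](m.cells)
    i_ts = mutual_information(m, target, source1)
    i_te = mutual_information(m, target, source2)
    i_total = mutual_information(m, target, (source1, source2))
    ui_sys = i_ts - si
    ui_env = i_te - si
    ci = i_total - si - ui_sys - ui_env
    terms = {"si": si, "ci": ci, "ui_sys": ui_sys, "ui_env": ui_env}
    for name, v in terms.items():
        if v < -TOL.neg_clamp:
            raise ValidationError(f"PID term {name} is negative ({v!r} bits)")
        terms[name] = max(0.0, v)
    return PIDResult(method=method, **terms)


def pid_consistency(
    result: PIDResult,
    joint: JointTable,
    target: str,
    source1: str,
    source2: str,
) -> dict[str, float]:
    """Absolute residuals of the four consistency equations linking the
    decomposition to independently computed MI/CMI values."""
    i_ts = mutual_information(joint, target, source1)
    i_te = mutual_information(joint, target, source2)
    i_te_s = conditional_mutual_information(joint, target, source2, source1)
    i_ts_e = conditional_mutual_information(joint, target, source1, source2)
    return {
        "pairwise_sys": abs(i_ts - result.si - result.ui_sys),
        "conditional_env": abs(i_te_s - result.ci - result.ui_env),
        "pairwise_env": abs(i_te - result.si - result.ui_env),
        "conditional_sys": abs(i_ts_e - result.ci - result.ui_sys),
    }
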