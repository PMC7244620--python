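"""Numerical tolerances used throughout the package.

All probability and information quantities here are exact sums over finite
tables, so the only error sources are floating-point rounding and iterative
linear algebra.  The defaults below are deliberately conservative; they can
be adjusted on the module-level :data:`TOL` instance, which every validation
routine consults.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Tolerances:
    #: absolute tolerance for probability normalisation checks
    prob_atol: float = 1e-9
    #: magnitude below which a negative information value is treated as a
    #: rounding artefact and clamped to zero; larger negatives raise
    neg_clamp: float = 1e-9
    #: residual bound for information-theoretic identities (chain rule,
    #: decomposition consistency, boundary-expansion algebra)
    identity_atol: float = 1e-8
    #: infinity-norm residual required of a stationary distribution
    stationary_atol: float = 1e-10
    #: entrywise tolerance for transition-matrix comparisons
    matrix_atol: float = 1e-12


#: package-wide default tolerances
TOL = Tolerances()
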