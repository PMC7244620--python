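"""The individuality measures of the system-environment decomposition.

The predictability of the next system state from the current joint state,
``Total_MI = I(S_{n+1}; S_n, E_n)``, admits two chain-rule allocations:

    Total_MI = I(S_{n+1}; S_n)       + I(S_{n+1}; E_n | S_n)   = A* + nC
    Total_MI = I(S_{n+1}; E_n)       + I(S_{n+1}; S_n | E_n)   = ... + A

* **A\\*** (organismal individuality, autonomy): all regularity between
  successive system states is credited to the system itself.
* **A** (colonial individuality): the environment is credited first; A is
  the system-to-future information that remains.
* **nC** (environmental determination): new information flowing from the
  environment into the system; ``nC = 0`` is *informational closure*.
* **NTIC** (environmental coding): ``A* - A``, equal to the shared-minus-
  synergistic balance ``SI - CI`` of any consistent partial information
  decomposition (it is the three-variable co-information, so it does not
  depend on the PID chosen).  It may be negative.

All measures are evaluated on a :class:`~iti.coupled_process.LaggedJoint`,
by default taken at the stationary distribution of the joint chain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coupled_process import CoupledProcess, FiniteDistribution, LaggedJoint, lagged_joint
from .discrete_info import (
    conditional_mutual_information,
    entropy,
    mutual_information,
)

__all__ = [
    "IndividualityProfile",
    "organismal",
    "colonial",
    "environmental_determination",
    "ntic",
    "total_predictive_information",
    "profile",
    "profile_from_lagged",
]


def organismal(lj: LaggedJoint) -> float:
    """Organismal individuality ``A* = I(S_{n+1}; S_n)`` in bits."""
    return mutual_information(lj.joint, "S_next", "S_n")


def colonial(lj: LaggedJoint) -> float:
    """Colonial individuality ``A = I(S_{n+1}; S_n | E_n)`` in bits."""
    return conditional_mutual_information(lj.joint, "S_next", "S_n", "E_n")


def environmental_determination(lj: LaggedJoint) -> float:
    """Environmental determination ``nC = I(S_{n+1}; E_n | S_n)`` in bits;
    zero means the system is informationally closed."""
    return conditional_mutual_information(lj.joint, "S_next", "E_n", "S_n")


def ntic(lj: LaggedJoint) -> float:
    """Environmental coding ``NTIC = SI - CI = A* - A`` in bits.

    Computed PID-free as the co-information
    ``I(S_{n+1}; S_n) - I(S_{n+1}; S_n | E_n)``; may be negative (net
    synergy between system and environment).
    """
    return organismal(lj) - colonial(lj)


def total_predictive_information(lj: LaggedJoint) -> float:
    """``Total_MI = I(S_{n+1}; S_n, E_n)`` in bits."""
    return mutual_information(lj.joint, "S_next", ("S_n", "E_n"))


@dataclass(frozen=True)
class IndividualityProfile:
    """The panel quantities of the parameter sweeps, all in bits.

    ``two_step_MI`` is the alternative reading of "mutual information
    between two time steps", ``I((S,E)_{n+1}; (S,E)_n)``; the headline
    ``total_MI`` is the predictability expression ``I(S_{n+1}; S_n, E_n)``.
    """

    A: float
    A_star: float
    nC: float
    NTIC: float
    total_MI: float
    H_sys: float
    base: str
    two_step_MI: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Total_MI": self.total_MI,
            "H_sys": self.H_sys,
            "A": self.A,
            "A_star": self.A_star,
            "nC": self.nC,
            "NTIC": self.NTIC,
        }


def profile_from_lagged(lj: LaggedJoint) -> IndividualityProfile:
    """Compute the full profile from an existing lagged joint."""
    a_star = organismal(lj)
    a = colonial(lj)
    nc = environmental_determination(lj)
    return IndividualityProfile(
        A=a,
        A_star=a_star,
        nC=nc,
        NTIC=a_star - a,
        total_MI=total_predictive_information(lj),
        H_sys=entropy(lj.joint.distribution("S_n")),
        base=lj.base_label,
        two_step_MI=mutual_information(
            lj.joint, ("S_next", "E_next"), ("S_n", "E_n")
        ),
    )


def profile(
    proc: CoupledProcess, base: str | FiniteDistribution = "stationary"
) -> IndividualityProfile:
    """Individuality profile of a coupled process at the given time-n
    distribution (default: stationary)."""
    return profile_from_lagged(lagged_joint(proc, base))
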