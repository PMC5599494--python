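"""Thermodynamics of membrane fluidity and molecular turnover.

Each triangle carries a fixed number ``m_u`` of membrane molecules, so the
vesicle holds ``M_t = N_t * m_u`` molecules and the intracellular reservoir
the remainder ``M_r = M_tt - M_t`` of a conserved total.  Flips exchange no
molecules and sample a canonical ensemble: an edge is attempted at rate
``1/tau_f`` and accepted with the Metropolis factor ``min(1, exp(-dU/kBT))``.
Split/merge moves exchange ``2 m_u`` molecules with the reservoir and sample
a grand-canonical ensemble: attempted at rate ``1/tau_t`` and accepted with
``min(1, exp(-(dE -/+ 2 m_u mu_r)/kBT))`` (upper sign for splits).

The turnover cost ``dE = eps_t * (1 -/+ strain/gamma_t)`` encodes
mechanosensing: stretching beyond the critical strain ``gamma_t`` makes
splitting energetically free, compression favors merging.  The reservoir
chemical potential derives from a cubic free energy
``G_r = kBT |M_t - M_eq|^3 / (12 m_u M_inst^2)`` whose stiffness ``M_inst``
sets how strongly the vesicle molecule number is pinned to ``M_eq``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "ReservoirState",
    "TurnoverParams",
    "chemical_potential",
    "turnover_cost",
    "flip_acceptance",
    "turnover_acceptance",
    "attempt_probability",
]


@dataclass
class ReservoirState:
    """Molecule bookkeeping for one vesicle coupled to a reservoir.

    ``M_t`` is the current vesicle content (``N_t * m_u``), ``M_tt`` the
    conserved cell total, ``M_eq`` the equilibrium vesicle content and
    ``M_inst`` the instability scale of its fluctuations.
    """

    M_t: int
    M_eq: float = 1.0e3
    M_inst: float = 10.0
    m_u: int = 1
    M_tt: int | None = None

    def __post_init__(self):
        if self.M_tt is None:
            # reservoir and vesicle of comparable size: M_r ~ M_t at equilibrium
            self.M_tt = int(round(2 * self.M_eq))
        if self.M_inst <= 0:
            raise ValueError("M_inst must be positive")
        if self.m_u <= 0:
            raise ValueError("m_u must be a positive integer")

    @property
    def M_r(self) -> int:
        return self.M_tt - self.M_t

    @property
    def M_req(self) -> float:
        return self.M_tt - self.M_eq

    def transfer_to_vesicle(self, n: int) -> None:
        """Move ``n`` molecules reservoir -> vesicle (negative: back)."""
        self.M_t += n

    def copy(self) -> "ReservoirState":
        return replace(self)


@dataclass(frozen=True)
class TurnoverParams:
    """Timescales and energetics of the stochastic remodeling moves.

    ``tau_f``/``tau_t`` are the per-edge characteristic times of fluidity
    and turnover (``tau_t = inf`` disables turnover); ``eps_t`` is the
    energetic cost of one turnover event and ``gamma_t`` the critical
    area strain at which that cost is annulled.
    """

    tau_f: float = 1.0e-2
    tau_t: float = math.inf
    eps_t: float = 1.0e-1
    gamma_t: float = 5.0e-2

    def __post_init__(self):
        if self.tau_f <= 0:
            raise ValueError("tau_f must be positive")
        if self.tau_t <= 0:
            raise ValueError("tau_t must be positive (may be inf)")
        if self.gamma_t <= 0:
            raise ValueError("gamma_t must be positive")
        if math.isfinite(self.tau_t) and self.tau_f >= self.tau_t:
            warnings.warn(
                "tau_f >= tau_t: fluidity is not fast compared to turnover, "
                "violating the timescale separation the model assumes",
                stacklevel=2,
            )

    def replace(self, **kw) -> "TurnoverParams":
        return replace(self, **kw)


def chemical_potential(reservoir: ReservoirState, kBT: float = 1.0) -> float:
    """Reservoir chemical potential ``mu_r = -dG_r/dM_t``.

    With the cubic reservoir free energy this is
    ``-(kBT / (4 m_u M_inst^2)) * (M_t - M_eq) * |M_t - M_eq|``: positive
    when the vesicle is depleted (drives splits), negative when overfull
    (drives merges), zero at equilibrium.
    """
    x = reservoir.M_t - reservoir.M_eq
    return -kBT / (4.0 * reservoir.m_u * reservoir.M_inst**2) * x * abs(x)


def turnover_cost(
    mean_area: float,
    a_eq: float,
    eps_t: float,
    gamma_t: float,
    direction: str,
) -> float:
    """Strain-dependent energetic cost ``dE`` of one split or merge.

    ``mean_area`` is the average area of the two faces adjacent to the
    candidate edge.  The cost falls to zero for splits at strain
    ``+gamma_t`` and for merges at ``-gamma_t``; beyond, it turns negative
    and the move becomes favorable.
    """
    if mean_area <= 0:
        raise ValueError("mean_area must be positive")
    strain = mean_area / a_eq - 1.0
    if direction == "split":
        return eps_t * (1.0 - strain / gamma_t)
    if direction == "merge":
        return eps_t * (1.0 + strain / gamma_t)
    raise ValueError(f"direction must be 'split' or 'merge', got {direction!r}")


def flip_acceptance(delta_U: float, kBT: float = 1.0) -> float:
    """Metropolis acceptance for an attempted edge flip."""
    if delta_U <= 0:
        return 1.0
    return math.exp(-delta_U / kBT)


def turnover_acceptance(
    delta_E: float,
    mu_r: float,
    m_u: int,
    direction: str,
    kBT: float = 1.0,
) -> float:
    """Grand-canonical acceptance for an attempted split or merge.

    The exponent is ``delta_E - 2 m_u mu_r`` for a split (the vesicle gains
    two triangles' worth of molecules) and ``delta_E + 2 m_u mu_r`` for a
    merge, capped at probability one.
    """
    if direction == "split":
        x = delta_E - 2.0 * m_u * mu_r
    elif direction == "merge":
        x = delta_E + 2.0 * m_u * mu_r
    else:
        raise ValueError(f"direction must be 'split' or 'merge', got {direction!r}")
    if x <= 0:
        return 1.0
    return math.exp(-x / kBT)


def attempt_probability(dt: float, tau: float) -> float:
    """Per-step Bernoulli attempt probability ``dt/tau`` (0 for tau = inf)."""
    if not math.isfinite(tau):
        return 0.0
    if dt > tau:
        raise ValueError("integration step exceeds the attempt timescale")
    return dt / tau
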