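"""Stage-structured biomass approximation of the cohort model.

The population is collapsed to total biomass per life stage: ``n >= 1``
juvenile stages ``J_1..J_n``, an adult stage ``A`` and a reproductive
storage pool ``B``, coupled to the shared resource ``R``.  Cohort-by-cohort
maturation is replaced by a size-independent per-capita maturation rate
``gamma`` chosen so that, at fixed resource density, the expected lifetime
biomass a newborn delivers to the adult stage matches the cohort model
(see :func:`seasonpop.bioenergetics.maturation_rate`).

With one juvenile stage the time a unit of newborn biomass needs to mature
is exponentially distributed; with ``n`` identical stages it is gamma
(Erlang) distributed, which concentrates maturation away from birth and
brings the dynamics closer to the cohort model.  All juvenile stages are
energetically equivalent: they share ``nu_J``, ``d_J`` and the ``2 - q``
foraging weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bioenergetics import (
    ResourceParams,
    SpeciesParams,
    functional_response,
    maturation_rate,
    net_production,
    positive_part,
    stage_mortality,
    stage_size_ratio,
)

__all__ = ["StageState", "stage_rhs", "apply_reproduction_stage"]


@dataclass
class StageState:
    """Biomass per stage plus resource; ``n`` juvenile stages in ``J``."""

    J: np.ndarray  # juvenile biomass per stage (mg L^-1), length n
    A: float  # adult biomass (mg L^-1)
    B: float  # reproductive-storage biomass (mg L^-1)
    R: float  # resource density (mg L^-1)
    t: float = 0.0

    def __post_init__(self) -> None:
        self.J = np.atleast_1d(np.asarray(self.J, float))

    @property
    def n_stages(self) -> int:
        return self.J.size

    @property
    def J_total(self) -> float:
        return float(self.J.sum())

    def copy(self) -> "StageState":
        return StageState(J=self.J.copy(), A=self.A, B=self.B, R=self.R, t=self.t)


def stage_rhs(state: StageState, sp: SpeciesParams, rp: ResourceParams):
    """Time derivatives (dJ, dA, dB, dR) of the stage-structured system.

    Each juvenile stage gains net production on its own biomass and loses
    biomass to mortality and to maturation into the next stage (the last
    into A) at the shared rate ``gamma`` evaluated with the per-stage size
    ratio ``z**(1/n)``.  Adults route net production into the storage pool
    B, which pays no maintenance, does not forage, and dies with its
    owners.
    """
    R = state.R
    n = state.n_stages
    nu_J = net_production(R, "juvenile", sp)
    nu_A = net_production(R, "adult", sp)
    d_J = stage_mortality(nu_J, sp.rates.mu)
    d_A = stage_mortality(nu_A, sp.rates.mu)
    gamma = maturation_rate(nu_J, d_J, stage_size_ratio(sp.z, n))

    J = state.J
    dJ = (positive_part(nu_J) - gamma - d_J) * J
    dJ[1:] += gamma * J[:-1]
    dA = gamma * J[-1] - d_A * state.A
    dB = positive_part(nu_A) * state.A - d_A * state.B

    grazing = (
        sp.rates.M
        * functional_response(R, sp.H)
        * ((2.0 - sp.q) * J.sum() + sp.q * state.A)
    )
    dR = rp.delta * (rp.Rmax - R) - grazing
    return dJ, dA, dB, dR


def apply_reproduction_stage(state: StageState) -> StageState:
    """Annual reproduction pulse: the storage pool becomes newborn biomass.

    ``J_1 += B`` and ``B = 0``; A and R are unchanged, so total consumer
    biomass is conserved across the pulse.
    """
    out = state.copy()
    out.J[0] += out.B
    out.B = 0.0
    return out
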