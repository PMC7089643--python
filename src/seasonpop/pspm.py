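"""Cohort-based physiologically structured population model (PSPM).

The consumer population is a finite set of cohorts.  Cohort ``i`` carries a
number density ``c_i`` (mg L^-1 g^-1), an individual body size ``s_i`` (g)
and a per-capita reproductive storage ``g_i`` (g).  Within a growing season
the cohorts and the shared resource follow ODEs; two kinds of discrete maps
punctuate them:

* maturation — when the largest juvenile cohort grows to the maturation
  size ``Sm`` it is relabelled an adult cohort (identity map on c, s, g);
* reproduction — at the end of each season all storage is converted at
  once into a single newborn cohort of size ``Sb``.

Juveniles (``Sb <= s < Sm``) spend positive net production on somatic
growth; adults (``s == Sm``) spend it on storage ``g``.  Stored biomass
neither forages nor pays maintenance, and dies with its owner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bioenergetics import (
    ResourceParams,
    SpeciesParams,
    functional_response,
    net_production,
    positive_part,
    stage_mortality,
)

__all__ = [
    "Cohort",
    "PSPMState",
    "pspm_rhs",
    "maturation_event_fn",
    "apply_maturation",
    "apply_reproduction_pspm",
    "cull_and_compact",
    "aggregate_biomasses",
]


@dataclass(frozen=True)
class Cohort:
    """One cohort: number density, individual size, per-capita storage."""

    c: float  # number density (mg L^-1 g^-1)
    s: float  # individual body size (g)
    g: float = 0.0  # per-capita reproductive storage (g)
    adult: bool = False


@dataclass
class PSPMState:
    """Cohort ensemble plus resource.

    Cohort arrays are kept ordered by descending body size (adults first).
    Because all juveniles share the same mass-specific growth rate the
    ordering is preserved under integration; newborn cohorts enter at the
    tail.
    """

    c: np.ndarray
    s: np.ndarray
    g: np.ndarray
    adult: np.ndarray
    R: float
    t: float = 0.0

    @classmethod
    def empty(cls, R: float, t: float = 0.0) -> "PSPMState":
        z = np.zeros(0)
        return cls(c=z.copy(), s=z.copy(), g=z.copy(), adult=np.zeros(0, bool), R=R, t=t)

    @classmethod
    def from_cohorts(cls, cohorts, R: float, t: float = 0.0) -> "PSPMState":
        cohorts = list(cohorts)
        c = np.array([x.c for x in cohorts], float)
        s = np.array([x.s for x in cohorts], float)
        g = np.array([x.g for x in cohorts], float)
        adult = np.array([x.adult for x in cohorts], bool)
        order = np.lexsort((~adult, s))[::-1]  # descending size, adults first
        return cls(c=c[order], s=s[order], g=g[order], adult=adult[order], R=R, t=t)

    @property
    def n_cohorts(self) -> int:
        return self.c.size

    def cohorts(self) -> list[Cohort]:
        return [
            Cohort(c=float(ci), s=float(si), g=float(gi), adult=bool(ai))
            for ci, si, gi, ai in zip(self.c, self.s, self.g, self.adult)
        ]

    def copy(self) -> "PSPMState":
        return PSPMState(
            c=self.c.copy(),
            s=self.s.copy(),
            g=self.g.copy(),
            adult=self.adult.copy(),
            R=self.R,
            t=self.t,
        )


def pspm_rhs(state: PSPMState, sp: SpeciesParams, rp: ResourceParams):
    """Time derivatives (dc, ds, dg, dR) of the full cohort system.

    Juveniles: dc = -d_J c, ds = nu_J^+ s, dg = 0.
    Adults:    dc = -d_A c, ds = 0,        dg = nu_A^+ Sm.
    Resource:  semi-chemostat renewal minus stage-weighted grazing on the
    structural biomass (storage does not forage).
    """
    R = state.R
    nu_J = net_production(R, "juvenile", sp)
    nu_A = net_production(R, "adult", sp)
    d_J = stage_mortality(nu_J, sp.rates.mu)
    d_A = stage_mortality(nu_A, sp.rates.mu)

    juv = ~state.adult
    dc = np.where(juv, -d_J * state.c, -d_A * state.c)
    ds = np.where(juv, positive_part(nu_J) * state.s, 0.0)
    dg = np.where(juv, 0.0, positive_part(nu_A) * sp.Sm)

    grazing = sp.rates.M * functional_response(R, sp.H) * (
        (2.0 - sp.q) * np.sum(state.c[juv] * state.s[juv])
        + sp.q * np.sum(state.c[~juv]) * sp.Sm
    )
    dR = rp.delta * (rp.Rmax - R) - grazing
    return dc, ds, dg, dR


def maturation_event_fn(state: PSPMState, Sm: float) -> float:
    """Root indicator for maturation: size of the largest juvenile minus ``Sm``.

    Negative before the event, zero at it.  With no juvenile cohorts there
    is no event and ``-inf`` is returned as a sentinel.
    """
    juv = ~state.adult
    if not juv.any():
        return -np.inf
    return float(np.max(state.s[juv]) - Sm)


def apply_maturation(state: PSPMState, sp: SpeciesParams, tol: float = 1e-6) -> PSPMState:
    """Relabel the largest juvenile cohort as adult, pinning its size to ``Sm``.

    Number density and storage are unchanged; so are all other cohorts and
    the resource.  Raises if no juvenile cohort is at ``Sm`` within
    ``tol * Sm``.
    """
    out = state.copy()
    juv = ~out.adult
    if not juv.any():
        raise RuntimeError("maturation event with no juvenile cohorts")
    i = np.flatnonzero(juv)[np.argmax(out.s[juv])]
    if abs(out.s[i] - sp.Sm) > tol * sp.Sm:
        raise RuntimeError(
            f"largest juvenile (s={out.s[i]:.6g}) is not at Sm={sp.Sm:.6g}"
        )
    out.s[i] = sp.Sm
    out.adult[i] = True
    return out


def apply_reproduction_pspm(state: PSPMState, sp: SpeciesParams) -> PSPMState:
    """Annual reproduction pulse: all storage becomes one newborn cohort.

    The newborn number density is ``sum(g_i c_i) / Sb`` so newborn biomass
    exactly equals the storage spent; every existing cohort keeps c and s
    and has g reset to zero.  R is unchanged.  With zero total storage no
    cohort is created.
    """
    out = state.copy()
    spent = float(np.sum(out.g * out.c))
    out.g[:] = 0.0
    if spent > 0.0:
        out.c = np.append(out.c, spent / sp.Sb)
        out.s = np.append(out.s, sp.Sb)
        out.g = np.append(out.g, 0.0)
        out.adult = np.append(out.adult, False)
    return out


def cull_and_compact(
    state: PSPMState,
    eps_c: float = 0.0,
    rel_biomass: float | None = None,
) -> tuple[PSPMState, float]:
    """Drop near-extinct cohorts; return the compacted state and biomass removed.

    A cohort is culled when its number density falls below ``eps_c``, or —
    if ``rel_biomass`` is given — when its biomass ``c (s + g)`` falls below
    ``rel_biomass`` times the total consumer biomass.
    """
    if eps_c < 0:
        raise ValueError("eps_c must be non-negative")
    biomass = state.c * (state.s + state.g)
    drop = state.c < eps_c
    if rel_biomass is not None:
        drop |= biomass < rel_biomass * biomass.sum()
    if not drop.any():
        return state, 0.0
    keep = ~drop
    out = PSPMState(
        c=state.c[keep],
        s=state.s[keep],
        g=state.g[keep],
        adult=state.adult[keep],
        R=state.R,
        t=state.t,
    )
    return out, float(biomass[drop].sum())


def aggregate_biomasses(state: PSPMState) -> dict[str, float]:
    """Stage-level biomass densities {J, A, B, total, R} (mg L^-1).

    J sums structural biomass of juvenile cohorts, A of adult cohorts, and
    B the stored reproductive biomass.
    """
    juv = ~state.adult
    J = float(np.sum(state.c[juv] * state.s[juv]))
    A = float(np.sum(state.c[~juv] * state.s[~juv]))
    B = float(np.sum(state.c[~juv] * state.g[~juv]))
    return {"J": J, "A": A, "B": B, "total": J + A + B, "R": float(state.R)}
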