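"""Individual-level rate functions shared by both population models.

All consumer rates are mass-specific (day^-1) and derive from allometric
scaling with the characteristic adult body size ``W_A``: maximum ingestion
``M``, somatic maintenance ``T`` and background mortality ``mu`` all scale
as ``prefactor * W_A**-0.25``.  Net biomass production is assimilated
intake minus maintenance; when it is negative the shortfall is paid as
starvation biomass loss, which is book-kept as extra mortality.

Units: individual sizes in g; population-level biomass densities (and the
resource) in mg L^-1; rates in day^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateSet",
    "SpeciesParams",
    "ResourceParams",
    "allometric_rates",
    "functional_response",
    "net_production",
    "positive_part",
    "stage_mortality",
    "maturation_rate",
    "stage_size_ratio",
    "expected_adult_contribution",
]

#: Allometric prefactors at unit adult body mass (day^-1).
INGESTION_PREFACTOR = 0.1
MAINTENANCE_PREFACTOR = 0.01
MORTALITY_PREFACTOR = 0.0015
#: Common mass-scaling exponent of the three rates.
ALLOMETRIC_EXPONENT = -0.25


@dataclass(frozen=True)
class RateSet:
    """Mass-specific rate triple for a species of given adult body size.

    Attributes
    ----------
    M : float
        Mass-specific maximum ingestion rate (day^-1).
    T : float
        Mass-specific maintenance rate (day^-1).
    mu : float
        Background (per-capita) mortality rate (day^-1).
    """

    M: float
    T: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.T > 0 and self.mu > 0):
            raise ValueError("all rates must be positive")


@dataclass(frozen=True)
class ResourceParams:
    """Semi-chemostat resource: dR/dt = delta * (Rmax - R) minus grazing."""

    Rmax: float = 20.0  # maximum resource density (mg L^-1)
    delta: float = 0.1  # turnover rate (day^-1)

    def __post_init__(self) -> None:
        if not (self.Rmax > 0 and self.delta > 0):
            raise ValueError("Rmax and delta must be positive")


@dataclass(frozen=True)
class SpeciesParams:
    """Full consumer parameterisation.

    ``q`` scales the stage asymmetry in ingestion: juveniles forage with
    weight ``2 - q`` and adults with weight ``q`` per unit biomass, so
    ``q < 1`` makes juveniles the superior competitors and ``q > 1`` the
    adults.  ``z = Sb / Sm`` is the birth-to-maturation size ratio.
    """

    rates: RateSet
    W_A: float = 50.0  # characteristic adult body size (g)
    H: float = 3.0  # half-saturation resource density (mg L^-1)
    q: float = 1.0  # stage competition asymmetry
    sigma: float = 0.5  # assimilation efficiency
    z: float = 0.1  # birth size / maturation size
    Sm: float = field(default=None)  # type: ignore[assignment]
    Sb: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        # Sm defaults to the adult body size; Sb to z * Sm.
        if self.Sm is None:
            object.__setattr__(self, "Sm", float(self.W_A))
        if self.Sb is None:
            object.__setattr__(self, "Sb", self.z * self.Sm)
        if not 0.0 < self.z < 1.0:
            raise ValueError("z must lie in (0, 1)")
        if not math.isclose(self.Sb, self.z * self.Sm, rel_tol=1e-9):
            raise ValueError("Sb must equal z * Sm")
        if not 0.0 < self.sigma <= 1.0:
            raise ValueError("sigma must lie in (0, 1]")
        if not 0.0 < self.q < 2.0:
            raise ValueError("q must lie in (0, 2)")
        if self.H <= 0:
            raise ValueError("H must be positive")

    @classmethod
    def from_adult_mass(
        cls,
        W_A: float = 50.0,
        *,
        q: float = 1.0,
        H: float = 3.0,
        sigma: float = 0.5,
        z: float = 0.1,
    ) -> "SpeciesParams":
        """Build the default allometric parameterisation for adult mass ``W_A``."""
        return cls(rates=allometric_rates(W_A), W_A=W_A, H=H, q=q, sigma=sigma, z=z)


def allometric_rates(W_A: float) -> RateSet:
    """Mass-specific rates for a species with characteristic adult mass ``W_A`` (g).

    All three rates scale with the -1/4 power of adult body mass, so small
    species are fast (high rates, short lives) and large species slow.
    """
    if not W_A > 0:
        raise ValueError("W_A must be positive")
    scale = W_A**ALLOMETRIC_EXPONENT
    return RateSet(
        M=INGESTION_PREFACTOR * scale,
        T=MAINTENANCE_PREFACTOR * scale,
        mu=MORTALITY_PREFACTOR * scale,
    )


def functional_response(R, H: float):
    """Holling type II resource dependence ``R / (H + R)``, in [0, 1)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resource density must be non-negative")
    if not H > 0:
        raise ValueError("H must be positive")
    out = R / (H + R)
    return out if out.ndim else float(out)


def net_production(R, stage: str, p: SpeciesParams):
    """Mass-specific net biomass production nu (day^-1); negative under starvation.

    Juveniles: ``sigma * (2 - q) * M * R/(H+R) - T``;
    adults:    ``sigma * q * M * R/(H+R) - T``.
    """
    if stage == "juvenile":
        weight = 2.0 - p.q
    elif stage == "adult":
        weight = p.q
    else:
        raise ValueError(f"unknown stage {stage!r}")
    intake = p.sigma * weight * p.rates.M * functional_response(R, p.H)
    out = intake - p.rates.T
    return float(out) if np.ndim(out) == 0 else out


def positive_part(nu):
    """Net production restricted to positive values (growth / storage only)."""
    out = np.maximum(nu, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def stage_mortality(nu, mu: float):
    """Per-capita mortality: background ``mu`` plus starvation loss ``-nu`` when nu < 0."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    out = mu - np.minimum(nu, 0.0)
    return float(out) if np.ndim(out) == 0 else out


# Relative half-width of the series window around the removable singularity
# nu == d of the maturation-rate expression.
_SERIES_SWITCH = 1e-7


def maturation_rate(nu: float, d: float, z_eff: float) -> float:
    """Per-capita juvenile-to-adult transition rate gamma(nu, d).

    Constructed so that, at a fixed resource density with positive net
    production ``nu`` and death rate ``d``, the expected lifetime biomass a
    newborn delivers to the next stage matches the cohort model's
    ``Sm * z_eff**(d/nu)`` per unit ``Sb``:

        gamma = (nu - d) / (1 - z_eff**(1 - d/nu))   for nu > 0,
        gamma = 0                                    otherwise.

    The expression has a removable singularity at ``nu == d`` with limit
    ``-d / ln(z_eff)``; near it a series expansion is used to avoid
    catastrophic cancellation.  The rate is continuous and non-negative.
    """
    if not 0.0 < z_eff < 1.0:
        raise ValueError("z_eff must lie in (0, 1)")
    if d < 0:
        raise ValueError("d must be non-negative")
    if nu <= 0.0:
        return 0.0
    L = math.log(z_eff)  # negative
    x = nu - d
    if abs(x) < _SERIES_SWITCH * max(nu, d):
        # gamma = x / (1 - exp(x*L/nu)); expand the denominator to 2nd order:
        # 1 - e^u = -u (1 + u/2 + u^2/6 + ...) with u = x*L/nu.
        u = x * L / nu
        return -nu / L / (1.0 + u / 2.0 + u * u / 6.0)
    expo = (1.0 - d / nu) * L  # z_eff**(1 - d/nu) = e^expo
    if expo > 700.0:
        # mortality overwhelms production (nu << d): the denominator is an
        # astronomically large negative number and the rate underflows
        return (d - nu) * math.exp(-expo)
    return x / (1.0 - math.exp(expo))


def stage_size_ratio(z: float, n: int) -> float:
    """Per-stage size ratio when the juvenile range is split into ``n`` stages.

    Stages are equal on a log-size scale, so ``z_eff = z**(1/n)`` and the
    product over the n stages recovers the overall ratio ``z``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("n must be a positive integer")
    if not 0.0 < z < 1.0:
        raise ValueError("z must lie in (0, 1)")
    return z ** (1.0 / n)


def expected_adult_contribution(nu: float, mu: float, z: float, Sm: float) -> float:
    """Expected biomass a newborn delivers to the adult stage, constant conditions.

    Under constant net production ``nu`` and mortality ``mu`` a newborn grows
    exponentially, matures after ``-ln(z)/nu`` days with survival
    ``z**(mu/nu)``, and arrives at size ``Sm``; the expectation is therefore
    ``Sm * z**(mu/nu)``.  Returns 0 when ``nu <= 0`` (no growth, no
    maturation).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if nu <= 0.0:
        return 0.0
    return Sm * z ** (mu / nu)
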