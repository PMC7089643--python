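"""Semi-discrete simulation driver shared by both models.

A run is a sequence of growing seasons of length ``Y`` days.  Within each
season the continuous dynamics are integrated with an adaptive ODE solver;
in the cohort model, maturation events are located by root finding on the
size of the largest juvenile cohort and applied as discrete maps
mid-season.  At every season boundary ``t_n = n Y`` the reproduction pulse
is applied instantaneously.  Winter is not simulated: seasons are
contiguous and the pulse sits at the boundary, on the assumption that all
rates are negligible outside the growing season.

The trace records the state on a fixed sampling grid plus explicit pre-
and post-event rows at every discontinuity, so that jumps are never
interpolated across, and keeps a per-year pulse registry (newborn biomass,
pre/post aggregates) for downstream summaries.  Runs are fully
deterministic: identical configurations produce identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .bioenergetics import (
    ResourceParams,
    SpeciesParams,
    RateSet,
    allometric_rates,
    maturation_rate,
    stage_size_ratio,
)
from . import pspm as _pspm
from . import stage_model as _stage
from .pspm import PSPMState
from .stage_model import StageState

__all__ = [
    "SimConfig",
    "Trace",
    "run_simulation",
    "cumulative_maturation_curve",
    "config_to_dict",
    "config_from_dict",
]

_EVENT_TOL = 1e-6  # relative tolerance for pinning a cohort to Sm after a root


@dataclass
class SimConfig:
    """Everything a run needs; fully deterministic (no randomness anywhere).

    ``model`` selects the cohort model (``"pspm"``) or the stage-structured
    biomass model (``"stage"``, with ``n_stages`` juvenile stages).  The
    default initial condition is a resource at ``Rmax`` and a small newborn
    inoculum of ``initial_biomass`` mg L^-1 introduced just after a nominal
    reproduction instant at t = 0.
    """

    model: str = "stage"
    species: SpeciesParams = field(default_factory=SpeciesParams.from_adult_mass)
    resource: ResourceParams = field(default_factory=ResourceParams)
    n_stages: int = 1
    Y: float = 250.0  # season length (days)
    n_years: int = 100
    initial_biomass: float = 0.1  # newborn inoculum (mg L^-1)
    initial_state: Optional[Union[PSPMState, StageState]] = None
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_dt: float = 1.0  # trace sampling interval (days)
    cull_rel_biomass: float = 1e-12  # cohort culled below this biomass fraction
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.model not in ("pspm", "stage"):
            raise ValueError("model must be 'pspm' or 'stage'")
        if self.Y <= 0:
            raise ValueError("Y must be positive")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")
        if self.sample_dt > self.Y:
            raise ValueError("sample_dt must not exceed Y")
        if self.n_stages < 1:
            raise ValueError("n_stages must be at least 1")


@dataclass
class Trace:
    """Simulation record: sampled rows, pulse registry, final state."""

    frame: pd.DataFrame
    pulses: pd.DataFrame
    final_state: Union[PSPMState, StageState]
    config: SimConfig

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def pulses_to_csv(self, path) -> None:
        self.pulses.to_csv(path, index=False)


class SolverError(RuntimeError):
    """ODE integration failure, carrying the last good time and state."""

    def __init__(self, message: str, t: float, state) -> None:
        super().__init__(f"{message} (t = {t:.6g})")
        self.t = t
        self.state = state


def run_simulation(cfg: SimConfig, progress=None) -> Trace:
    """Run ``cfg.n_years`` seasons and return the full :class:`Trace`.

    ``progress``, if given, is called once per completed year with
    ``(year, n_years)``.
    """
    if cfg.model == "pspm":
        return _run_pspm(cfg, progress)
    return _run_stage(cfg, progress)


# ---------------------------------------------------------------------------
# stage-structured model driver


def _stage_initial(cfg: SimConfig) -> StageState:
    if cfg.initial_state is not None:
        st = cfg.initial_state.copy()
        if st.n_stages != cfg.n_stages:
            raise ValueError("initial state has wrong number of juvenile stages")
        return st
    J = np.zeros(cfg.n_stages)
    J[0] = cfg.initial_biomass
    return StageState(J=J, A=0.0, B=0.0, R=cfg.resource.Rmax, t=0.0)


def _stage_row(t: float, st: StageState, event: str) -> dict:
    row = {"t": t}
    for k in range(st.n_stages):
        row[f"J_{k + 1}"] = st.J[k]
    row.update(
        J=st.J_total,
        A=st.A,
        B=st.B,
        total=st.J_total + st.A + st.B,
        R=st.R,
        n_cohorts=st.n_stages,
        event=event,
    )
    return row


def _run_stage(cfg: SimConfig, progress=None) -> Trace:
    sp, rp = cfg.species, cfg.resource
    st = _stage_initial(cfg)
    n = st.n_stages

    def rhs(t, y):
        s = StageState(J=y[:n], A=y[n], B=y[n + 1], R=y[n + 2], t=t)
        dJ, dA, dB, dR = _stage.stage_rhs(s, sp, rp)
        return np.concatenate([dJ, [dA, dB, dR]])

    rows = [_stage_row(st.t, st, "none")]
    pulses = []
    for year in range(cfg.n_years):
        t0, t1 = year * cfg.Y, (year + 1) * cfg.Y
        y0 = np.concatenate([st.J, [st.A, st.B, st.R]])
        sol = solve_ivp(
            rhs, (t0, t1), y0, method=cfg.method, dense_output=True,
            rtol=cfg.rtol, atol=cfg.atol,
        )
        if not sol.success:
            raise SolverError(sol.message, t0, st)
        for t in _sample_grid(t0, t1, cfg.sample_dt):
            y = sol.sol(t)
            rows.append(
                _stage_row(t, StageState(J=y[:n], A=y[n], B=y[n + 1], R=y[n + 2]), "none")
            )
        y = sol.y[:, -1]
        st = StageState(J=y[:n], A=y[n], B=y[n + 1], R=y[n + 2], t=t1)
        rows.append(_stage_row(t1, st, "reproduction_pre"))
        newborn = st.B
        pre = {"J": st.J_total, "A": st.A, "B": st.B, "total": st.J_total + st.A + st.B,
               "R": st.R}
        st = _stage.apply_reproduction_stage(st)
        rows.append(_stage_row(t1, st, "reproduction_post"))
        pulses.append(_pulse_row(year + 1, t1, newborn, pre, st_post={
            "J": st.J_total, "A": st.A, "B": st.B,
            "total": st.J_total + st.A + st.B, "R": st.R}, culled=0.0))
        if progress is not None:
            progress(year + 1, cfg.n_years)
    return Trace(pd.DataFrame(rows), pd.DataFrame(pulses), st, cfg)


# ---------------------------------------------------------------------------
# cohort (PSPM) driver


def _pspm_initial(cfg: SimConfig) -> PSPMState:
    if cfg.initial_state is not None:
        return cfg.initial_state.copy()
    sp = cfg.species
    return PSPMState(
        c=np.array([cfg.initial_biomass / sp.Sb]),
        s=np.array([sp.Sb]),
        g=np.array([0.0]),
        adult=np.array([False]),
        R=cfg.resource.Rmax,
        t=0.0,
    )


def _pspm_row(t: float, st: PSPMState, event: str) -> dict:
    agg = _pspm.aggregate_biomasses(st)
    return {"t": t, **agg, "n_cohorts": st.n_cohorts, "event": event}


def _pack(st: PSPMState) -> np.ndarray:
    return np.concatenate([st.c, st.s, st.g, [st.R]])


def _unpack(y: np.ndarray, adult: np.ndarray, t: float) -> PSPMState:
    k = adult.size
    return PSPMState(
        c=y[:k].copy(), s=y[k : 2 * k].copy(), g=y[2 * k : 3 * k].copy(),
        adult=adult.copy(), R=float(y[-1]), t=t,
    )


def _integrate_season_pspm(st, t0, t1, cfg, rows):
    """Integrate one season with maturation-event handling; returns state at t1."""
    sp, rp = cfg.species, cfg.resource
    t_cur = st.t

    while t_cur < t1 - 1e-12 * max(1.0, t1):
        adult = st.adult  # fixed within a segment
        k = adult.size

        def rhs(t, y, adult=adult, k=k):
            s = _unpack(y, adult, t)
            dc, ds, dg, dR = _pspm.pspm_rhs(s, sp, rp)
            return np.concatenate([dc, ds, dg, [dR]])

        events = None
        juv = ~adult
        if juv.any():
            juv_idx = np.flatnonzero(juv) + k  # indices of juvenile sizes in y

            def hit_Sm(t, y, juv_idx=juv_idx):
                return float(np.max(y[juv_idx]) - sp.Sm)

            hit_Sm.terminal = True
            hit_Sm.direction = 1.0
            events = [hit_Sm]

        sol = solve_ivp(
            rhs, (t_cur, t1), _pack(st), method=cfg.method, dense_output=True,
            events=events, rtol=cfg.rtol, atol=cfg.atol,
        )
        if not sol.success:
            raise SolverError(sol.message, t_cur, st)

        t_end = sol.t[-1]
        for t in _sample_grid(t_cur, min(t_end, t1), cfg.sample_dt):
            rows.append(_pspm_row(t, _unpack(sol.sol(t), adult, t), "none"))

        st = _unpack(sol.y[:, -1], adult, t_end)
        if sol.status == 1:  # maturation root located
            rows.append(_pspm_row(t_end, st, "maturation"))
            # mature every cohort sitting at Sm (ties can occur after a
            # no-growth season leaves cohorts with identical sizes)
            while _pspm.maturation_event_fn(st, sp.Sm) >= -_EVENT_TOL * sp.Sm:
                st = _pspm.apply_maturation(st, sp, tol=_EVENT_TOL)
            rows.append(_pspm_row(t_end, st, "maturation"))
        t_cur = t_end
        st.t = t_cur
    st.t = t1
    return st


def _run_pspm(cfg: SimConfig, progress=None) -> Trace:
    sp = cfg.species
    st = _pspm_initial(cfg)
    rows = [_pspm_row(st.t, st, "none")]
    pulses = []
    for year in range(cfg.n_years):
        t0, t1 = year * cfg.Y, (year + 1) * cfg.Y
        st = _integrate_season_pspm(st, t0, t1, cfg, rows)
        rows.append(_pspm_row(t1, st, "reproduction_pre"))
        pre = _pspm.aggregate_biomasses(st)
        newborn = float(np.sum(st.g * st.c))
        st = _pspm.apply_reproduction_pspm(st, sp)
        rows.append(_pspm_row(t1, st, "reproduction_post"))
        post = _pspm.aggregate_biomasses(st)
        st, culled = _pspm.cull_and_compact(st, rel_biomass=cfg.cull_rel_biomass)
        pulses.append(_pulse_row(year + 1, t1, newborn, pre, post, culled))
        if progress is not None:
            progress(year + 1, cfg.n_years)
    return Trace(pd.DataFrame(rows), pd.DataFrame(pulses), st, cfg)


# ---------------------------------------------------------------------------
# shared helpers


def _sample_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    """Fixed global day grid restricted to the open interval (t0, t1)."""
    k0 = int(np.floor(t0 / dt + 1e-9)) + 1
    k1 = int(np.ceil(t1 / dt - 1e-9))
    return np.arange(k0, k1) * dt


def _pulse_row(year, t, newborn, st_pre, st_post, culled) -> dict:
    row = {"year": year, "t": t, "newborn": newborn, "culled": culled}
    row.update({f"{k}_pre": v for k, v in st_pre.items()})
    row.update({f"{k}_post": v for k, v in st_post.items()})
    return row


def cumulative_maturation_curve(
    kind: str,
    n: int,
    nu: float,
    mu: float,
    z: float,
    Sm: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Cumulative biomass delivered to the adult stage by one newborn.

    Constant-environment comparison of the two maturation representations.
    In the cohort model the whole surviving cohort matures at once at age
    ``-ln(z)/nu``, so the curve is a step of height ``Sm * z**(mu/nu)``.
    In the stage model maturation is a flow at rate ``gamma`` through the
    ``n``-stage chain seeded with one newborn mass ``Sb = z * Sm``; the
    curve is the integral of the flux out of the last stage, which rises
    gradually and asymptotes to the same value.
    """
    t_grid = np.asarray(t_grid, float)
    if nu <= 0.0:
        return np.zeros_like(t_grid)
    if kind == "pspm":
        a_m = -np.log(z) / nu
        return np.where(t_grid >= a_m, Sm * z ** (mu / nu), 0.0)
    if kind != "stage":
        raise ValueError("kind must be 'pspm' or 'stage'")

    gamma = maturation_rate(nu, mu, stage_size_ratio(z, n))
    Sb = z * Sm

    def rhs(t, y):
        J = y[:n]
        dJ = (nu - mu - gamma) * J
        dJ[1:] += gamma * J[:-1]
        return np.concatenate([dJ, [gamma * J[-1]]])

    y0 = np.zeros(n + 1)
    y0[0] = Sb
    t_max = float(t_grid.max()) if t_grid.size else 0.0
    if t_max == 0.0:
        return np.zeros_like(t_grid)
    sol = solve_ivp(
        rhs, (0.0, t_max), y0, t_eval=np.clip(t_grid, 0.0, t_max),
        method="LSODA", rtol=1e-10, atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"maturation-curve integration failed: {sol.message}")
    return sol.y[-1]


# ---------------------------------------------------------------------------
# configuration (de)serialisation — flat key names follow the standard
# symbols: M, T, mu, W_A, H, q, sigma, z, Y, Sm, Sb, Rmax, delta


def config_to_dict(cfg: SimConfig) -> dict:
    sp, rp = cfg.species, cfg.resource
    return {
        "model": cfg.model,
        "n_stages": cfg.n_stages,
        "W_A": sp.W_A,
        "M": sp.rates.M,
        "T": sp.rates.T,
        "mu": sp.rates.mu,
        "H": sp.H,
        "q": sp.q,
        "sigma": sp.sigma,
        "z": sp.z,
        "Sm": sp.Sm,
        "Sb": sp.Sb,
        "Rmax": rp.Rmax,
        "delta": rp.delta,
        "Y": cfg.Y,
        "n_years": cfg.n_years,
        "initial_biomass": cfg.initial_biomass,
        "rtol": cfg.rtol,
        "atol": cfg.atol,
        "sample_dt": cfg.sample_dt,
        "cull_rel_biomass": cfg.cull_rel_biomass,
        "method": cfg.method,
    }


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    W_A = float(d.pop("W_A", 50.0))
    base = allometric_rates(W_A)
    rates = RateSet(
        M=float(d.pop("M", base.M)),
        T=float(d.pop("T", base.T)),
        mu=float(d.pop("mu", base.mu)),
    )
    sp_kwargs = dict(rates=rates, W_A=W_A)
    for key in ("H", "q", "sigma", "z", "Sm", "Sb"):
        if key in d:
            sp_kwargs[key] = float(d.pop(key))
    species = SpeciesParams(**sp_kwargs)
    resource = ResourceParams(
        Rmax=float(d.pop("Rmax", 20.0)), delta=float(d.pop("delta", 0.1))
    )
    kwargs = {}
    for key in ("model", "method"):
        if key in d:
            kwargs[key] = d.pop(key)
    for key in ("n_stages", "n_years"):
        if key in d:
            kwargs[key] = int(d.pop(key))
    for key in ("Y", "initial_biomass", "rtol", "atol", "sample_dt", "cull_rel_biomass"):
        if key in d:
            kwargs[key] = float(d.pop(key))
    if d:
        raise ValueError(f"unknown config keys: {sorted(d)}")
    return SimConfig(species=species, resource=resource, **kwargs)
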