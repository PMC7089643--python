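"""Numerical-experiment protocol: averaging, sweeps and model comparison.

The long-run protocol integrates each parameter combination over many
seasons, summarises the attractor by trapezoidal time averages over the
trailing portion of the run and by the set of post-reproduction biomasses
in a trailing window, and steps a control parameter in small increments
with each run warm-started from the previous endpoint (a bifurcation
sweep).  Reproduction-gap statistics quantify how many consecutive years
pass without an effective newborn pulse, the signature of single-cohort
(juvenile-driven) population cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bioenergetics import SpeciesParams
from .season_engine import SimConfig, Trace, run_simulation

__all__ = [
    "SweepSpec",
    "PRESETS",
    "preset_config",
    "time_average",
    "post_reproduction_series",
    "reproduction_gap_stats",
    "bifurcation_sweep",
    "compare_models",
]

#: Named parameter scenarios.  All use the default allometric
#: parameterisation; ``q`` sets which stage is the superior forager.
PRESETS = {
    "symmetric": {"W_A": 50.0, "q": 1.0},
    "adult_superior": {"W_A": 50.0, "q": 1.5},
    "juvenile_superior": {"W_A": 50.0, "q": 0.5},
    "small_juvenile_superior": {"W_A": 1.0, "q": 0.5},
}

#: Long-run protocol at full scale: 200,000 days per parameter step,
#: averages over the trailing 60 %, post-pulse samples over the last
#: 10,000 days.  The desk-scale default divides the step length by 10.
PAPER_DAYS_PER_STEP = 200_000.0
DEFAULT_DAYS_PER_STEP = 20_000.0
AVERAGING_FRACTION = 0.6
PAPER_POST_WINDOW = 10_000.0


def preset_config(name: str, model: str = "stage", **overrides) -> SimConfig:
    """Build a :class:`SimConfig` for a named preset scenario."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    species = SpeciesParams.from_adult_mass(p["W_A"], q=p["q"])
    return SimConfig(model=model, species=species, **overrides)


@dataclass
class SweepSpec:
    """A bifurcation sweep: step ``param`` along ``grid``, one long run each.

    With ``continuation`` (the default) every step is warm-started from the
    final state of the previous one, so the sweep tracks an attractor
    branch; otherwise each step restarts from the default inoculum.
    ``post_window`` defaults to the same fraction of the step length as
    10,000 days is of the full-scale 200,000-day protocol.
    """

    base: SimConfig
    param: str  # one of {"q", "W_A", "n_stages"}
    grid: Sequence[float]
    days_per_step: float = DEFAULT_DAYS_PER_STEP
    averaging_fraction: float = AVERAGING_FRACTION
    post_window: Optional[float] = None
    continuation: bool = True

    def __post_init__(self) -> None:
        if self.param not in ("q", "W_A", "n_stages"):
            raise ValueError("param must be 'q', 'W_A' or 'n_stages'")
        g = np.asarray(self.grid, float)
        if g.size == 0 or (g.size > 1 and not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0))):
            raise ValueError("grid must be non-empty and strictly monotone")
        if not 0.0 < self.averaging_fraction <= 1.0:
            raise ValueError("averaging_fraction must lie in (0, 1]")
        if self.post_window is None:
            self.post_window = self.days_per_step * PAPER_POST_WINDOW / PAPER_DAYS_PER_STEP


_AVG_COLUMNS = ("J", "A", "B", "total", "R")


def time_average(trace: Trace, fraction: float = AVERAGING_FRACTION) -> dict[str, float]:
    """Trapezoidal time averages over the trailing ``fraction`` of the run.

    The trace carries duplicate-time pre/post rows at every discontinuity,
    so the trapezoid rule integrates each continuous piece separately and
    never averages across a jump (a zero-width interval contributes
    nothing).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    f = trace.frame
    if len(f) == 0:
        raise ValueError("empty trace")
    t = f["t"].to_numpy()
    t_start = t[-1] - fraction * (t[-1] - t[0])
    win = f[t >= t_start - 1e-12]
    tw = win["t"].to_numpy()
    span = tw[-1] - tw[0]
    if span <= 0:
        raise ValueError("averaging window is empty")
    return {
        col: float(np.trapezoid(win[col].to_numpy(), tw)) / span for col in _AVG_COLUMNS
    }


def post_reproduction_series(trace: Trace, window_days: float) -> pd.DataFrame:
    """Post-pulse states for every year boundary in the trailing window.

    Returns one row per reproduction event with the post-pulse biomasses
    (newborn pulse included in J) and the pulse size itself.
    """
    p = trace.pulses
    if len(p) == 0:
        raise ValueError("trace has no reproduction pulses")
    t_end = float(p["t"].iloc[-1])
    t_first = float(trace.frame["t"].iloc[0])
    if window_days > t_end - t_first:
        raise ValueError("window longer than the simulated period")
    win = p[p["t"] > t_end - window_days + 1e-9]
    cols = {"year": win["year"], "t": win["t"], "newborn": win["newborn"]}
    for c in _AVG_COLUMNS:
        cols[c] = win[f"{c}_post"]
    return pd.DataFrame(cols).reset_index(drop=True)


def reproduction_gap_stats(
    trace: Trace,
    rel_threshold: float = 1e-6,
    window_days: Optional[float] = None,
) -> dict[str, int]:
    """Longest run of years without an effective reproduction pulse.

    A year counts as "without reproduction" when the newborn-pulse biomass
    is below ``rel_threshold`` times the total consumer biomass at the
    pulse (years with no consumers at all also count).  Returns the longest
    consecutive run and the total number of such years, optionally
    restricted to the trailing ``window_days``.
    """
    if not 0.0 <= rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in [0, 1)")
    p = trace.pulses
    if window_days is not None:
        t_end = float(p["t"].iloc[-1])
        p = p[p["t"] > t_end - window_days + 1e-9]
    newborn = p["newborn"].to_numpy()
    total = p["total_pre"].to_numpy()
    skipped = newborn < rel_threshold * total
    skipped |= total <= 0.0
    max_gap = gap = 0
    for flag in skipped:
        gap = gap + 1 if flag else 0
        max_gap = max(max_gap, gap)
    return {"max_gap_years": int(max_gap), "n_skipped_years": int(np.sum(skipped))}


def _with_param(cfg: SimConfig, param: str, value) -> SimConfig:
    if param == "n_stages":
        return replace(cfg, n_stages=int(value), initial_state=None)
    sp = cfg.species
    if param == "q":
        species = SpeciesParams.from_adult_mass(
            sp.W_A, q=float(value), H=sp.H, sigma=sp.sigma, z=sp.z
        )
    else:  # W_A: rates, Sm and Sb all change with adult mass
        species = SpeciesParams.from_adult_mass(
            float(value), q=sp.q, H=sp.H, sigma=sp.sigma, z=sp.z
        )
    return replace(cfg, species=species)


def _warm_start(cfg: SimConfig, final_state, old_sp: SpeciesParams) -> SimConfig:
    """Carry the previous endpoint over as the initial state of the next step."""
    st = final_state.copy()
    if cfg.model == "pspm" and cfg.species.Sm != old_sp.Sm:
        # adult mass changed: rescale individual sizes so each cohort keeps
        # its relative position in the [Sb, Sm] range
        st.s = st.s * (cfg.species.Sm / old_sp.Sm)
        st.s[st.adult] = cfg.species.Sm
    st.t = 0.0
    return replace(cfg, initial_state=st)


def bifurcation_sweep(spec: SweepSpec, progress=None) -> pd.DataFrame:
    """Run the sweep and return one summary row per grid value.

    Each row carries the time-averaged biomasses, the post-pulse cycle
    amplitude (max - min of post-pulse total biomass in the trailing
    window) and the reproduction-gap statistics.  A solver failure flags
    the row and restarts the next step from the default inoculum.
    """
    cfg = spec.base
    n_years = max(1, int(round(spec.days_per_step / cfg.Y)))
    cfg = replace(cfg, n_years=n_years)
    rows = []
    state = None
    old_sp = cfg.species
    for i, value in enumerate(np.asarray(spec.grid, float)):
        step_cfg = _with_param(cfg, spec.param, value)
        if spec.continuation and state is not None and spec.param != "n_stages":
            step_cfg = _warm_start(step_cfg, state, old_sp)
        row = {spec.param: value, "failed": False}
        try:
            trace = run_simulation(step_cfg)
        except Exception as err:  # solver failure: flag and restart fresh
            row.update(failed=True, error=str(err))
            state = None
            rows.append(row)
            continue
        avg = time_average(trace, spec.averaging_fraction)
        row.update({f"avg_{k}": v for k, v in avg.items()})
        post = post_reproduction_series(trace, spec.post_window)
        row["amplitude"] = float(post["total"].max() - post["total"].min())
        for c in _AVG_COLUMNS:
            row[f"post_{c}_min"] = float(post[c].min())
            row[f"post_{c}_max"] = float(post[c].max())
        row.update(reproduction_gap_stats(trace, window_days=spec.post_window))
        rows.append(row)
        state = trace.final_state
        old_sp = step_cfg.species
        if progress is not None:
            progress(i + 1, len(spec.grid))
    return pd.DataFrame(rows)


def compare_models(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    tiny: float = 1e-30,
) -> pd.DataFrame:
    """Per-output relative differences |a - b| / max(|a|, |b|, tiny).

    Both summaries must share the same parameter grid (their first
    column).  Quantifies how closely the two model variants agree.
    """
    key = summary_a.columns[0]
    if key != summary_b.columns[0] or not np.allclose(
        summary_a[key].to_numpy(), summary_b[key].to_numpy()
    ):
        raise ValueError("summaries are on different parameter grids")
    if columns is None:
        columns = [
            c for c in summary_a.columns
            if c.startswith("avg_") and c in summary_b.columns
        ]
    out = {key: summary_a[key].to_numpy()}
    for c in columns:
        a = summary_a[c].to_numpy(float)
        b = summary_b[c].to_numpy(float)
        out[c] = np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), tiny)
    return pd.DataFrame(out)
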