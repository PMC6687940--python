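"""Diel forcing and time integration of the storage pools.

The trichome is forced with a 12 h / 12 h light-dark cycle at constant
irradiance during the light phase, and a prescribed step function for the
photosynthetic cell fraction f_P (high at dawn, reduced during midday
when more cells commit to N2 fixation, high again toward evening). The
two prognostic reserves C_Sto and N_Sto are advanced with an explicit
Euler scheme; oxygen is closed algebraically within every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fluxes as _fl
from .oxygen import solve_oxygen
from .params import (
    FluxSet,
    ForcingState,
    InputDomainError,
    ModelParameters,
    OxygenSolution,
    StorageState,
)

HOURS_PER_DAY = 24.0

# Dawn (hour 0) storage state on the diel limit cycle of the calibrated
# default parameters, precomputed by trichoflux.calibrate.attractor_state.
# Starting here lets the standard 3-day spin-up satisfy diel periodicity.
DEFAULT_INITIAL_C_STO = 0.0342321
DEFAULT_INITIAL_N_STO = 0.0497046


class IntegrationError(RuntimeError):
    """Raised when a step produces an invalid state despite limiting."""


class SpinupError(RuntimeError):
    """Raised when no diel-periodic state is reached within the allowed days."""


@dataclass(frozen=True)
class ForcingSchedule:
    """24 h periodic forcing: light window and f_P step schedule.

    ``f_P_steps`` maps the start hour of each segment to its f_P value;
    segments extend to the next start (the last wraps to 24 h).
    """

    I_light: float = 200.0
    light_start: float = 0.0
    light_end: float = 12.0
    f_P_steps: tuple = ((0.0, 0.8), (3.0, 0.55), (9.0, 0.8))

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.f_P_steps]
        if starts != sorted(starts) or starts[0] != 0.0:
            raise InputDomainError("f_P_steps must start at hour 0 and be sorted")
        if any(not 0.0 <= v <= 1.0 for _, v in self.f_P_steps):
            raise InputDomainError("f_P values must lie in [0, 1]")
        if self.I_light < 0:
            raise InputDomainError("I_light must be >= 0")


def forcing_at(schedule: ForcingSchedule, t_hours: float) -> ForcingState:
    """Evaluate the periodic forcing at an absolute time in hours."""
    if t_hours < 0:
        raise InputDomainError("time must be >= 0")
    tau = t_hours % HOURS_PER_DAY
    I = schedule.I_light if schedule.light_start <= tau < schedule.light_end else 0.0
    f_p = schedule.f_P_steps[0][1]
    for start, value in schedule.f_P_steps:
        if tau >= start:
            f_p = value
    return ForcingState(t=tau, I=I, f_P=f_p, f_N=1.0 - f_p)


def fvfm(forcing: ForcingState, params: ModelParameters) -> float:
    """Trichome-average Fv/Fm (delegates to the flux layer)."""
    return _fl.fvfm(forcing, params)


def step(
    state: StorageState,
    t_hours: float,
    dt_days: float,
    params: ModelParameters,
    schedule: ForcingSchedule,
) -> tuple[StorageState, FluxSet, OxygenSolution, ForcingState]:
    """Advance the reserves one explicit Euler step of ``dt_days``.

    Order of evaluation: forcing -> C fixation, biomass production,
    P-cell respiration -> carbon supply ceiling for N cells -> O2
    closure (yields F_Res_N and [O2]_N) -> N2 fixation -> Euler update
    with a positivity limiter that rescales F_Bio, then F_Nfix, then
    F_Res_N if a pool would be overdrawn.
    """
    if dt_days <= 0:
        raise InputDomainError("dt must be > 0")
    forcing = forcing_at(schedule, t_hours)
    f_cfix = _fl.carbon_fixation_rate(params, state, forcing)
    f_bio = _fl.biomass_production_rate(params, state)
    f_res_p = _fl.respiration_P(params, f_bio)

    # carbon available for oxidation in N cells this step: the whole C
    # store (per dt) plus fixation beyond the P-cell commitments
    c_supply_max = max(state.C_Sto / dt_days + f_cfix - f_bio - f_res_p, 0.0)
    oxy = solve_oxygen(params, f_cfix, f_res_p, c_supply_max)
    f_res_n = oxy.F_Res_N
    f_nfix = _fl.n2_fixation_rate(params, state, forcing, oxy.O2_N)

    # --- positivity limiter (C pool first, then the N pool) ---
    c_avail = state.C_Sto + f_cfix * dt_days
    def c_use() -> float:
        return (f_bio * (1.0 + params.Y_Res_Bio) + f_nfix * params.Y_Nfix_CN + f_res_n) * dt_days

    if c_use() > c_avail:
        # cut biomass production (and its coupled respiration) first
        excess = c_use() - c_avail
        cut = min(f_bio, excess / ((1.0 + params.Y_Res_Bio) * dt_days))
        f_bio -= cut
        f_res_p = _fl.respiration_P(params, f_bio)
        if c_use() > c_avail and params.Y_Nfix_CN > 0:
            excess = c_use() - c_avail
            cut = min(f_nfix, excess / (params.Y_Nfix_CN * dt_days))
            f_nfix -= cut
        if c_use() > c_avail:
            excess = c_use() - c_avail
            f_res_n = max(f_res_n - excess / dt_days, 0.0)

    n_avail = state.N_Sto + f_nfix * dt_days
    n_use = f_bio * params.Y_Bio_NC * dt_days
    if n_use > n_avail and params.Y_Bio_NC > 0:
        f_bio = min(f_bio, n_avail / (params.Y_Bio_NC * dt_days))
        f_res_p = _fl.respiration_P(params, f_bio)

    f_res = f_res_p + f_res_n
    dc_dt = f_cfix - f_bio - f_nfix * params.Y_Nfix_CN - f_res
    dn_dt = f_nfix - f_bio * params.Y_Bio_NC
    c_new = state.C_Sto + dc_dt * dt_days
    n_new = state.N_Sto + dn_dt * dt_days
    # round-off guard and hard capacity clamp
    c_new = min(max(c_new, 0.0), params.C_Sto_max)
    n_new = min(max(n_new, 0.0), params.N_Sto_max)
    if math.isnan(c_new) or math.isnan(n_new):
        raise IntegrationError(f"NaN state at t={t_hours:.3f} h (dt={dt_days} d)")

    f_resn2 = min(params.Y_ResN2_Nfix * f_nfix, f_res_n)
    flux = FluxSet(
        F_Cfix=f_cfix,
        F_Bio=f_bio,
        F_Nfix=f_nfix,
        F_Res_P=f_res_p,
        F_Res_N=f_res_n,
        F_ResN2=f_resn2,
        F_RP=f_res_n - f_resn2,
        F_CSto=max(dc_dt, 0.0),
        F_Nfix_C=f_nfix * params.Y_Nfix_CN,
    )
    # report the solution with the possibly limited F_Res_N
    if f_res_n != oxy.F_Res_N:
        oxy = solve_oxygen(params, f_cfix, f_res_p, f_res_n)
    return StorageState(C_Sto=c_new, N_Sto=n_new), flux, oxy, forcing


_SERIES_COLUMNS = [
    "t_hours", "I", "f_P", "f_N", "C_Sto", "N_Sto",
    "F_Cfix", "F_Bio", "F_Nfix", "F_Res_P", "F_Res_N", "F_Res",
    "F_ResN2", "F_RP", "F_CSto", "F_Nfix_C",
    "O2_P", "O2_N", "O2_B", "O2_E", "J_PB", "J_PN", "J_BN", "J_BE",
    "regime_carbon_limited", "FvFm",
]


@dataclass
class SimulationResult:
    """Full multi-day time series plus run metadata.

    ``frame`` has one row per step (fluxes and O2 diagnosed at the start
    of the step, storages at the end). ``analysis_day`` marks the first
    post-spin-up day used for diel statistics.
    """

    frame: pd.DataFrame
    params: ModelParameters
    schedule: ForcingSchedule
    dt_days: float
    days: int
    spinup_days: int
    periodic: bool
    metadata: dict = field(default_factory=dict)

    @property
    def analysis_day_start_hours(self) -> float:
        return self.spinup_days * HOURS_PER_DAY

    def analysis_day(self) -> pd.DataFrame:
        """One diel cycle after spin-up, with the clock re-zeroed."""
        t0 = self.analysis_day_start_hours
        sel = self.frame[
            (self.frame.t_hours >= t0 - 1e-9)
            & (self.frame.t_hours < t0 + HOURS_PER_DAY - 1e-9)
        ].copy()
        sel["hour"] = sel.t_hours - t0
        return sel

    def window(self, h0: float, h1: float) -> pd.DataFrame:
        """Analysis-day rows with hour-of-day in [h0, h1)."""
        day = self.analysis_day()
        return day[(day.hour >= h0 - 1e-9) & (day.hour < h1 - 1e-9)]


def run(
    params: ModelParameters,
    schedule: ForcingSchedule | None = None,
    days: int = 4,
    dt_days: float = 0.001,
    spinup_days: int = 3,
    initial: StorageState | None = None,
    require_periodic: bool = False,
    periodic_tol: float = 1e-3,
) -> SimulationResult:
    """Integrate the model for ``days`` diel cycles.

    The first ``spinup_days`` cycles bring the reserves onto the diel
    attractor and are excluded from diel statistics (but retained in the
    output). With ``require_periodic`` the final day is checked against
    the previous one at relative tolerance ``periodic_tol``.
    """
    if days < 1:
        raise InputDomainError("days must be >= 1")
    if spinup_days >= days:
        raise InputDomainError("need at least one post-spin-up day: days > spinup_days")
    schedule = schedule or ForcingSchedule()
    state = initial or StorageState(
        C_Sto=min(DEFAULT_INITIAL_C_STO, params.C_Sto_max),
        N_Sto=min(DEFAULT_INITIAL_N_STO, params.N_Sto_max),
    )
    steps_per_day = round(1.0 / dt_days)
    n_steps = days * steps_per_day
    rows = np.empty((n_steps, len(_SERIES_COLUMNS)))
    for k in range(n_steps):
        t_h = k * dt_days * HOURS_PER_DAY
        state, flux, oxy, forcing = step(state, t_h, dt_days, params, schedule)
        rows[k] = (
            t_h, forcing.I, forcing.f_P, forcing.f_N, state.C_Sto, state.N_Sto,
            flux.F_Cfix, flux.F_Bio, flux.F_Nfix, flux.F_Res_P, flux.F_Res_N,
            flux.F_Res, flux.F_ResN2, flux.F_RP, flux.F_CSto, flux.F_Nfix_C,
            oxy.O2_P, oxy.O2_N, oxy.O2_B, oxy.O2_E,
            oxy.J_PB, oxy.J_PN, oxy.J_BN, oxy.J_BE,
            float(oxy.regime == "carbon_limited"), _fl.fvfm(forcing, params),
        )
    frame = pd.DataFrame(rows, columns=_SERIES_COLUMNS)

    periodic = False
    if days >= 2:
        last = frame.iloc[-steps_per_day:][["C_Sto", "N_Sto"]].to_numpy()
        prev = frame.iloc[-2 * steps_per_day : -steps_per_day][["C_Sto", "N_Sto"]].to_numpy()
        scale = np.maximum(np.abs(prev).max(axis=0), 1e-12)
        periodic = bool((np.abs(last - prev).max(axis=0) / scale < periodic_tol).all())
    if require_periodic and not periodic:
        raise SpinupError(
            f"no diel-periodic state after {days} days (tol={periodic_tol})"
        )
    meta = {
        "params_hash": params.content_hash(),
        "dt_days": dt_days,
        "days": days,
        "spinup_days": spinup_days,
        "integrator": "explicit Euler, algebraic O2 closure per step",
    }
    return SimulationResult(
        frame=frame,
        params=params,
        schedule=schedule,
        dt_days=dt_days,
        days=days,
        spinup_days=spinup_days,
        periodic=periodic,
        metadata=meta,
    )
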