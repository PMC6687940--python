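"""Algebraic flux laws of the trichome model.

Pure functions mapping (parameters, state, forcing) to instantaneous
biomass-specific rates. No time stepping happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    FluxSet,
    ForcingState,
    InputDomainError,
    ModelParameters,
    ParameterError,
    StorageState,
)


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def n2_fixation_rate(
    params: ModelParameters,
    storage: StorageState,
    forcing: ForcingState,
    O2_N: float,
) -> float:
    """N2 fixation rate of the average trichome cell.

    The ceiling F_Nfix_full * f_N * f_NITROGE (only nitrogenase-bearing
    nonphotosynthetic cells fix) is scaled by three factors in [0, 1]:
    linear O2 inhibition below the critical concentration, Monod
    saturation on the C storage accessible to N cells (C_Sto / f_N), and
    linear inhibition by N-storage filling. In darkness the optional gate
    zeroes the rate, reproducing the observed shutdown at lights-off.
    """
    if O2_N < 0:
        raise InputDomainError(f"O2_N must be >= 0, got {O2_N}")
    storage.check_capacity(params)
    if forcing.f_N <= 0.0:
        return 0.0
    if params.dark_gate_n2fix and forcing.I <= 0.0:
        return 0.0
    ceiling = params.F_Nfix_full * forcing.f_N * params.f_NITROGE
    o2_term = _clamp01((params.O2_crit - O2_N) / params.O2_crit) if params.O2_crit > 0 else float(O2_N <= 0)
    c_sto_n = storage.C_Sto / forcing.f_N
    c_term = _clamp01(c_sto_n / (c_sto_n + params.K_C)) if (c_sto_n + params.K_C) > 0 else 0.0
    n_term = _clamp01((params.N_Sto_max - storage.N_Sto) / params.N_Sto_max) if params.N_Sto_max > 0 else 0.0
    return ceiling * o2_term * c_term * n_term


def biomass_production_rate(params: ModelParameters, storage: StorageState) -> float:
    """Biomass production: Liebig minimum of two Monod terms on the reserves."""
    c_term = storage.C_Sto / (storage.C_Sto + params.K_C) if (storage.C_Sto + params.K_C) > 0 else 0.0
    n_term = storage.N_Sto / (storage.N_Sto + params.K_N) if (storage.N_Sto + params.K_N) > 0 else 0.0
    return params.F_Bio_max * min(c_term, n_term)


def carbon_fixation_rate(
    params: ModelParameters, storage: StorageState, forcing: ForcingState
) -> float:
    """Chlorophyll- and light-limited C fixation.

    Saturating-exponential light response, linear slowdown as C storage
    approaches capacity, and proportionality to the photosynthetic cell
    fraction through the chlorophyll pool Chl_P = f_P * Chl_full.
    """
    if storage.C_Sto > params.C_Sto_max * (1 + 1e-9):
        raise InputDomainError("C_Sto exceeds C_Sto_max")
    light = 1.0 - math.exp(-params.K_I * forcing.I)
    headroom = max(params.C_Sto_max - storage.C_Sto, 0.0)
    chl_p = forcing.f_P * params.Chl_full
    return params.F_Cfix_MaxChl * light * headroom * chl_p


def respiration_P(params: ModelParameters, F_Bio: float) -> float:
    """Respiration in P cells, proportional to biomass production."""
    if F_Bio < 0:
        raise InputDomainError("F_Bio must be >= 0")
    return F_Bio * params.Y_Res_Bio


@dataclass(frozen=True)
class CarbonBudget:
    """The six-way partition of carbon use at one instant.

    Absolute rates [mol C (mol biomass C)^-1 d^-1] plus two fractional
    normalizations: ``fractions_total`` over all C use including storage
    accumulation, ``fractions_nonstorage`` excluding it. Degenerate
    (all-zero) input yields ``valid=False`` and zero fractions rather
    than NaNs.
    """

    F_CSto: float
    F_RP: float
    F_ResN2: float
    F_Nfix_C: float
    F_ResBio: float
    F_Bio: float
    fractions_total: dict
    fractions_nonstorage: dict
    valid: bool


_CATEGORIES = ("F_CSto", "F_RP", "F_ResN2", "F_Nfix_C", "F_ResBio", "F_Bio")


def partition_carbon_budget(
    params: ModelParameters, fluxes: FluxSet, dC_Sto_dt: float
) -> CarbonBudget:
    """Split one step's carbon use into the six budget categories.

    F_ResN2 = Y_ResN2_Nfix * F_Nfix (energetic cost of fixation); F_RP is
    the remaining N-cell respiration. A parameter set whose energetic
    cost exceeds the whole N-cell respiration is rejected as
    misconfigured (Y_ResN2_Nfix too large for the O2 budget).
    """
    f_resn2 = params.Y_ResN2_Nfix * fluxes.F_Nfix
    f_rp = fluxes.F_Res_N - f_resn2
    if f_rp < -1e-9 * max(fluxes.F_Res_N, 1.0):
        raise ParameterError(
            "F_RP would be negative: Y_ResN2_Nfix too large for the N-cell "
            f"respiration budget (F_Res_N={fluxes.F_Res_N:.4g}, "
            f"F_ResN2={f_resn2:.4g})"
        )
    f_rp = max(f_rp, 0.0)
    f_csto = max(dC_Sto_dt, 0.0)
    absolute = {
        "F_CSto": f_csto,
        "F_RP": f_rp,
        "F_ResN2": f_resn2,
        "F_Nfix_C": fluxes.F_Nfix * params.Y_Nfix_CN,
        "F_ResBio": fluxes.F_Res_P,
        "F_Bio": fluxes.F_Bio,
    }
    total = sum(absolute.values())
    nonstorage = total - f_csto
    valid = total > 0.0
    if valid:
        fr_total = {k: v / total for k, v in absolute.items()}
    else:
        fr_total = {k: 0.0 for k in _CATEGORIES}
    if nonstorage > 0.0:
        fr_non = {k: (0.0 if k == "F_CSto" else absolute[k] / nonstorage) for k in _CATEGORIES}
    else:
        fr_non = {k: 0.0 for k in _CATEGORIES}
    return CarbonBudget(
        F_CSto=f_csto,
        F_RP=f_rp,
        F_ResN2=f_resn2,
        F_Nfix_C=absolute["F_Nfix_C"],
        F_ResBio=fluxes.F_Res_P,
        F_Bio=fluxes.F_Bio,
        fractions_total=fr_total,
        fractions_nonstorage=fr_non,
        valid=valid,
    )


def fvfm(forcing: ForcingState, params: ModelParameters) -> float:
    """Trichome-average photosystem II quantum yield.

    Cell-fraction-weighted mean of the per-type endpoint yields
    (photosynthetic cells high, N2-fixing cells low).
    """
    return forcing.f_P * params.FvFm_P + forcing.f_N * params.FvFm_N
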