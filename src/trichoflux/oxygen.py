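"""Pseudo-steady-state oxygen balance of the four-box trichome system.

Oxygen equilibrates on timescales of seconds while the C and N reserves
evolve over hours, so at every step the three box balances (P cells, N
cells, boundary layer) are closed algebraically with the environment held
at a fixed concentration. Fluxes between boxes follow the linear law
J_ij = A_ij ([O2]_i - [O2]_j).

The system has four unknowns ([O2]_P, [O2]_N, [O2]_B and the N-cell
respiration F_Res_N) and three balance equations. The closing constraint
expresses respiratory protection: N cells respire exactly fast enough to
hold their internal O2 at a floor (default 0), *unless* the carbon
available to fuel that respiration runs out, in which case F_Res_N is
capped at the supply and [O2]_N rises freely (carbon-limited regime).
"""

from __future__ import annotations

import numpy as np

from .params import (
    CARBON_LIMITED,
    FULL_SCAVENGING,
    ModelParameters,
    OxygenSolution,
    ParameterError,
)


def diffusive_flux(A_ij: float, O2_i: float, O2_j: float) -> float:
    """Linear diffusive O2 flux from box i to box j (antisymmetric in i, j)."""
    if A_ij < 0:
        raise ParameterError("diffusion coefficient must be >= 0")
    return A_ij * (O2_i - O2_j)


def _assemble_solution(
    params: ModelParameters,
    O2_P: float,
    O2_N: float,
    O2_B: float,
    F_Res_N: float,
    regime: str,
    S_P: float,
) -> OxygenSolution:
    clamped = False
    if min(O2_P, O2_N, O2_B) < 0.0:
        clamped = True
        O2_P, O2_N, O2_B = max(O2_P, 0.0), max(O2_N, 0.0), max(O2_B, 0.0)
    a_pb, a_pn, a_bn, a_be = params.A_PB, params.A_PN, params.A_BN, params.A_BE
    j_pb = diffusive_flux(a_pb, O2_P, O2_B)
    j_pn = diffusive_flux(a_pn, O2_P, O2_N)
    j_bn = diffusive_flux(a_bn, O2_B, O2_N)
    j_be = diffusive_flux(a_be, O2_B, params.O2_env)
    r_vol = F_Res_N * params.Y_O2_C * params.Q_C_conc
    res_p = -j_pb - j_pn + S_P
    res_n = j_pn + j_bn - r_vol
    res_b = -j_be + j_pb - j_bn
    scale = max(abs(S_P), abs(r_vol), a_be * params.O2_env, 1e-300)
    residual = max(abs(res_p), abs(res_n), abs(res_b)) / scale
    return OxygenSolution(
        O2_P=O2_P,
        O2_N=O2_N,
        O2_B=O2_B,
        O2_E=params.O2_env,
        J_PB=j_pb,
        J_PN=j_pn,
        J_BN=j_bn,
        J_BE=j_be,
        F_Res_N=F_Res_N,
        regime=regime,
        clamped=clamped,
        residual=residual,
    )


def solve_oxygen(
    params: ModelParameters,
    F_Cfix: float,
    F_Res_P: float,
    C_supply_max: float,
) -> OxygenSolution:
    """Close the three O2 balances for one instant.

    Parameters
    ----------
    F_Cfix, F_Res_P:
        Biomass-specific gross C fixation and P-cell respiration
        [mol C (mol C)^-1 d^-1]; their difference times Y_O2_C and the
        cellular C concentration is the volumetric O2 source in P cells.
    C_supply_max:
        Maximum biomass-specific rate at which carbon can be oxidized in
        N cells this step (storage drawdown plus surplus fixation).

    Returns an :class:`OxygenSolution` whose ``regime`` records whether
    the O2 floor could be held (``full_scavenging``) or respiration was
    capped by carbon supply (``carbon_limited``).
    """
    a_pb, a_pn, a_bn, a_be = params.A_PB, params.A_PN, params.A_BN, params.A_BE
    if a_be <= 0.0:
        raise ParameterError(
            "A_BE must be > 0: the boundary layer must exchange with the environment"
        )
    if a_pn + a_bn <= 0.0:
        raise ParameterError("N cells are uncoupled: A_PN + A_BN must be > 0")
    yq = params.Y_O2_C * params.Q_C_conc
    S_P = (F_Cfix - F_Res_P) * yq          # volumetric O2 source in P box
    O2_E = params.O2_env
    floor = params.O2_N_floor

    # --- regime 1: pin [O2]_N to the floor, solve for [O2]_P, [O2]_B, F_Res_N
    # P: (a_pb + a_pn) P - a_pb B = S_P + a_pn * floor
    # B: -a_pb P + (a_pb + a_bn + a_be) B = a_be E + a_bn * floor
    m = np.array(
        [[a_pb + a_pn, -a_pb], [-a_pb, a_pb + a_bn + a_be]], dtype=float
    )
    rhs = np.array([S_P + a_pn * floor, a_be * O2_E + a_bn * floor], dtype=float)
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det <= 0.0:
        raise ParameterError("singular diffusion matrix: all couplings zero")
    O2_P = (rhs[0] * m[1, 1] - m[0, 1] * rhs[1]) / det
    O2_B = (m[0, 0] * rhs[1] - m[1, 0] * rhs[0]) / det
    r_vol = a_pn * (O2_P - floor) + a_bn * (O2_B - floor)
    f_res_n = r_vol / yq
    if 0.0 <= f_res_n <= max(C_supply_max, 0.0):
        return _assemble_solution(
            params, O2_P, floor, O2_B, f_res_n, FULL_SCAVENGING, S_P
        )

    # --- regime 2: respiration capped by carbon supply (or floored at 0),
    # solve the full linear system for the three concentrations
    f_res_n = max(min(f_res_n, C_supply_max), 0.0)
    r_vol = f_res_n * yq
    m3 = np.array(
        [
            [a_pb + a_pn, -a_pn, -a_pb],
            [a_pn, -(a_pn + a_bn), a_bn],
            [-a_pb, -a_bn, a_pb + a_bn + a_be],
        ],
        dtype=float,
    )
    rhs3 = np.array([S_P, r_vol, a_be * O2_E], dtype=float)
    try:
        O2_P, O2_N, O2_B = np.linalg.solve(m3, rhs3)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(f"singular diffusion matrix: {exc}") from exc
    return _assemble_solution(params, O2_P, O2_N, O2_B, f_res_n, CARBON_LIMITED, S_P)


def o2_input_partition(solution: OxygenSolution) -> dict:
    """Fractions of the O2 entering N cells via each route.

    Returns ``{"from_P": ..., "from_boundary": ..., "valid": ...}`` where
    the two fractions sum to 1 over the positive inputs J_PN and J_BN.
    Zero (or negative) total input yields ``valid=False`` with zero
    fractions instead of a division error.
    """
    j_pn = max(solution.J_PN, 0.0)
    j_bn = max(solution.J_BN, 0.0)
    total = j_pn + j_bn
    if total <= 0.0:
        return {"from_P": 0.0, "from_boundary": 0.0, "valid": False}
    return {"from_P": j_pn / total, "from_boundary": j_bn / total, "valid": True}
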