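"""Independent reference solvers used only by the tests.

The oxygen oracle solves the pseudo-steady four-unknown system
([O2]_P, [O2]_N, [O2]_B, N-cell respiration) with a generic nonlinear
root-finder on the complementarity formulation, instead of the regime
split + closed-form linear algebra used by the implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root


def brute_force_oxygen(params, F_Cfix, F_Res_P, C_supply_max):
    """Solve the O2 closure by nonlinear root finding.

    Unknowns v = (O2_P, O2_N, O2_B, R) with R the volumetric N-cell
    respiration. The fourth equation is the complementarity condition
    min(O2_N - floor, R_max - R) = 0: either the floor is held or the
    carbon supply is exhausted. Returns (O2_P, O2_N, O2_B, F_Res_N).
    """
    a_pb, a_pn, a_bn, a_be = params.A_PB, params.A_PN, params.A_BN, params.A_BE
    yq = params.Y_O2_C * params.Q_C_conc
    s_p = (F_Cfix - F_Res_P) * yq
    r_max = max(C_supply_max, 0.0) * yq
    floor = params.O2_N_floor
    env = params.O2_env
    scale = max(abs(s_p), a_be * env, 1.0)

    def residuals(v):
        p, n, b, r = v
        return np.array(
            [
                (-a_pb * (p - b) - a_pn * (p - n) + s_p) / scale,
                (a_pn * (p - n) + a_bn * (b - n) - r) / scale,
                (-a_be * (b - env) + a_pb * (p - b) - a_bn * (b - n)) / scale,
                min(n - floor, (r_max - r) / scale),
            ]
        )

    best = None
    for guess in (
        np.array([env, floor, env, min(r_max, a_bn * env)]),
        np.array([env * 2, floor, env, 0.5 * r_max]),
        np.array([env, env, env, r_max]),
        np.array([10 * env, floor, 2 * env, r_max]),
    ):
        sol = root(residuals, guess, method="hybr", tol=1e-14)
        err = np.abs(residuals(sol.x)).max()
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < 1e-11:
            break
    err, x = best
    if err > 1e-8:
        raise RuntimeError(f"oracle failed to converge (residual {err:.3e})")
    p, n, b, r = x
    return p, n, b, r / yq
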