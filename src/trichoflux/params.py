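"""Domain types for the trichome flux model.

The model abstracts a *Trichodesmium* trichome into four well-mixed boxes:
photosynthetic cells (P), nonphotosynthetic cells (N), the diffusive
boundary layer around the filament (B), and the ambient environment (E).
Carbon and nitrogen storage pools are prognostic; oxygen is diagnosed from
a pseudo-steady-state balance each step.

Internal units are SI-based throughout: concentrations in mol m^-3, storage
pools in mol per mol biomass C, rates in mol (mol biomass C)^-1 day^-1,
box-coupling coefficients in day^-1 (per total trichome volume), time in
days for integration and hours for the diel clock.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical domain."""


class InputDomainError(ValueError):
    """Raised when a state or forcing value is outside its physical domain."""


@dataclass
class ModelParameters:
    """All fixed constants of the trichome flux model.

    Rates and yields are biomass-specific (per mol biomass C). Diffusive
    couplings ``A_*_water`` are referenced to the diffusivity of water at
    25 degC; the membrane couplings (P-B, P-N, B-N) are multiplied by
    ``eps_membrane`` (the cell-envelope diffusivity relative to water),
    while the boundary-layer/environment exchange ``A_BE`` is water-side
    and is not scaled.
    """

    # --- N2 fixation (O2-sensitive nitrogenase in a subset of N cells) ---
    F_Nfix_full: float = 0.4          # mol N (mol C)^-1 d^-1 at f_N = 1, unthrottled
    f_NITROGE: float = 1.0            # fraction of N cells containing nitrogenase
    O2_crit: float = 0.01             # mol m^-3; full inhibition above this
    dark_gate_n2fix: bool = True      # force F_Nfix = 0 in darkness

    # --- storage pools ---
    K_C: float = 0.3                  # half-saturation of C storage [mol C (mol C)^-1]
    C_Sto_max: float = 3.0            # C storage capacity
    N_Sto_max: float = 0.15           # N storage capacity [mol N (mol C)^-1]

    # --- biomass production ---
    F_Bio_max: float = 0.339          # mol C (mol C)^-1 d^-1

    # --- light-limited carbon fixation ---
    F_Cfix_MaxChl: float = 1.876       # chlorophyll-specific maximum coefficient
    K_I: float = 0.01                 # light-saturation coefficient [per light unit]
    Chl_full: float = 1.0             # chlorophyll content at f_P = 1 (normalized)

    # --- stoichiometric yields ---
    Y_Nfix_CN: float = 2.0            # mol C (electron donation) per mol N fixed
    Y_Bio_NC: float = 0.2             # N:C of biomass
    Y_Res_Bio: float = 0.4            # respiratory C per C of biomass produced
    Y_O2_C: float = 1.0               # mol O2 per mol C (respiration & fixation)
    Y_ResN2_Nfix: float = 2.39        # respiratory C per mol N fixed (energetics)

    # --- O2 diffusive couplings, water-referenced [day^-1] ---
    A_PB_water: float = 1.31e8
    A_PN_water: float = 6.62e6
    A_BN_water: float = 9.05e7
    A_BE: float = 1.334e5              # boundary layer <-> environment, not scaled
    eps_membrane: float = 1.0e-3      # membrane diffusivity relative to water

    # --- geometry (relative volumes; only scale the pseudo-steady residuals) ---
    V_P_frac: float = 0.8
    V_N_frac: float = 0.2
    V_B_frac: float = 5.0

    # --- environment and cellular composition ---
    O2_env: float = 0.2               # mol m^-3, tropical surface water
    O2_N_floor: float = 0.0           # target O2 in N cells under full scavenging
    Q_C_conc: float = 1.83e4          # cellular carbon concentration [mol C m^-3]

    # --- photophysiology diagnostic ---
    FvFm_P: float = 0.5
    FvFm_N: float = 0.1

    def __post_init__(self) -> None:
        self.validate()

    # effective (membrane-scaled) couplings
    @property
    def A_PB(self) -> float:
        return self.A_PB_water * self.eps_membrane

    @property
    def A_PN(self) -> float:
        return self.A_PN_water * self.eps_membrane

    @property
    def A_BN(self) -> float:
        return self.A_BN_water * self.eps_membrane

    @property
    def K_N(self) -> float:
        """Half-saturation of N storage, tied to K_C by biomass stoichiometry."""
        return self.K_C * self.Y_Bio_NC

    def validate(self) -> None:
        nonneg = (
            "F_Nfix_full", "O2_crit", "K_C", "C_Sto_max", "N_Sto_max",
            "F_Bio_max", "F_Cfix_MaxChl", "K_I", "Chl_full", "Y_Nfix_CN",
            "Y_Bio_NC", "Y_Res_Bio", "Y_O2_C", "Y_ResN2_Nfix", "A_PB_water",
            "A_PN_water", "A_BN_water", "A_BE", "O2_env", "O2_N_floor",
            "Q_C_conc", "FvFm_P", "FvFm_N",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.f_NITROGE <= 1.0:
            raise ParameterError(f"f_NITROGE must be in [0, 1], got {self.f_NITROGE}")
        if not 0.0 < self.eps_membrane <= 1.0:
            raise ParameterError(
                f"eps_membrane must be in (0, 1], got {self.eps_membrane}"
            )
        for name in ("V_P_frac", "V_N_frac", "V_B_frac"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if abs(self.V_P_frac + self.V_N_frac - 1.0) > 1e-9:
            raise ParameterError("V_P_frac + V_N_frac must equal 1 (cell volume basis)")

    def replace(self, **changes) -> "ModelParameters":
        d = asdict(self)
        d.update(changes)
        return ModelParameters(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class ForcingState:
    """Instantaneous diel forcing: irradiance and cell-type fractions."""

    t: float          # time of day [h]
    I: float          # irradiance [model light units]
    f_P: float        # fraction of photosynthetic cells
    f_N: float        # fraction of nonphotosynthetic cells

    def __post_init__(self) -> None:
        if self.I < 0:
            raise InputDomainError(f"irradiance must be >= 0, got {self.I}")
        if not (0.0 <= self.f_P <= 1.0 and 0.0 <= self.f_N <= 1.0):
            raise InputDomainError("cell fractions must lie in [0, 1]")
        if abs(self.f_P + self.f_N - 1.0) > 1e-12:
            raise InputDomainError("f_P + f_N must equal 1")


@dataclass(frozen=True)
class StorageState:
    """Prognostic reserve pools, per mol biomass C."""

    C_Sto: float      # mol C (mol biomass C)^-1
    N_Sto: float      # mol N (mol biomass C)^-1

    def __post_init__(self) -> None:
        if self.C_Sto < 0 or self.N_Sto < 0:
            raise InputDomainError(
                f"storage pools must be >= 0, got C={self.C_Sto}, N={self.N_Sto}"
            )

    def check_capacity(self, params: ModelParameters) -> None:
        if self.C_Sto > params.C_Sto_max * (1 + 1e-9):
            raise InputDomainError("C_Sto exceeds C_Sto_max")
        if self.N_Sto > params.N_Sto_max * (1 + 1e-9):
            raise InputDomainError("N_Sto exceeds N_Sto_max")


FULL_SCAVENGING = "full_scavenging"
CARBON_LIMITED = "carbon_limited"


@dataclass(frozen=True)
class OxygenSolution:
    """Pseudo-steady-state O2 diagnosis for one instant.

    Concentrations are per box [mol m^-3]; fluxes J_ij are positive from
    box i to box j, in mol O2 per total trichome volume per day; F_Res_N
    is the biomass-specific respiration of the N cells required (or
    achievable) to close the balance.
    """

    O2_P: float
    O2_N: float
    O2_B: float
    O2_E: float
    J_PB: float
    J_PN: float
    J_BN: float
    J_BE: float
    F_Res_N: float
    regime: str                     # FULL_SCAVENGING or CARBON_LIMITED
    clamped: bool = False           # a linear solution undershot zero and was clamped
    residual: float = 0.0           # max steady-state residual, source-normalized


@dataclass(frozen=True)
class FluxSet:
    """All biomass-specific C/N fluxes of one time step [mol (mol C)^-1 d^-1].

    ``F_ResN2`` is the energetic respiration cost of N2 fixation
    (Y_ResN2_Nfix * F_Nfix); ``F_RP`` is the remaining N-cell respiration,
    interpreted as respiratory protection; ``F_CSto`` is storage
    accumulation (positive part of dC_Sto/dt); ``F_Nfix_C`` is the carbon
    consumed as electron donation for N2 fixation.
    """

    F_Cfix: float
    F_Bio: float
    F_Nfix: float
    F_Res_P: float
    F_Res_N: float
    F_ResN2: float
    F_RP: float
    F_CSto: float
    F_Nfix_C: float

    @property
    def F_Res(self) -> float:
        return self.F_Res_P + self.F_Res_N
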