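# Model description and numerical methods

## The system

`trichoflux` simulates the diel metabolism of a *Trichodesmium* trichome —
a filament of cyanobacterial cells that fixes both CO₂ and N₂ even though
the nitrogenase enzyme is irreversibly damaged by trace O₂. The filament
is abstracted into four well-mixed boxes: photosynthetic cells (P),
nonphotosynthetic cells (N, a fraction of which carry nitrogenase), the
diffusive boundary layer around the filament (B), and the ambient
environment (E, an infinite reservoir). All fluxes and concentrations are
normalized to the total trichome volume, so the model represents any
number of cells with given type fractions f_P and f_N = 1 − f_P.

Two slow prognostic reserves are integrated in time:

- C_Sto — carbohydrate storage [mol C (mol biomass C)⁻¹],
- N_Sto — nitrogen storage [mol N (mol biomass C)⁻¹],

with budgets

    dC_Sto/dt = F_Cfix − F_Bio − F_Nfix·Y_Nfix^C:N − F_Res
    dN_Sto/dt = F_Nfix − F_Bio·Y_Bio^N:C

Oxygen, by contrast, is fast: cellular C and N concentrations are of
order 10⁴ and 10³ mol m⁻³ while O₂ stays below 1 mol m⁻³, so the O₂
pools equilibrate in seconds. The three box O₂ balances are therefore
closed algebraically at every step (pseudo-steady state), with linear
diffusive exchange J_ij = A_ij([O₂]_i − [O₂]_j).

## Flux laws

- **C fixation** F_Cfix = F_Cfix^MaxChl · (1 − e^(−K_I·I)) · (C_Sto^max −
  C_Sto) · f_P·Chl_full: saturating-exponential light response, linear
  shutdown as storage fills, chlorophyll proportional to the P-cell
  fraction (constant light during the photoperiod makes per-cell
  chlorophyll effectively constant).
- **Biomass production** F_Bio = F_Bio^max · min(C-Monod, N-Monod), a
  Liebig minimum on the two reserves, with K_N = K_C·Y_Bio^N:C.
- **P-cell respiration** F_Res^P = Y_Res:Bio · F_Bio (biosynthesis cost,
  assumed to occur in P cells).
- **N₂ fixation** F_Nfix = F_Nfix^full·f_N·f_NITROGE × (linear O₂
  inhibition below [O₂]_crit) × (Monod on C_Sto/f_N, the storage
  accessible to N cells) × (linear inhibition as N_Sto fills). Each
  factor is clamped to [0, 1]. An optional dark gate (default on) forces
  F_Nfix = 0 when I = 0, reproducing the observed shutdown at
  lights-off; the underlying energetic mechanism is not modeled, so the
  gate is an explicit switch rather than an emergent property.
- **N-cell respiration** F_Res^N is *not* a prescribed law — it is the
  diagnosed oxygen-scavenging rate, see below. Its partition into the
  energetic cost of fixation (F_ResN2 = Y_ResN2:Nfix·F_Nfix) and the
  remainder (respiratory protection, F_RP) is diagnostic only.

## The oxygen closure

With [O₂]_E fixed, the three steady balances have four unknowns
([O₂]_P, [O₂]_N, [O₂]_B, F_Res^N). The closing constraint encodes
respiratory protection: N cells respire exactly fast enough to hold
their internal O₂ at a floor (default 0 mol m⁻³). This gives a 2×2
linear system for [O₂]_P and [O₂]_B and an explicit F_Res^N
(full-scavenging regime). If that F_Res^N exceeds the carbon available
this step (storage drawdown + fixation surplus after P-cell
commitments), respiration is capped at the supply and the full 3×3
linear system is solved for the concentrations; [O₂]_N then rises and
throttles N₂ fixation through its inhibition factor (carbon-limited
regime). The two regimes agree identically at the crossover. Residuals
of the steady-state equations are checked against 10⁻¹⁰ of the largest
source term. Extreme parameter draws can push a linear solution slightly
negative; concentrations are then clamped at zero and flagged
(`clamped=True`) rather than aborting the run.

The membrane diffusivity enters as one scalar: A_PB, A_PN, A_BN are
water-referenced couplings multiplied by eps_membrane (default 10⁻³, a
cell-envelope diffusivity relative to water). A_BE is water-side
exchange and is never scaled — the diffusivity sweep therefore varies
only the cell-envelope barrier, as the sensitivity analysis intends.

## Forcing and integration

Forcing is a 24-h cycle: constant irradiance I_light over hours [0, 12),
darkness over [12, 24), and a prescribed piecewise-constant f_P — 0.8
over [0, 3), 0.55 over [3, 9) (the midday commitment of ~45% of cells to
N₂ fixation), 0.8 over [9, 24). Transitions are exact steps so their
effects are clearly discernible in the output; f_P is prescribed, not
emergent.

Integration is explicit Euler at dt = 0.001 day (86.4 s). Stiffness
lives entirely in the O₂ subsystem, which the algebraic closure removes;
halving dt moves the end-of-day reserves by well under 1% (tested
against dt/2 and dt/10 references). A positivity limiter rescales, in
priority order, F_Bio (with its coupled respiration), F_Nfix, and
F_Res^N whenever a step would overdraw a reserve; capacity overshoot is
clamped at C_Sto^max / N_Sto^max. Off the limiter, per-step C and N
budgets close to round-off (tested).

Runs default to 4 days: 3 spin-up days plus one analysis day. The
default initial condition is the dawn state of the diel limit cycle of
the calibrated defaults (C_Sto = 0.0342, N_Sto = 0.0497), precomputed by
`trichoflux.calibrate.attractor_state` from a 40-day integration and
committed as constants. Starting on the attractor makes the standard
3-day spin-up satisfy diel periodicity to ≪0.1% (from an arbitrary
state, the attractor contraction is ≈0.65/day and convergence to that
tolerance would need ~2 weeks of simulated time). Storage is most
depleted just before dawn, consistent with observations of diel
carbohydrate cycling.

## Parameters

Values taken from published measurements: cellular carbon concentration
Q_C = 1.83 × 10⁴ mol C m⁻³; environmental O₂ 0.2 mol m⁻³ (tropical
surface water); Fv/Fm endpoints 0.5 (photosynthetic) and 0.1 (N₂-fixing
phase); biomass N:C = 0.2; photosynthetic/respiratory quotient Y_O2:C =
1; eps_membrane = 10⁻³ (upper bound inferred for multilayer Gram-negative
envelopes).

The remaining rate constants and couplings are not directly measurable
and were calibrated (once, by `trichoflux.calibrate`, a least-squares
match in log-parameter space over converged diel cycles) so that the
spun-up default run reproduces the observed diel anchors: daytime
respiration ≈ 2 mol O₂ (mol C)⁻¹ d⁻¹; >80% of light-period non-storage
carbon use as respiratory protection (hence a realized growth rate ≈20%
of potential); boundary-layer O₂ ≈ 400 μM at the early peak, ≈ 300 μM at
midday, < 200 μM at night; >80% of N-cell O₂ input via the boundary
layer; and daily-mean rates inside the observed envelopes (N₂ fixation
0.006–0.146, net C fixation 0.16–2.57, O₂ production 1.10–288 mol (mol
biomass C)⁻¹ d⁻¹). The calibrated values are committed both as the
dataclass defaults and as `data/default_config.yaml` (annotated with
provenance). Notable calibrated values: F_Cfix^MaxChl = 1.876 d⁻¹,
F_Bio^max = 0.339 d⁻¹, Y_ResN2:Nfix = 2.39 mol C (mol N)⁻¹, couplings
A_PB/A_PN/A_BN = 1.31 × 10⁸ / 6.62 × 10⁶ / 9.05 × 10⁷ d⁻¹
(water-referenced) and A_BE = 1.334 × 10⁵ d⁻¹.

The box volume fractions V_P, V_N, V_B appear only in the time-derivative
terms that the pseudo-steady closure sets to zero; they are retained in
the parameter set for completeness but do not influence the algebraic
solution.

## Diagnostics and conventions

- Epochs on the analysis day follow the f_P step boundaries: early light
  [0, 3) h, midday [3, 9) h, evening [9, 12) h, dark [12, 24) h.
- The respiratory-protection share is ∫F_RP / ∫(F_Bio + F_Res + F_Nfix
  electron-donation C), excluding storage accumulation from the
  denominator; during darkness all consumption is storage-derived, so
  the two normalizations coincide there. Both normalizations are
  available from `partition_carbon_budget`.
- The growth handicap is the complement of the light-phase protection
  share: the effective biomass yield of fixed carbon relative to the
  yield with the protection flux removed from the budget.
- O₂ turnover time is [O₂] / (respiration·Q_C/86400): ≈0.5 s at ambient
  concentrations and ≈1.4 s at P-cell concentrations for a respiration
  of 2 mol O₂ (mol C)⁻¹ d⁻¹ — far shorter than the minutes-scale
  switching of photosynthetic activity, which motivates the pseudo-steady
  treatment.
- Concentrations are SI (mol m⁻³) internally and converted to μM
  (× 1000) only at reporting boundaries.

## What the model does and does not represent

The forcing and parameters emulate laboratory diel cycles of cultured
*Trichodesmium*: constant photoperiod light, abrupt prescribed cell-type
shifts, no nutrient (Fe/P) limitation, no colony morphology beyond the
single boundary-layer box, no spatial structure along the filament, no
per-cell stochasticity, and no explicit EPS or "buffer cell" mechanics.
Nighttime N₂-fixation shutdown is imposed (the dark gate), not derived
from energetics. Passing tests therefore demonstrate the internal
consistency of this idealized diel machine and its agreement with the
compiled observational anchors — not predictive skill against any
particular culture's time series. The smooth dawn/dusk transitions,
variable light fields and nutrient co-limitation of real populations are
outside its scope.

## Known limitations

- The carbon-supply ceiling offered to the O₂ closure includes the whole
  storage pool per step (storage/dt), so in the carbon-limited regime
  the instantaneous supply is dt-dependent; under the defaults this
  regime never activates (it appears in the diffusivity sweep above ~2×
  the default membrane diffusivity, where it is the phenomenon of
  interest rather than a numerical artifact).
- Explicit Euler is first-order; the committed dt = 0.001 day makes the
  discretization error (<1%) negligible against parameter uncertainty,
  but users lowering storage capacities or raising rate ceilings by
  orders of magnitude should re-run the dt-halving check.
- The calibration is under-determined: other knob combinations can match
  the same anchors. The committed set is one reproducible solution of
  the committed routine, not a unique inference.
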