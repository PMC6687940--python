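# trichoflux

A mechanistic four-compartment flux model of a *Trichodesmium* trichome,
resolving the diel coexistence of photosynthesis and N₂ fixation.

*Trichodesmium* is a colonial marine cyanobacterium responsible for a
large share of oceanic N₂ fixation. Its paradox: nitrogenase is
destroyed by trace O₂, yet the organism fixes N₂ **during the day**,
while photosynthesizing, and without the heterocysts other
cyanobacteria use for protection. `trichoflux` is a box model for
exploring how the three postulated mechanisms — division of labor along
the filament, respiratory O₂ scavenging ("respiratory protection"), and
strong cell-envelope diffusion barriers — combine to make this possible,
and what each costs in carbon.

The package is aimed at microbial oceanographers and modelers who want a
fast, transparent diel simulator of diazotroph energetics: every flux
law is a few lines, a 4-day run takes a fraction of a second, and every
published diel statistic is a one-line diagnostic.

## Model

Four well-mixed boxes: photosynthetic cells (P), nonphotosynthetic cells
(N), boundary layer (B), environment (E). Two prognostic reserves per
mol biomass C:

    dC_Sto/dt = F_Cfix − F_Bio − F_Nfix·Y_Nfix^C:N − F_Res
    dN_Sto/dt = F_Nfix − F_Bio·Y_Bio^N:C

with Monod/Liebig resource limitation (F_Bio), a saturating-exponential
light response with storage-capacity shutdown (F_Cfix), and an
N₂-fixation law F_Nfix throttled by linear O₂ inhibition, the C storage
accessible to N cells, and N-storage filling. Oxygen is fast relative to
the reserves and is closed algebraically each step (pseudo-steady
state): N cells respire exactly fast enough to hold internal O₂ at a
floor — unless carbon runs out, in which case respiration is capped and
[O₂]_N rises, throttling fixation. Diffusive exchange between boxes is
linear, J_ij = A_ij([O₂]_i − [O₂]_j), with cell-envelope couplings
scaled by a membrane/water diffusivity ratio (default 10⁻³).

Forcing is a 12 h/12 h light–dark cycle with the photosynthetic cell
fraction stepping 0.8 → 0.55 → 0.8 at hours 3 and 9 (midday commitment
of ~45% of cells to N₂ fixation). See `docs/methods.md` for the full
equations, the oxygen closure, parameter provenance and calibration.

## Worked example

```python
import trichoflux as tf
from trichoflux import diagnostics as dg

params = tf.ModelParameters()          # committed calibrated defaults
result = tf.run(params, days=4)        # 3 spin-up days + 1 analysis day

stats = dg.boundary_layer_stats(result)
print(f"light-period respiratory-protection share: "
      f"{100*dg.respiratory_protection_fraction(result, 'light'):.1f} %")
print(f"realized mu_max: {dg.mu_max_handicap(result):.1f} % of potential")
print(f"daytime respiration: "
      f"{dg.daily_mean_rates(result)['daytime_respiration']:.2f} mol O2 (mol C)^-1 d^-1")
print(f"boundary-layer O2: early peak {stats.early_peak_uM:.0f} uM, "
      f"midday mean {stats.midday_mean_uM:.0f} uM, dark max {stats.dark_max_uM:.0f} uM")
print(f"O2 into N cells via boundary layer: "
      f"{100*dg.boundary_o2_input_fraction(result, 'light'):.1f} %")
print(f"O2 turnover at 0.2 mol m^-3: "
      f"{dg.o2_turnover_time(0.2, 2.0, params.Q_C_conc):.2f} s")
```

prints

```
light-period respiratory-protection share: 80.6 %
realized mu_max: 19.4 % of potential
daytime respiration: 2.00 mol O2 (mol C)^-1 d^-1
boundary-layer O2: early peak 406 uM, midday mean 297 uM, dark max 115 uM
O2 into N cells via boundary layer: 86.6 %
O2 turnover at 0.2 mol m^-3: 0.47 s
```

In words: during the photoperiod four fifths of all carbon consumed
(storage accumulation aside) is burned purely to scavenge O₂ out of the
N₂-fixing cells — which is why the realized growth rate is only ~20% of
what the same photosynthetic machinery could support, matching the low
growth rates observed for this genus. Most of that O₂ arrives from the
supersaturated boundary layer (~300–400 μM by day, dipping below ambient
at night), not directly from neighboring photosynthetic cells. And an
O₂ residence time of half a second means a cell that stops
photosynthesizing is effectively anoxic within seconds.

A command-line interface mirrors the library:

```
trichoflux simulate --out run1/           # tidy CSV + JSON summary
trichoflux sweep --multipliers 0.5,1,2,3,water --out sweep.csv
trichoflux diagnose run1/
trichoflux make-default-config --out default.yaml
trichoflux calibrate --out recalibrated.yaml
```

The diffusivity sweep reproduces the sensitivity of the O₂ budget to the
membrane barrier: above ~2× the default diffusivity the N cells can no
longer be kept anoxic (carbon-limited episodes appear), above ~3× the
boundary layer loses its contrast with the environment, and at water
diffusivity all four boxes equilibrate and N₂ fixation collapses.

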