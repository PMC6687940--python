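# trichoflux calibrated default configuration (schema v1)
# Keys marked [obs] are taken from published measurements;
# unmarked rate/coupling values come from the calibration routine
# (trichoflux.calibrate) that matches the observed diel anchors.

schema_version: 1
parameters:
  F_Nfix_full_molN_per_molC_per_day: 0.4
  f_NITROGE: 1.0
  O2_crit_mol_per_m3: 0.01
  dark_gate_n2fix: True
  K_C_molC_per_molC: 0.3
  C_Sto_max_molC_per_molC: 3.0
  N_Sto_max_molN_per_molC: 0.15
  F_Bio_max_per_day: 0.339
  F_Cfix_MaxChl_per_day_per_chl: 1.876
  K_I_per_light_unit: 0.01
  Chl_full_relative: 1.0
  Y_Nfix_CN_molC_per_molN: 2.0
  Y_Bio_NC_molN_per_molC: 0.2  # [obs] biomass N:C stoichiometry
  Y_Res_Bio_molC_per_molC: 0.4
  Y_O2_C_molO2_per_molC: 1.0  # [obs] photosynthetic/respiratory quotient
  Y_ResN2_Nfix_molC_per_molN: 2.39
  A_PB_water_per_day: 131000000.0
  A_PN_water_per_day: 6620000.0
  A_BN_water_per_day: 90500000.0
  A_BE_per_day: 133400.0
  eps_membrane: 0.001  # [obs] upper bound on membrane/water diffusivity ratio
  V_P_frac: 0.8
  V_N_frac: 0.2
  V_B_frac: 5.0
  O2_env_mol_per_m3: 0.2  # [obs] typical tropical surface-water O2
  O2_N_floor_mol_per_m3: 0.0
  Q_C_conc_molC_per_m3: 18300.0  # [obs] published cellular C concentration
  FvFm_P: 0.5  # [obs] observed quantum yield, photosynthetic phase
  FvFm_N: 0.1  # [obs] observed quantum yield, N2-fixing phase
forcing:
  I_light: 200.0
  light_start_h: 0.0
  light_end_h: 12.0  # [obs] 12-h/12-h light-dark cycle
  f_P_steps:  # [obs] photosynthetic fraction steps 0.8 / 0.55 / 0.8
    0.0: 0.8
    3.0: 0.55
    9.0: 0.8
run:
  days: 4
  dt_days: 0.001
  spinup_days: 3
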