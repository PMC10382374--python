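# Default model constants for the transdermal-fentanyl digital twin.
#
# Internal canonical units are seconds, meters, liters and ng/ml; keys carry
# the unit they are stated in and the loader converts at the boundary.

skin:
  # Stratum-corneum thickness [um]:
  #   (sc_slope_um_per_year * age + sc_base_um * (gender + (1 - gender) * sc_female_factor)) * exp(theta)
  sc_slope_um_per_year: 0.125
  sc_base_um: 11.80
  sc_female_factor: 1.40
  # Optional global multiplier on the SC formula (1.0 = literal formula).
  sc_calibration_factor: 1.0
  # Viable-epidermis thickness [um]:
  #   vep_base_um * (gender + (1 - gender) / vep_female_divisor) * exp(theta)
  # vep_base_um is calibrated so the reference-population mean is 29.7 um.
  vep_base_um: 31.085
  vep_female_divisor: 1.11
  # Equivalent dermis thickness: BMI-linear expression in mm,
  #   gender branch: slope * BMI + intercept   [mm]
  # multiplied by the dimensionless age-scaling ratio (calibrated so the
  # reference-population mean is 242.6 um) and exp(theta).
  edm_male_slope: 0.0369
  edm_male_intercept: 0.9531
  edm_female_slope: 0.0325
  edm_female_intercept: 0.8915
  edm_age_scaling_ratio: 0.13402
  bmi_valid_range: [15.0, 45.0]

patch:
  thickness_um: 50.8
  area_cm2: 31.5        # linear area-strength scaling: 31.5 cm^2 for 75 ug/h
  load_mg: 12.6
  nominal_flux_ug_h: 75.0

transport:
  # Diffusivities [m^2/s]; one epidermis value serves both SC and viable
  # epidermis, the dermis value the equivalent-dermis layer.
  D_patch: 6.91e-16
  D_epidermis: 3.02e-14
  D_dermis: 3.84e-11
  # Capacities (dimensionless); only ratios matter: K_patch/K_epidermis =
  # 1/3.4 = 0.29 and K_epidermis/K_dermis = 1.
  K_patch: 1.0
  K_sc: 3.4
  K_vep: 3.4
  K_dermis: 3.4

pk_reference:
  # Unbound fraction of fentanyl in plasma.
  f_u: 0.20
  # Reproduce the printed Eq-4 renal-term sign (renal clearance as a source)
  # instead of treating it as elimination.
  literal_eq4_sign: false
  # Apply the unbound fraction only inside the central balance (the literal
  # printed placement) instead of gating the full transfer flux.  The literal
  # reading creates mass in every central->tissue transfer and is unstable.
  literal_fu_central_only: false
  # Reference volumes [L] and effective inter-compartment clearances [L/min]
  # for a 70-kg reference male / female.  Volumes are lumped-organ
  # physiological values (central = blood + lungs; rapid = brain, heart,
  # skin, kidneys; slow = muscle, fat, carcass; gut = gut, spleen, pancreas;
  # liver).  Flows are effective clearances calibrated so the simulated
  # plasma kinetics of a 75 ug/h patch reproduce published fentanyl
  # behaviour; anatomical perfusion rates are not identifiable in this
  # lumped structure.
  male:
    V_central_L: 6.0
    V_rapid_L: 5.6
    V_slow_L: 45.0
    V_gut_L: 1.65
    V_liver_L: 1.8
    Q_central_rapid_L_min: 15.0
    Q_central_slow_L_min: 7.5
    Q_central_gut_L_min: 4.0
    Q_central_liver_L_min: 2.0
    Q_gut_liver_L_min: 0.8
    Q_liver_central_L_min: 1.2
    CL_hepatic_L_min: 0.85
    CL_renal_L_min: 0.28
  female:
    V_central_L: 5.4
    V_rapid_L: 5.1
    V_slow_L: 42.0
    V_gut_L: 1.5
    V_liver_L: 1.55
    Q_central_rapid_L_min: 13.5
    Q_central_slow_L_min: 6.8
    Q_central_gut_L_min: 3.6
    Q_central_liver_L_min: 1.8
    Q_gut_liver_L_min: 0.72
    Q_liver_central_L_min: 1.08
    CL_hepatic_L_min: 0.78
    CL_renal_L_min: 0.25

pd:
  vas:
    k_e_per_s: 2.0e-3
    E0: 8.0
    Emax: 8.0
    gamma: 2.71
    # Patient-specific EC50 [ng/ml]: ec50_age_slope * age + ec50_intercept
    ec50_age_slope_per_year: -1.148e-2
    ec50_intercept_ng_ml: 1.96
  ventilation:
    k_e_per_s: 7.0e-4
    E0_L_min: 20.0
    Emax_fraction: 0.91
    ec50_ng_ml: 1.14
    gamma: 2.69

variability:
  # Lognormal inter-individual variability: each physiology-derived
  # parameter is multiplied by exp(theta), theta ~ Normal(0, sd_theta),
  # putting ~95% of values within +-20% of the deterministic formula.
  sd_theta: 0.1

policy:
  kind: twin_assisted
  check_interval_h: 8.0
  vas_target: 3.0
  replacement_interval_h: 72.0
  horizon_h: 72.0

numerics:
  # Finite-volume cells per layer (patch, SC, viable epidermis, dermis);
  # geometric grading toward layer interfaces.
  n_cells_per_layer: [28, 20, 20, 32]
  interface_refinement: 2.0
  rtol: 1.0e-6
  atol: 1.0e-9
  max_step_h: 6.0
  output_step_h: 1.0
  # Keep the residual skin depot of a replaced patch releasing (true) or
  # retire the old site entirely (false).
  residual_depot: true

thresholds:
  toxicity_ng_ml: 2.0          # alternative printed value: 3.0
  hypoventilation_L_min: 4.0
  pain_free_vas: 3.0
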