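# Default simulation parameters for microstoich.
#
# This file is the single source of the shipped defaults; SimulationParams
# loads it at import time.  Keys marked "paper-fixed" are structural model
# constants and may only be changed with an explicit override flag in
# load_config().  All other rate constants are calibration decisions of this
# implementation; the bracketed ranges are the documented calibration ranges
# within which the defaults were chosen (once) so that a uniform-population
# run at litter C:N 50 loses ~60% of its mass in ~40 simulated weeks.
#
# Units: fmol C (or N) per microsite; one time step = 3 h.

schema: microstoich-params-v1

# --- enzymatic degradation (classes: plant, MR-C, MR-N) ---------------------
vmax: [0.55, 2.0, 1.5]      # fmol C degraded per fmol enzyme C per step  [0.1-5]
km: [10.0, 10.0, 10.0]       # half-saturation, fmol C per microsite       [5-1000]

# --- microbial physiology ---------------------------------------------------
uptake_coeff: 0.2            # max DOC uptake per (fmol biomass C)^(2/3) per step [0.05-1]
surface_exponent: 0.6666666666666666   # surface/volume scaling of uptake capacity
maintenance_fract: 0.0017    # C respired per biomass C per step           [0.001-0.02]
resp_growth: 0.2             # overhead respiration per C grown            [0.1-0.6]
resp_enz: 0.2                # overhead respiration per enzyme C produced  [0.1-0.6]
constitutive_fract: 0.1      # paper-fixed: one tenth of maximal enzyme production
enzyme_cn: 5.0               # enzymes are protein, C:N = 5
enzyme_lifetime: 20.0        # mean active steps before shift to MR-N      [8-240]

# --- transport --------------------------------------------------------------
diff_dom: 0.1                # fraction of site DOM exchanged per step     [0.05-0.8]
diff_din: 0.9                # fraction of site DIN exchanged per step     [0.05-0.9]
leach_fract: 0.002           # fraction of diffusing material leached      [0-0.05]

# --- demography -------------------------------------------------------------
mortality_ref: 0.001         # per-step catastrophic-death prob at MCS = mcs_ref [0.0005-0.01]
mcs_ref: 100.0               # reference MCS for the inverse mortality scaling
starvation_min: 0.05         # death when biomass < this fraction of MCS   [0.02-0.5]
invade_prob: 0.01            # paper-fixed: invasion probability of occupied sites
colonise_neighbourhood: moore

# --- initial state ----------------------------------------------------------
grid_size: 100               # paper-fixed: 100 x 100 microsites
init_plant_c: 3000.0         # fmol C plant material per microsite         [1000-10000]
init_occupancy: 0.05         # fraction of sites seeded per functional group [0.01-0.2]
init_din: 1.0                # fmol N per microsite                        [0-20]
init_dom_c: 5.0              # fmol C per microsite                        [0-100]
init_dom_cn: 15.0            # C:N of initial DOM (cell-soluble-like)
init_enzyme_c: 0.3           # fmol active enzyme C per microsite at t=0   [0-10]

# --- run control ------------------------------------------------------------
steps_max: 20000
mass_loss_stop: 0.9
step_hours: 3.0              # paper-fixed: one step = 3 h

# --- fixed component stoichiometry (paper-fixed) ----------------------------
component_cn:
  dom: 15.0
  mrc: 150.0
  mrn: 5.0
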