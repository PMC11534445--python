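# Default scavsim run configuration.
#
# Biomass densities are in ton/ha, time in years, rates in 1/yr.
# Every key is optional; anything omitted falls back to the calibrated
# defaults of the model. Unknown keys are rejected.

# Parameter overrides (flat mapping; keys are the model symbols).
params: {}
  # C_VS: 0.036      # vegetation -> scavenger conversion
  # carrion_dialect: literal   # or "proportional"

# Solver settings.
settings:
  t_end: 250.0       # simulation horizon (years)
  output_step: 1.0   # output grid spacing (years)
  rtol: 1.0e-8
  atol: 1.0e-10
  extinction_floor: 1.0e-12

# Factorial scenario grid: presence combinations x hunting targets x
# leftover fractions (targets and leftovers vary jointly for deer and boar).
grid:
  targets: [0.0, 0.5, 1.0]     # hunting target biomass (ton/ha)
  leftovers: [0.0, 0.5, 1.0]   # fraction of hunted biomass left in the field
  presence:                    # [boar_present, wolf_present]
    - [true, true]
    - [true, false]
    - [false, true]
    - [false, false]
  hunting_rate: 1.0            # shared hunting rate H (1/yr)

# Initial biomasses for guilds that are present.
initial:
  V: 5.0
  D: 0.5
  B: 0.5
  S: 0.1
  W: 0.05

# Sensitivity design (used by `scavsim sensitivity`).
sensitivity:
  varied: [C_VS]
  factors: [0.7, 1.0, 1.3]

# Where to write the run bundle.
output: scavsim_output

# Reserved; the pipeline is deterministic and uses no random numbers.
seed: 0
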