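# Example simulation config for `maternet simulate` / `maternet run`.
#
# Any omitted entry keeps the built-in preset value.  The fragmentation
# values (per-slot switch probabilities) and the repertoire vectors are
# tuning choices of the synthetic generator -- no dwell-time measurements
# exist to calibrate them against -- chosen so that the simulated housing
# effects have the documented direction (see docs/methods.md).

seed: 0
n_dams_per_group: 9
ppd_min: 2
ppd_max: 9

# Per-profile overrides.  Profiles: ctrl_light, ctrl_dark, lbn_light, lbn_dark.
# Fields: fragmentation, day_drift, initial_dist (7 floats over
# HG, LW, SUP, L, HG/L, DN, OFF), switch_kernel (7x7 rows, zero diagonal).

lbn_dark:
  # Elevated switch probability: the fragmented-care condition.
  fragmentation: 0.50
  day_drift: -0.015

ctrl_dark:
  fragmentation: 0.35
  day_drift: -0.015
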