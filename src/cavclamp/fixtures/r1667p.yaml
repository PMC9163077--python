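# R1667P mutant CaV2.1 genotype fixture.
#
# Relative to wild type: ~10 mV hyperpolarized activation, slower
# activation (tau_act(+20) = 1.8 ms) and deactivation, and a much lower
# conductance density (calibrated so the noiseless single-cell peak
# current density at 0 mV is -9.6 pA/pF).
label: R1667P
gating:
  act_vhalf: -10.0      # mV
  act_slope: 6.6        # mV
  act_tau:              # bell profile, ms / mV
    tau_min: 0.3
    amp: 4.254356
    v_center: -5.0
    slope_left: 40.0
    slope_right: 30.0
  inact_vhalf: -42.1    # mV
  inact_slope: -10.7    # mV
  inact_tau:
    tau_min: 600.0
    amp: 400.0
    v_center: -40.0
    slope_left: 60.0
    slope_right: 60.0
gmax_density: 0.175805  # nS/pF (calibrated; see above)
erev: 70.0              # mV
gleak_density: 0.02     # nS/pF
eleak: 0.0              # mV
cm: 23.0                # pF
ra: 4.9                 # MOhm
noise_sd: 0.4           # pA/pF per sample
variability:
  act_vhalf: 2.5        # mV
  act_slope: 0.8        # mV
  inact_vhalf: 4.0      # mV
  inact_slope: 2.0      # mV
  tau_act_scale: 0.15
  tau_inact_scale: 0.15
  ra: 1.0               # MOhm
  gmax_density: 0.33    # sigma of log
  cm: 0.2               # sigma of log
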