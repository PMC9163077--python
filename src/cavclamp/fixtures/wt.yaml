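# Wild-type CaV2.1 genotype fixture.
#
# Gating midpoints/slopes are the cohort-mean fitted values the pipeline
# is expected to report; the activation tau profile is calibrated so that
# tau_act(+20 mV) = 0.7 ms; gmax_density is calibrated so the noiseless
# single-cell peak current density at +10 mV is -34.9 pA/pF.  Variability
# dispersions are chosen so cohort SEMs at the study cell counts are of
# the order of the reported SEMs.
label: WT
gating:
  act_vhalf: 0.9        # mV
  act_slope: 5.4        # mV
  act_tau:              # bell profile, ms / mV
    tau_min: 0.15
    amp: 3.383993
    v_center: -5.0
    slope_left: 15.0
    slope_right: 14.0
  inact_vhalf: -39.3    # mV
  inact_slope: -12.6    # mV
  inact_tau:            # slow closed-state inactivation, ~1 s near -40 mV
    tau_min: 600.0
    amp: 400.0
    v_center: -40.0
    slope_left: 60.0
    slope_right: 60.0
gmax_density: 0.725336  # nS/pF (calibrated; see above)
erev: 70.0              # mV
gleak_density: 0.02     # nS/pF
eleak: 0.0              # mV
cm: 23.0                # pF
ra: 4.9                 # MOhm
noise_sd: 0.4           # pA/pF per sample
variability:
  act_vhalf: 2.5        # mV (normal sd)
  act_slope: 0.8        # mV
  inact_vhalf: 4.0      # mV
  inact_slope: 2.0      # mV
  tau_act_scale: 0.15   # fractional (normal sd)
  tau_inact_scale: 0.15
  ra: 1.0               # MOhm
  gmax_density: 0.33    # sigma of log (lognormal, unit mean)
  cm: 0.2               # sigma of log
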