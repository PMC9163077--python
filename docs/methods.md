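# Methods

## Model

The simulator is a single-compartment whole-cell clamp. The command
potential charges the membrane through the access resistance,
`dVm/dt = (Vcmd − Vm)/(Ra·Cm)`; with `Ra = 0` the membrane follows the
command exactly. Channel gating is first order: one Boltzmann activation
gate `m` (slope factor k > 0) and one slow closed-state availability gate
`h` (k < 0), each relaxing mono-exponentially toward its steady state with
a voltage-dependent time constant

    tau(V) = tau_min + amp / (exp((V − v_center)/slope_right)
                              + exp(−(V − v_center)/slope_left)),

a strictly positive bell bounded by `tau_min + amp`. The recorded current
is `Cm·[g_leak(Vm − E_leak) + g_max·m·h·(Vm − E_rev)] + Cm·dVm/dt` plus
white Gaussian noise of sd `noise_sd·Cm` per 10-µs sample. The driving
force is linear with `E_rev = +70 mV`; Goldman–Hodgkin–Katz permeation,
open-state (voltage-/Ca²⁺-dependent) inactivation, gate cooperativity and
series-resistance compensation artifacts are deliberately out of scope.

Because `Vm` is independent of the gates and the command is piecewise
linear, `Vm(t)` has a closed form on every segment. The gates are advanced
with exponential-Euler steps (midpoint `Vm`) while the clamp settles or
during ramps, and with the exact constant-voltage relaxation elsewhere, so
step responses are not discretized at all. Sweeps start from the
holding-potential steady state, emulating the 10-s inter-sweep interval.
The integration step must resolve the fastest activation time constant
(`dt ≤ min tau_act/5`) and at least coarsely resolve the membrane charging
(`dt ≤ Ra·Cm/2`); the default `dt = 10 µs` corresponds to 100 kHz
digitization.

## Protocols

Six named protocols cover the study: `step_iv` (25-ms steps, −50…+80 mV
in 10-mV increments, repolarization to −40 mV), `deactivation` (+30 mV
prepulse, tails at −50…−20 mV), `closed_state_inactivation` (5-s
conditioning at −100…+30 mV, 5-ms return to −80 mV, 25-ms test step to
+20 mV), `ap_ramp` (1-ms ramp −80→+30 mV, 1-ms ramp back, averaged over
10 repeats), `reversal_tail` (25 ms at +70 mV, near the reversal
potential, then −40 mV) and `cm_test` (5-ms step from −80 to −70 mV,
uncompensated). All protocols except `cm_test` carry a −P/4 policy: four
sub-sweeps at −1/4 of the main deviation from the −80 mV holding
potential, delivered per repeat; the combine rule
`(main − baseline) + Σ(sub − baseline)` cancels any current affine in the
command deviation exactly (verified to < 1e−9 pA on pure-leak cells).

### Desk-scale inactivation

Closed-state inactivation in this channel relaxes on the ~1-s scale, so
the full protocol conditions for 5 s. The packaged studies default to a
fast variant in which every inactivation-relevant interval and the h-gate
time constants are scaled by the same factor of 10: tau profile ÷10,
conditioning 0.5 s, return-to-holding gap 0.5 ms. Scaling the gap along
with the kinetics keeps the fraction of channels recovering before the
test step identical to the full-length protocol; the shorter gap leaves a
small residual activation in slowly deactivating cells, which the
fixed-cursor amplitude measurement (below) renders harmless because all
sweeps have converged to a common gating trajectory well before the
cursor. The full 5-s protocol remains available
(`StudyConfig(fast_inact=False)`) and is what the noiseless recovery tests
use; its residual midpoint bias is below 1 mV.

## Estimator conventions

- **Capacitance**: `Cm = ∫(I − I_steady)dt / ΔV` over the on-transient of
  the −80→−70 mV step, integrating from the detected transient onset
  sample (integrating across the pre-step panel would smear the
  discontinuity). Accurate to ~0.3% on noiseless cells; the residual error
  is the leak current's own relaxation, of order `g_leak·Ra·Cm`.
- **Mono-exponential fits** use `I = A·exp(−t/τ) + C` by least squares.
  Activation fits start 0.3 ms after step onset (≈3 membrane time
  constants) and add a linear baseline-drift term that absorbs the slow,
  locally linear sag contributed by closed-state inactivation during the
  25-ms step; without it the sag deflates τ by several percent.
  Deactivation fits start after a 0.15-ms blank and use the plain
  offset form (tails carry no comparable sag).
- **Tail amplitudes**: `measure_tail` defaults to back-extrapolation of
  the fitted exponential to the repolarization instant, which is exact
  under an ideal clamp and is guarded against noise-locked fits (the
  decay must be slower than the blank, faster than the window, and the
  exponential component must clear the residual noise). With the
  uncompensated `Ra·Cm ≈ 109 µs` settle of the realistic fixtures,
  however, back-extrapolation through the settle period is systematically
  inflated (the driving force is not yet established at the nominal
  repolarization time), so the study pipeline measures tail amplitudes by
  the bounded post-blank **peak** instead.
- **Fixed-cursor families**: for curves built from amplitude families
  (G–V tails, availability test currents), the latency of the reference
  sweep's peak is located once and every sweep is read at that same
  latency, with the normalizer taken from fixed saturated sweeps (the
  three highest test potentials; the most hyperpolarized conditioning).
  Per-sweep extremum picking and max-normalization would otherwise add a
  noise-dependent lift to the curve foot and inflate fitted slopes.
- **Peaks** are signed extrema of boxcar-smoothed current (0.5 ms window,
  narrow against the ≥2-ms plateau around every peak measured here).
- **Window current** is `∫ min(act(V), avail(V)) dV` over −100…+30 mV by
  trapezoid with a dv/2 refinement check (the symmetric-pair oracle
  10·ln 2 mV is reproduced to 0.1%).
- **Charge flux** is `Q = |∫I dt|` over the 2-ms ramp window of the
  corrected, repeat-averaged sweep; `Q/Cm` (fC/pF) and `Q/|I_tail|`
  (fC/pA, tail at the reversal-potential protocol) are reported.
- **Statistics**: mean ± SEM (sd/√n, ddof = 1) and the pooled-variance
  unpaired two-tailed Student t-test (Welch available by flag).

## Genotype fixtures and calibration

`fixtures/wt.yaml` and `fixtures/r1667p.yaml` encode the two channel
variants. Boltzmann parameters are the reported fit values (activation
0.9/5.4 vs −10.0/6.6 mV; availability −39.3/−12.6 vs −42.1/−10.7 mV).
The activation-tau bells are pinned to tau_act(+20 mV) = 0.7 and 1.8 ms;
their deactivation limbs are not constrained by any printed number and
were chosen once within the physiological range for this channel type at
room temperature (WT tau_deact ≈ 0.5 ms at −40 mV falling to ≈0.17 ms at
−80 mV; R1667P ≈ 4× slower throughout, consistent with its slowed
closure). `g_max` densities (0.725 and 0.176 nS/pF) are calibrated so a
noiseless single cell reproduces the reported peak current densities
(−34.9 pA/pF at +10 mV; −9.6 pA/pF at 0 mV). The inactivation tau profile
is a broad slow bell (~1 s near −40 mV). `Cm = 23 pF`, `Ra = 4.9 MΩ`
(hence tau_m ≈ 113 µs), leak 0.02 nS/pF, per-sample noise 0.4 pA/pF.

Between-cell variability is normal for voltage midpoints/slopes and tau
scale factors and lognormal (unit mean) for `g_max` and `Cm`, with
dispersions chosen so cohort SEMs at the study cell counts are of the
order of the reported SEMs (e.g. midpoint sd 2.5 mV → SEM ≈ 0.6 mV at
n = 17; `g_max` sigma 0.33 → peak-density SEM ≈ 2.8 pA/pF). Access
resistance draws are floored at 3 MΩ: lower values do not occur in
acceptable recordings and would leave the membrane charging unresolved at
the default sampling interval.

## What the synthetic data do and do not emulate

Emulated: RC filtering of the command through the access resistance,
capacitive transients, linear leak, −P/4 acquisition, sweep-to-sweep
timing, recording noise, and between-cell parameter scatter. Not
emulated: GHK rectification of the open-channel current, sigmoidal
(multi-state) activation delay, open-state inactivation, rundown,
series-resistance compensation artifacts, temperature effects. Passing
recovery tests therefore demonstrates that the estimators are unbiased
for a first-order-gate channel under realistic acquisition — not that
they are unbiased for every real-channel nonlinearity.

Two reported quantities are structurally outside this model class, and
the package reports them honestly rather than forcing them:

- With the peak density pinned at −34.9 pA/pF and a linear driving force
  to +70 mV, the wild-type AP-ramp flux integral cannot fall below
  ≈15 fC/pF for any admissible tau profile with tau_act(+20) = 0.7 ms
  (sweeping the entire profile family gives 15.5–19.5 fC/pF); the
  packaged fixture yields ≈17 fC/pF versus the reported 12.0. The
  missing factor is the real channel's activation delay and GHK
  rectification at hyperpolarized potentials, both out of scope. The
  R1667P cohort, whose flux flows at more depolarized potentials, lands
  within ~12% of its reported 3.4 fC/pF, and the wild-type > mutant flux
  ordering holds across all seeds. As a consequence the wild-type
  `Q/I_tail` is also inflated, so the reported non-significance of that
  comparison is not reproduced.
- The reported wild-type tail density at the reversal protocol
  (−67.8 pA/pF) presumes an amplitude convention that is not stated with
  the value; the peak convention used here gives ≈ −55 pA/pF
  (extrapolation gives ≈ −92). The mutant value is reproduced under the
  peak convention.
- The reported window-current magnitudes are not reproducible from the
  reported curve parameters under either the min-overlap or the product
  convention (both give the mutant a ~40% larger window); the
  hyperpolarizing shift of the mutant window is reproduced.

## Problem sizes

The default study simulates independent cohorts per assay at the study
cell counts (I–V 17/19, kinetics 17/15, deactivation 13/9,
inactivation 13/6, flux 13/12 cells for WT/R1667P), at 10-µs sampling
with the desk-scale inactivation protocol; a full run takes well under
two minutes on one CPU. Cohort-mean checks pool three replicate cohorts
(seeds spawned from one base seed) so they hold under any seed;
`scripts/acceptance.py` averages six replicates per quantity and reports
the total cell count used.
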