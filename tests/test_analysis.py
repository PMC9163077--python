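"""Measurement and fitting oracles: capacitance, -P/4, tails, Boltzmann
fits, window overlap, ramp charge."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cavclamp as cc
from cavclamp.analysis import (ap_charge, fit_monoexp, measure_peak,
                               measure_tail, window_area)
from cavclamp.errors import AnalysisError
from cavclamp.gating import boltzmann
from cavclamp.traceio import Sweep


# ---------------------------------------------------------------------------
# capacitance


def test_cm_by_transient_integration(quiet_wt):
    """RC analytic: integrating the 10 mV test transient returns Cm."""
    rec = cc.simulate_recording(cc.build_protocol("cm_test"), quiet_wt, seed=0)
    assert cc.measure_cm(rec) == pytest.approx(quiet_wt.cm, rel=5e-3)


def test_cm_cohort_mean(wt_cell):
    """A 36-cell cohort drawn around 23 pF reports a ~23.0 pF mean."""
    spec = cc.CohortSpec(n_cells=36, base=wt_cell,
                         variability={"cm": 0.2}, seed=21)
    cohort = cc.generate_cohort(spec, [cc.build_protocol("cm_test")])
    measured = [cc.measure_cm(recs["cm_test"]) for _, recs in cohort]
    truth = [cell.cm for cell, _ in cohort]
    s = cc.summarize(measured)
    assert s.n == 36
    assert s.mean == pytest.approx(np.mean(truth), abs=s.sem)
    assert s.mean == pytest.approx(23.0, abs=2 * s.sem)


def test_cm_zero_step_rejected(quiet_wt):
    proto = cc.build_protocol("cm_test", {"step_v": -80.0})
    rec = cc.simulate_recording(proto, quiet_wt, seed=0)
    with pytest.raises(AnalysisError):
        cc.measure_cm(rec)


# ---------------------------------------------------------------------------
# -P/4 correction


def test_p4_nulls_pure_leak(leak_only_wt):
    """Linear leak + capacitive currents cancel to < 1e-9 pA."""
    rec = cc.simulate_recording(cc.build_protocol("step_iv"), leak_only_wt, seed=0)
    corr = cc.correct_recording(rec)
    for sweep in corr.sweeps:
        assert np.max(np.abs(sweep.current)) < 1e-9


@settings(deadline=None, max_examples=10, derandomize=True)
@given(
    gleak=st.floats(0.005, 0.2),
    ra=st.floats(3.0, 12.0),
    cm=st.floats(12.0, 40.0),
    eleak=st.floats(-20.0, 20.0),
)
def test_p4_exact_for_any_affine_system(wt_cell, gleak, ra, cm, eleak):
    cell = replace(wt_cell, gmax_density=0.0, noise_sd=0.0, gleak_density=gleak,
                   ra=ra, cm=cm, eleak=eleak)
    proto = cc.build_protocol("reversal_tail")
    corr = cc.correct_recording(cc.simulate_recording(proto, cell, seed=0))
    assert np.max(np.abs(corr.sweeps[0].current)) < 1e-9


def test_corrected_current_is_ionic_alone(quiet_wt):
    """After -P/4, the remaining steady current equals the analytic ionic
    current (leak and capacitive components removed)."""
    proto = cc.build_protocol("step_iv", {"test_potentials": [10.0]})
    corr = cc.correct_recording(cc.simulate_recording(proto, quiet_wt, seed=0))
    t0, t1 = proto.segment_bounds(0)[1]
    i1 = int(round(t1 / proto.dt))
    g = quiet_wt.gating
    h = g.h_inf(-80.0) + (g.h_inf(10.0) - g.h_inf(-80.0)) * (
        1 - np.exp(-25.0 / g.tau_inact(10.0)))
    expected = quiet_wt.cm * quiet_wt.gmax_density * g.m_inf(10.0) * h * (10.0 - quiet_wt.erev)
    assert corr.sweeps[0].current[i1 - 5] == pytest.approx(expected, rel=5e-3)


def test_double_correction_refused(quiet_wt):
    rec = cc.simulate_recording(cc.build_protocol("cm_test"), quiet_wt, seed=0)
    with pytest.raises(AnalysisError):  # no sub-sweeps on cm_test
        cc.correct_recording(rec)
    rec2 = cc.simulate_recording(cc.build_protocol("reversal_tail"), quiet_wt, seed=0)
    corr = cc.correct_recording(rec2)
    with pytest.raises(AnalysisError):
        cc.correct_recording(corr)


# ---------------------------------------------------------------------------
# peaks and tails


def test_peak_of_zero_conductance_cell(leak_only_wt):
    rec = cc.simulate_recording(cc.build_protocol("step_iv"), leak_only_wt, seed=0)
    corr = cc.correct_recording(rec)
    iv = cc.compute_iv(corr, leak_only_wt.cm)
    assert np.max(np.abs(iv["i_peak_density"])) < 1e-9


def test_peak_window_validation(quiet_wt):
    rec = cc.simulate_recording(cc.build_protocol("cm_test"), quiet_wt, seed=0)
    with pytest.raises(AnalysisError):
        measure_peak(rec.sweeps[0], (0.0, 1e6), quiet_wt.cm)


def test_tail_amplitude_matches_analytic_under_ideal_clamp(ideal_wt):
    """Noiseless, zero-ra: back-extrapolated tail equals
    cm*gmax*m(t_repol)*h*(V_tail - Erev) within 1%."""
    proto = cc.build_protocol("reversal_tail")
    rec = cc.simulate_recording(proto, ideal_wt, seed=0, return_states=True)
    corr = cc.correct_recording(rec)
    t0, t1 = proto.segment_bounds(0)[proto.segment_by_role("tail")]
    amp = measure_tail(corr.sweeps[0], t0, t1, method="extrapolated")
    main = rec.sweeps_where(role="main")[0]
    i_rep = int(round(t0 / proto.dt))
    m0 = rec.states[main]["m"][i_rep]
    h0 = rec.states[main]["h"][i_rep]
    expected = ideal_wt.cm * ideal_wt.gmax_density * m0 * h0 * (-40.0 - ideal_wt.erev)
    assert amp == pytest.approx(expected, rel=0.01)


def test_tail_of_zero_conductance_cell(leak_only_wt):
    proto = cc.build_protocol("reversal_tail")
    corr = cc.correct_recording(cc.simulate_recording(proto, leak_only_wt, seed=0))
    t0, t1 = proto.segment_bounds(0)[2]
    assert abs(measure_tail(corr.sweeps[0], t0, t1)) < 1e-9


def test_tail_blank_validation(quiet_wt):
    proto = cc.build_protocol("reversal_tail")
    corr = cc.correct_recording(cc.simulate_recording(proto, quiet_wt, seed=0))
    t0, t1 = proto.segment_bounds(0)[2]
    with pytest.raises(AnalysisError):
        measure_tail(corr.sweeps[0], t0, t1, blank=t1 - t0)


# ---------------------------------------------------------------------------
# mono-exponential fitting


def test_monoexp_exact_recovery():
    t = np.arange(0, 8, 0.01)
    y = -500.0 * np.exp(-t / 0.7)
    fit = fit_monoexp(t, y)
    assert fit.ok
    assert fit.amplitude == pytest.approx(-500.0, abs=1e-6)
    assert fit.tau == pytest.approx(0.7, abs=1e-8)
    assert fit.offset == pytest.approx(0.0, abs=1e-6)
    y2 = y + 50.0
    fit2 = fit_monoexp(t, y2)
    assert fit2.offset == pytest.approx(50.0, abs=1e-6)
    assert fit2.tau == pytest.approx(0.7, abs=1e-8)


def test_monoexp_estimator_bias_under_noise():
    """Monte-Carlo: with 5 pA Gaussian noise the tau estimator bias is
    below 2%."""
    rng = np.random.default_rng(42)
    t = np.arange(0, 8, 0.01)
    clean = -500.0 * np.exp(-t / 0.7) + 25.0
    taus = []
    for _ in range(1000):
        fit = fit_monoexp(t, clean + rng.normal(0, 5.0, t.size))
        if fit.ok:
            taus.append(fit.tau)
    assert len(taus) > 990
    assert abs(np.mean(taus) - 0.7) / 0.7 < 0.02


def test_monoexp_needs_enough_samples():
    with pytest.raises(AnalysisError):
        fit_monoexp(np.arange(5.0), np.ones(5))


def test_deactivation_tau_exact_under_ideal_clamp(ideal_wt):
    """Noiseless, zero-ra tails recover the generative deactivation time
    constant at each repolarization potential."""
    proto = cc.build_protocol("deactivation")
    corr = cc.correct_recording(cc.simulate_recording(proto, ideal_wt, seed=0))
    for v in (-50.0, -40.0, -30.0, -20.0):
        tau = cc.fit_deactivation_tau(corr, v)
        assert tau == pytest.approx(ideal_wt.gating.tau_act(v), rel=5e-3)


# ---------------------------------------------------------------------------
# Boltzmann curve fits


def test_gv_fit_exact_on_model_class():
    """Points sampled exactly from a Boltzmann (0.9, 5.4) fit back to
    (0.9, 5.4) to 4 decimals."""
    from cavclamp.analysis import _fit_boltzmann
    v = np.arange(-50.0, 90.0, 10.0)
    fit = _fit_boltzmann(v, boltzmann(v, 0.9, 5.4), "increasing")
    assert fit.vhalf == pytest.approx(0.9, abs=1e-4)
    assert fit.slope == pytest.approx(5.4, abs=1e-4)
    fit2 = _fit_boltzmann(v, boltzmann(v, -39.3, -12.6), "decreasing")
    assert fit2.vhalf == pytest.approx(-39.3, abs=1e-4)
    assert fit2.slope == pytest.approx(-12.6, abs=1e-4)


def test_gv_recovery_noiseless(ideal_wt):
    """Pipeline G-V recovers the generative activation parameters."""
    corr = cc.correct_recording(
        cc.simulate_recording(cc.build_protocol("step_iv"), ideal_wt, seed=0))
    _, fit = cc.compute_gv(corr)
    assert fit.vhalf == pytest.approx(ideal_wt.gating.act_vhalf, abs=0.5)
    assert fit.slope == pytest.approx(ideal_wt.gating.act_slope, abs=0.2)


def test_gv_zero_conductance_rejected(leak_only_wt):
    corr = cc.correct_recording(
        cc.simulate_recording(cc.build_protocol("step_iv"), leak_only_wt, seed=0))
    with pytest.raises(AnalysisError):
        cc.compute_gv(corr)


def test_inactivation_recovery_noiseless(quiet_wt):
    """Full-length (5 s) conditioning recovers V_1/2inact within 1 mV, and
    the -100 mV point sits at full availability."""
    proto = cc.build_protocol("closed_state_inactivation")
    corr = cc.correct_recording(cc.simulate_recording(proto, quiet_wt, seed=0))
    df, fit = cc.compute_inactivation(corr)
    assert fit.vhalf == pytest.approx(quiet_wt.gating.inact_vhalf, abs=1.0)
    assert df.loc[df["v"] == -100.0, "avail"].iloc[0] == pytest.approx(1.0, abs=0.02)


# ---------------------------------------------------------------------------
# window current


def test_window_area_closed_form():
    """Symmetric pair act(0,5)/inact(0,-5) over +/-100 mV -> 10*ln2 mV."""
    area = window_area((0.0, 5.0), (0.0, -5.0), v_range=(-100.0, 100.0), dv=0.05)
    assert area == pytest.approx(10.0 * math.log(2.0), rel=1e-3)


def test_window_area_disjoint_curves():
    area = window_area((1000.0, 5.0), (-1000.0, -5.0))
    assert area == pytest.approx(0.0, abs=1e-6)


def test_window_area_refinement_stable():
    a1 = window_area((0.9, 5.4), (-39.3, -12.6), dv=0.2)
    a2 = window_area((0.9, 5.4), (-39.3, -12.6), dv=0.1)
    assert abs(a2 - a1) / a1 < 1e-3


def test_window_area_mirror_invariance():
    """Swapping (act, inact) for their mirror images about the crossing
    voltage leaves the overlap unchanged."""
    act, inact = (0.9, 5.4), (-39.3, -12.6)
    # crossing of the two logistics
    from scipy.optimize import brentq
    vx = brentq(lambda v: boltzmann(v, *act) - boltzmann(v, *inact), -80, 40)
    mirr_act = (2 * vx - inact[0], -inact[1])  # reflected availability
    mirr_inact = (2 * vx - act[0], -act[1])
    a = window_area(act, inact, v_range=(vx - 90, vx + 90), dv=0.05)
    b = window_area(mirr_act, mirr_inact, v_range=(vx - 90, vx + 90), dv=0.05)
    assert a == pytest.approx(b, rel=1e-9)


def test_window_area_reversed_range_rejected():
    with pytest.raises(AnalysisError):
        window_area((0.0, 5.0), (0.0, -5.0), v_range=(30.0, -100.0))


# ---------------------------------------------------------------------------
# charge flux


def _corrected_like(proto, sweep):
    from cavclamp.traceio import Recording
    return Recording(cell_id="synthetic", genotype="synthetic", protocol=proto,
                     sweeps=[sweep], sweep_tags=[{"sweep": 0, "role": "corrected"}],
                     metadata={"corrected": True})


def test_ap_charge_rectangular_current():
    """A synthetic 100 pA current lasting 1 ms carries 100 fC."""
    proto = cc.build_protocol("ap_ramp")
    dt = proto.dt
    n = int(round(proto.sweep_duration(0) / dt)) + 1
    cur = np.zeros(n)
    t = dt * np.arange(n)
    cur[(t >= 5.0) & (t < 6.0)] = 100.0
    sweep = Sweep(dt=dt, command=proto.command(0), current=cur)
    q_density, q_per_tail = ap_charge(_corrected_like(proto, sweep), cm=1.0,
                                      tail_at_reversal=50.0)
    # half-a-sample ambiguity at the rectangle edges bounds the error
    assert q_density == pytest.approx(100.0, rel=1e-2)
    assert q_per_tail == pytest.approx(2.0, rel=1e-2)


def test_ap_charge_refinement(quiet_wt):
    """Trapezoidal Q agrees with a 10x-finer-dt simulation within 0.2%."""
    qs = {}
    for dt in (0.01, 0.001):
        proto = cc.build_protocol("ap_ramp", {"dt": dt})
        corr = cc.correct_recording(cc.simulate_recording(proto, quiet_wt, dt=dt, seed=0))
        qs[dt], _ = ap_charge(corr, quiet_wt.cm, tail_at_reversal=1000.0)
    assert abs(qs[0.01] - qs[0.001]) / qs[0.001] < 2e-3


def test_ap_charge_warns_without_tail(quiet_wt):
    proto = cc.build_protocol("ap_ramp")
    corr = cc.correct_recording(cc.simulate_recording(proto, quiet_wt, seed=0))
    with pytest.warns(UserWarning):
        q_density, q_per_tail = ap_charge(corr, quiet_wt.cm)
    assert q_per_tail is None
    assert q_density > 0


def test_q_per_tail_invariant_to_gmax_scaling(quiet_wt):
    """Charge flux normalized by the reversal tail is a per-channel-flux
    proxy: scaling the conductance density rescales numerator and
    denominator identically."""
    vals = {}
    for scale in (1.0, 3.0):
        cell = replace(quiet_wt, gmax_density=quiet_wt.gmax_density * scale)
        ap = cc.correct_recording(
            cc.simulate_recording(cc.build_protocol("ap_ramp"), cell, seed=0))
        rev = cc.correct_recording(
            cc.simulate_recording(cc.build_protocol("reversal_tail"), cell, seed=0))
        t0, t1 = rev.protocol.segment_bounds(0)[2]
        tail = measure_tail(rev.sweeps[0], t0, t1, method="peak")
        _, vals[scale] = ap_charge(ap, cell.cm, tail)
    assert vals[3.0] == pytest.approx(vals[1.0], rel=1e-6)
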