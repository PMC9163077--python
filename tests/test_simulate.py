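"""Simulator physics: RC charge conservation, linearity, gate relaxation."""

from dataclasses import replace

import numpy as np
import pytest

import cavclamp as cc
from cavclamp.analysis import fit_monoexp
from cavclamp.errors import StabilityError


def _step_charge(cell, dt):
    """Integral of (I - steady) across the on-transient of a 10 mV step."""
    proto = cc.build_protocol("cm_test", {"dt": dt})
    rec = cc.simulate_recording(proto, cell, dt=dt, seed=0)
    sweep = rec.sweeps[0]
    t0, t1 = proto.segment_bounds(0)[1]
    i_on, i_off = int(round(t0 / dt)), int(round(t1 / dt))
    steady = float(np.mean(sweep.current[i_off - 100:i_off]))
    return float(np.trapezoid(sweep.current[i_on:i_off] - steady, dx=dt))


def test_capacitive_charge_conservation(leak_only_wt):
    """The transient integral equals cm * dV and is dt-refinement stable."""
    q1 = _step_charge(leak_only_wt, 0.01)
    q2 = _step_charge(leak_only_wt, 0.002)
    expected = leak_only_wt.cm * 10.0  # pF * mV = fC
    assert q1 == pytest.approx(expected, rel=5e-3)
    assert q2 == pytest.approx(expected, rel=5e-3)
    assert abs(q1 - q2) / expected < 5e-3


def test_capacitive_transient_time_constant(quiet_wt):
    """The transient decays with tau_m = Ra*Cm (~112.7 us here, in the
    experimentally reported range)."""
    rec = cc.simulate_recording(cc.build_protocol("cm_test"), quiet_wt, seed=0)
    tau_us = cc.measure_tau_m(rec)
    assert tau_us == pytest.approx(quiet_wt.tau_m_us, rel=0.02)
    assert tau_us == pytest.approx(112.7, rel=0.05)


def test_late_step_current_matches_steady_state(quiet_wt):
    """After a long step the ionic current sits at the analytic steady state."""
    proto = cc.build_protocol("step_iv", {"test_potentials": [10.0], "step": 60.0})
    rec = cc.simulate_recording(proto, quiet_wt, seed=0)
    sweep = rec.sweeps[rec.sweeps_where(role="main")[0]]
    t0, t1 = proto.segment_bounds(0)[1]
    i1 = int(round(t1 / proto.dt))
    g = quiet_wt.gating
    v = 10.0
    # h has relaxed only slightly over 60 ms; use its exact relaxation
    h0 = g.h_inf(-80.0)
    h = g.h_inf(v) + (h0 - g.h_inf(v)) * np.exp(-60.0 / g.tau_inact(v))
    expected = quiet_wt.cm * (
        quiet_wt.gmax_density * g.m_inf(v) * h * (v - quiet_wt.erev)
        + quiet_wt.gleak_density * (v - quiet_wt.eleak))
    assert sweep.current[i1 - 5] == pytest.approx(expected, rel=2e-3)


def test_linearity_superposition(leak_only_wt):
    """With gmax = 0 the recorded current is affine in command amplitude."""
    base = cc.build_protocol("cm_test")

    def response(dv):
        proto = cc.build_protocol("cm_test", {"step_v": -80.0 + dv})
        rec = cc.simulate_recording(proto, leak_only_wt, seed=0)
        return rec.sweeps[0].current

    r0, r10, r25 = response(0.0), response(10.0), response(25.0)
    np.testing.assert_allclose(r0 + 2.5 * (r10 - r0), r25, atol=1e-8)


def test_gate_trajectory_relaxes_monoexponentially(ideal_wt):
    """Zero-noise, zero-ra: fitting the simulated m(t) recovers tau_act(V)
    to better than 0.1% relative error."""
    v_test = 20.0
    proto = cc.build_protocol("step_iv", {"test_potentials": [v_test]})
    rec = cc.simulate_recording(proto, ideal_wt, seed=0, return_states=True)
    main = rec.sweeps_where(role="main")[0]
    m = rec.states[main]["m"]
    t0, t1 = proto.segment_bounds(0)[1]
    i0, i1 = int(round(t0 / proto.dt)), int(round(t1 / proto.dt))
    t = proto.dt * np.arange(i1 - i0)
    fit = fit_monoexp(t, m[i0:i1])
    assert fit.ok
    assert fit.tau == pytest.approx(ideal_wt.gating.tau_act(v_test), rel=1e-3)


def test_identical_seed_identical_recording(wt_cell):
    proto = cc.build_protocol("reversal_tail")
    a = cc.simulate_recording(proto, wt_cell, seed=123)
    b = cc.simulate_recording(proto, wt_cell, seed=123)
    for sa, sb in zip(a.sweeps, b.sweeps):
        np.testing.assert_array_equal(sa.current, sb.current)
    c = cc.simulate_recording(proto, wt_cell, seed=124)
    assert not np.array_equal(a.sweeps[0].current, c.sweeps[0].current)


def test_dt_too_coarse_raises(wt_cell):
    with pytest.raises(StabilityError):
        cc.simulate_recording(cc.build_protocol("cm_test", {"dt": 0.2}), wt_cell,
                              dt=0.2, seed=0)


def test_generate_cohort_reproducible(wt_cell):
    spec = cc.CohortSpec(n_cells=2, base=wt_cell,
                         variability={"gmax_density": 0.3}, seed=5)
    protos = [cc.build_protocol("cm_test")]
    a = cc.generate_cohort(spec, protos)
    b = cc.generate_cohort(spec, protos)
    assert a[0][0] == b[0][0]
    np.testing.assert_array_equal(
        a[1][1]["cm_test"].sweeps[0].current,
        b[1][1]["cm_test"].sweeps[0].current)
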