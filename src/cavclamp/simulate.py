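"""Whole-cell voltage-clamp simulator.

The model is the standard single-compartment clamp circuit: the command
potential charges the membrane through the access resistance,

    dVm/dt = (Vcmd - Vm) / (Ra * Cm),

while a Boltzmann-activated conductance with voltage-dependent
mono-exponential kinetics gates the ionic current,

    dm/dt = (m_inf(Vm) - m) / tau_act(Vm)
    dh/dt = (h_inf(Vm) - h) / tau_inact(Vm)

    I(t) = Cm * [gleak * (Vm - Eleak) + gmax * m * h * (Vm - Erev)]
           + Cm * dVm/dt + Gaussian noise (sd = noise_sd * Cm).

States start from their steady values at the holding potential of each
sweep, emulating the long (10 s) inter-sweep interval.

Because Vm is driven by a piecewise-linear command and is independent of
the gates, it has a closed form on every segment; the gates are advanced
with exponential-Euler steps while Vm is still settling (or during ramps)
and with the exact constant-voltage relaxation once it has.  Constant-
voltage relaxations are therefore exact, not discretized.
"""

from __future__ import annotations

import math

import numpy as np

from .cell import CellParams, CohortSpec, sample_cells
from .errors import StabilityError
from .protocols import VoltageProtocol, expand_p4
from .traceio import Recording, Sweep

__all__ = ["simulate_recording", "generate_cohort"]

# samples integrated step-by-step after a command discontinuity before the
# exact constant-voltage branch takes over (~12 membrane time constants)
_SETTLE_TAUS = 12.0


def _check_stability(protocol: VoltageProtocol, cell: CellParams, dt: float):
    # Vm is advanced by its closed form (exact) and the gates by
    # exponential Euler (unconditionally stable), so the accuracy
    # requirements are: resolve the fastest gate relaxation well, and the
    # membrane charging at least coarsely (it only sets the gate-update
    # midpoint voltage while the clamp settles).
    lim = cell.gating.min_tau_act() / 5.0
    if cell.ra > 0:
        lim = min(lim, cell.tau_m_ms / 2.0)
    if dt > lim:
        raise StabilityError(
            f"dt={dt} ms too coarse: must be <= {lim:.4g} ms for this cell's "
            "membrane and activation time constants")


def _simulate_sweep(segments, holding, cell: CellParams, dt: float,
                    rng: np.random.Generator | None):
    """Simulate one sweep; returns (command, vm, m, h, current)."""
    g = cell.gating
    tau_m = cell.tau_m_ms
    ns = [int(round(seg.duration / dt)) for seg in segments]
    N = sum(ns) + 1

    vcmd = np.empty(N)
    vm = np.empty(N)
    m = np.empty(N)
    h = np.empty(N)

    vm_state = holding
    m_state = float(g.m_inf(holding))
    h_state = float(g.h_inf(holding))
    vm[0], m[0], h[0] = vm_state, m_state, h_state

    j = 0
    for seg, n in zip(segments, ns):
        tl = dt * np.arange(1, n + 1)  # local times of samples owned here
        is_ramp = seg.kind == "ramp"
        # -- command (left-aligned: boundary sample owned by this segment)
        t0 = dt * np.arange(n)
        if is_ramp:
            vcmd[j:j + n] = seg.v_start + (seg.v_end - seg.v_start) * t0 / seg.duration
        else:
            vcmd[j:j + n] = seg.v_start

        # -- membrane potential (closed form)
        if cell.ra == 0:
            if is_ramp:
                vm_seg = seg.v_start + (seg.v_end - seg.v_start) * tl / seg.duration
            else:
                vm_seg = np.full(n, seg.v_start)
        elif is_ramp:
            r = (seg.v_end - seg.v_start) / seg.duration
            c0 = vm_state - seg.v_start + r * tau_m
            vm_seg = seg.v_start + r * tl - r * tau_m + c0 * np.exp(-tl / tau_m)
        else:
            vm_seg = seg.v_start + (vm_state - seg.v_start) * np.exp(-tl / tau_m)

        # -- gates
        m_seg = np.empty(n)
        h_seg = np.empty(n)
        if is_ramp or (cell.ra > 0 and abs(vm_state - seg.v_start) > 1e-12):
            if is_ramp:
                n_loop = n
            else:
                n_loop = min(n, int(math.ceil(_SETTLE_TAUS * tau_m / dt)))
            # midpoint membrane potential for the exponential-Euler step
            vprev = np.concatenate(([vm_state], vm_seg[:n_loop - 1])) if n_loop else vm_seg[:0]
            vmid = 0.5 * (vprev + vm_seg[:n_loop])
            minf_mid = g.m_inf(vmid)
            hinf_mid = g.h_inf(vmid)
            am = np.exp(-dt / g.act_tau(vmid))
            ah = np.exp(-dt / g.inact_tau(vmid))
            ms, hs = m_state, h_state
            for k in range(n_loop):
                ms = minf_mid[k] + (ms - minf_mid[k]) * am[k]
                hs = hinf_mid[k] + (hs - hinf_mid[k]) * ah[k]
                m_seg[k] = ms
                h_seg[k] = hs
            m_state, h_state = ms, hs
        else:
            n_loop = 0
        if n_loop < n:
            # exact relaxation at fixed command voltage
            v_c = seg.v_start
            minf = float(g.m_inf(v_c))
            hinf = float(g.h_inf(v_c))
            trel = tl[n_loop:] - (tl[n_loop - 1] if n_loop else 0.0)
            m_seg[n_loop:] = minf + (m_state - minf) * np.exp(-trel / g.act_tau(v_c))
            h_seg[n_loop:] = hinf + (h_state - hinf) * np.exp(-trel / g.inact_tau(v_c))
            m_state = float(m_seg[-1])
            h_state = float(h_seg[-1])

        vm[j + 1:j + n + 1] = vm_seg
        m[j + 1:j + n + 1] = m_seg
        h[j + 1:j + n + 1] = h_seg
        vm_state = float(vm_seg[-1])
        j += n
    vcmd[-1] = segments[-1].v_end

    ionic = cell.cm * cell.gmax_density * m * h * (vm - cell.erev)
    leak = cell.cm * cell.gleak_density * (vm - cell.eleak)
    if cell.ra > 0:
        icap = 1000.0 * (vcmd - vm) / cell.ra  # == Cm * dVm/dt, in pA
    else:
        icap = cell.cm * np.diff(vm, prepend=vm[0]) / dt
    current = ionic + leak + icap
    if rng is not None and cell.noise_sd > 0:
        current = current + rng.normal(0.0, cell.noise_sd * cell.cm, N)
    return vcmd, vm, m, h, current


def simulate_recording(protocol: VoltageProtocol, cell: CellParams,
                       dt: float | None = None, seed: int = 0,
                       return_states: bool = False) -> Recording:
    """Simulate a cell under a protocol; deterministic for a given seed.

    A protocol flagged ``p4`` is expanded into its -P/4 sub-sweep family
    and every (sweep, repeat) group stores one main plus four sub-sweeps,
    all with independent noise, mirroring online -P/4 acquisition.
    """
    dt = dt or protocol.dt
    _check_stability(protocol, cell, dt)
    if protocol.p4:
        expanded = expand_p4(protocol)
        groups = expanded.p4_groups
    else:
        expanded = protocol
        groups = [[i] for i in range(protocol.n_sweeps)]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sweeps, tags, states = [], [], []
    for s, group in enumerate(groups):
        value = protocol.sweep_values[s] if protocol.sweep_values else None
        for rep in range(protocol.repeats):
            for gi, idx in enumerate(group):
                segs = expanded.sweeps[idx]
                vcmd, vm, m, h, cur = _simulate_sweep(
                    segs, protocol.holding, cell, dt, rng)
                sweeps.append(Sweep(dt=dt, command=vcmd, current=cur))
                tags.append({
                    "sweep": s, "repeat": rep,
                    "role": "main" if gi == 0 else "p4sub",
                    "sub": None if gi == 0 else gi - 1,
                    "value": value,
                })
                if return_states:
                    states.append({"vm": vm, "m": m, "h": h})

    metadata = {
        "seed": seed,
        "dt": dt,
        "corrected": False,
        "label": cell.label,
        "cm_true": cell.cm,
        "tau_m_us": cell.tau_m_us,
        "cell": cell.to_dict(),
    }
    rec = Recording(cell_id=cell.label or "cell", genotype=cell.label,
                    protocol=protocol, sweeps=sweeps, sweep_tags=tags,
                    metadata=metadata)
    if return_states:
        rec.states = states  # not serialized; for model-level tests
    return rec


def generate_cohort(spec: CohortSpec, protocols: list[VoltageProtocol],
                    dt: float | None = None):
    """Simulate every protocol for every cell of a cohort.

    Returns a list of ``(CellParams, {protocol_name: Recording})`` so the
    per-cell generative truth stays available for recovery tests.
    Reproducible: cohort draws come from ``spec.seed`` and each cell's
    noise streams from seeds spawned deterministically from it.
    """
    cells = sample_cells(spec)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(cells))
    out = []
    for i, (cell, child) in enumerate(zip(cells, children)):
        sim_seeds = child.generate_state(len(protocols)) % (2**31)
        recs = {}
        for proto, s in zip(protocols, sim_seeds):
            rec = simulate_recording(proto, cell, dt=dt, seed=int(s))
            rec.cell_id = f"{cell.label or 'cell'}_{i:03d}"
            recs[proto.name] = rec
        out.append((cell, recs))
    return out
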