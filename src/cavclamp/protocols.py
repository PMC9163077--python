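"""Voltage-clamp command protocols.

Builds the study's stimulus families -- the step I-V, deactivation,
closed-state inactivation, action-potential-like ramp, reversal-potential
tail and capacitance test protocols -- and expands any protocol into its
-P/4 leak-subtraction sub-sweep family.

Every protocol is a list of sweeps; a sweep is a contiguous list of
hold/step/ramp segments that begins and ends at the holding potential.
Times are in ms, voltages in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError

__all__ = [
    "ProtocolSegment",
    "VoltageProtocol",
    "build_protocol",
    "expand_p4",
    "PROTOCOL_NAMES",
]

DEFAULT_HOLDING = -80.0
DEFAULT_DT = 0.01  # ms (100 kHz)


@dataclass(frozen=True)
class ProtocolSegment:
    kind: str  # "hold" | "step" | "ramp"
    v_start: float
    v_end: float
    duration: float  # ms

    def __post_init__(self):
        if self.kind not in ("hold", "step", "ramp"):
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ProtocolError("segment duration must be > 0")
        if self.kind in ("hold", "step") and self.v_start != self.v_end:
            raise ProtocolError(f"{self.kind} segment must have v_start == v_end")

    def to_dict(self):
        return {"kind": self.kind, "v_start": self.v_start, "v_end": self.v_end,
                "duration": self.duration}

    @classmethod
    def from_dict(cls, d):
        return cls(d["kind"], d["v_start"], d["v_end"], d["duration"])


def _const(v: float, duration: float, kind: str = "step") -> ProtocolSegment:
    return ProtocolSegment(kind, v, v, duration)


@dataclass
class VoltageProtocol:
    """A named sweep family with an optional -P/4 policy.

    ``sweeps`` is a list of segment lists; all sweeps share the same
    segment structure (one role per position, named in ``segment_roles``).
    ``sweep_values`` records the value that varies across sweeps (test,
    repolarization or conditioning potential).  When ``p4_groups`` is set
    the sweep list already contains explicit -P/4 sub-sweeps.
    """

    name: str
    holding: float
    sweeps: list
    sweep_variable: str = ""
    sweep_values: list = field(default_factory=list)
    segment_roles: list = field(default_factory=list)
    dt: float = DEFAULT_DT
    repeats: int = 1
    inter_sweep_interval: float = 10.0  # s (0.1 Hz)
    p4: bool = False
    p4_groups: list | None = None

    def __post_init__(self):
        if len(self.sweeps) < 1:
            raise ProtocolError("protocol needs at least one sweep")
        if self.repeats < 1:
            raise ProtocolError("repeats must be >= 1")
        for i, segs in enumerate(self.sweeps):
            if segs[0].v_start != self.holding or segs[-1].v_end != self.holding:
                raise ProtocolError(
                    f"sweep {i} of {self.name!r} must begin and end at holding "
                    f"({self.holding} mV)")
            # steps may jump, but a ramp must take off from the voltage the
            # previous segment left the command at
            for a, b in zip(segs, segs[1:]):
                if b.kind == "ramp" and a.v_end != b.v_start:
                    raise ProtocolError(
                        f"sweep {i} of {self.name!r}: ramp is not contiguous "
                        f"({a.v_end} -> {b.v_start} mV)")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_duration(self, i: int = 0) -> float:
        return sum(s.duration for s in self.sweeps[i])

    def segment_samples(self, i: int = 0, dt: float | None = None) -> list[int]:
        dt = dt or self.dt
        ns = []
        for seg in self.sweeps[i]:
            n = int(round(seg.duration / dt))
            if n < 1 or abs(n * dt - seg.duration) > 1e-9 * max(1.0, seg.duration):
                raise ProtocolError(
                    f"segment duration {seg.duration} ms is not a multiple of dt={dt} ms")
            ns.append(n)
        return ns

    def segment_bounds(self, i: int = 0) -> list[tuple[float, float]]:
        """(t_start, t_end) of each segment of sweep ``i``, in ms."""
        out, t = [], 0.0
        for seg in self.sweeps[i]:
            out.append((t, t + seg.duration))
            t += seg.duration
        return out

    def segment_by_role(self, role: str) -> int:
        try:
            return self.segment_roles.index(role)
        except ValueError:
            raise ProtocolError(f"protocol {self.name!r} has no segment with role {role!r}")

    def command(self, i: int = 0, dt: float | None = None) -> np.ndarray:
        """Sampled command voltage for sweep ``i`` (boundary sample owned by
        the following segment; one trailing sample at holding)."""
        dt = dt or self.dt
        ns = self.segment_samples(i, dt)
        out = np.empty(sum(ns) + 1)
        j = 0
        for seg, n in zip(self.sweeps[i], ns):
            t = dt * np.arange(n)
            if seg.kind == "ramp":
                out[j:j + n] = seg.v_start + (seg.v_end - seg.v_start) * t / seg.duration
            else:
                out[j:j + n] = seg.v_start
            j += n
        out[-1] = self.sweeps[i][-1].v_end
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "holding": self.holding,
            "sweeps": [[s.to_dict() for s in sw] for sw in self.sweeps],
            "sweep_variable": self.sweep_variable,
            "sweep_values": list(self.sweep_values),
            "segment_roles": list(self.segment_roles),
            "dt": self.dt,
            "repeats": self.repeats,
            "inter_sweep_interval": self.inter_sweep_interval,
            "p4": self.p4,
            "p4_groups": self.p4_groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        sweeps = [[ProtocolSegment.from_dict(s) for s in sw] for sw in d["sweeps"]]
        return cls(
            name=d["name"], holding=d["holding"], sweeps=sweeps,
            sweep_variable=d.get("sweep_variable", ""),
            sweep_values=d.get("sweep_values", []),
            segment_roles=d.get("segment_roles", []),
            dt=d.get("dt", DEFAULT_DT), repeats=d.get("repeats", 1),
            inter_sweep_interval=d.get("inter_sweep_interval", 10.0),
            p4=d.get("p4", False), p4_groups=d.get("p4_groups"),
        )


def _steps(start: float, stop: float, inc: float) -> list[float]:
    n = int(round((stop - start) / inc)) + 1
    return [start + k * inc for k in range(n)]


def build_step_iv(holding=DEFAULT_HOLDING, pre=5.0, step=25.0,
                  test_potentials=None, tail_v=-40.0, tail=10.0, post=5.0,
                  dt=DEFAULT_DT):
    vs = list(test_potentials) if test_potentials is not None else _steps(-50.0, 80.0, 10.0)
    sweeps = [[
        _const(holding, pre, "hold"),
        _const(v, step),
        _const(tail_v, tail),
        _const(holding, post, "hold"),
    ] for v in vs]
    return VoltageProtocol(
        name="step_iv", holding=holding, sweeps=sweeps,
        sweep_variable="test_potential", sweep_values=vs,
        segment_roles=["hold", "test", "tail", "hold"], dt=dt, p4=True)


def build_deactivation(holding=DEFAULT_HOLDING, pre=5.0, act_v=30.0, act=25.0,
                       repol_potentials=None, tail=10.0, post=5.0, dt=DEFAULT_DT):
    vs = list(repol_potentials) if repol_potentials is not None else _steps(-50.0, -20.0, 10.0)
    sweeps = [[
        _const(holding, pre, "hold"),
        _const(act_v, act),
        _const(v, tail),
        _const(holding, post, "hold"),
    ] for v in vs]
    return VoltageProtocol(
        name="deactivation", holding=holding, sweeps=sweeps,
        sweep_variable="repolarization_potential", sweep_values=vs,
        segment_roles=["hold", "act", "tail", "hold"], dt=dt, p4=True)


def build_closed_state_inactivation(holding=DEFAULT_HOLDING, pre=5.0,
                                    conditioning_duration=5000.0,
                                    conditioning_potentials=None,
                                    gap=5.0, test_v=20.0, test=25.0, post=5.0,
                                    dt=DEFAULT_DT):
    vs = (list(conditioning_potentials) if conditioning_potentials is not None
          else _steps(-100.0, 30.0, 10.0))
    sweeps = [[
        _const(holding, pre, "hold"),
        _const(v, conditioning_duration),
        _const(holding, gap),
        _const(test_v, test),
        _const(holding, post, "hold"),
    ] for v in vs]
    return VoltageProtocol(
        name="closed_state_inactivation", holding=holding, sweeps=sweeps,
        sweep_variable="conditioning_potential", sweep_values=vs,
        segment_roles=["hold", "conditioning", "gap", "test", "hold"],
        dt=dt, p4=True)


def build_ap_ramp(holding=DEFAULT_HOLDING, pre=5.0, peak_v=30.0, ramp_up=1.0,
                  ramp_down=1.0, post=5.0, repeats=10, dt=DEFAULT_DT):
    sweeps = [[
        _const(holding, pre, "hold"),
        ProtocolSegment("ramp", holding, peak_v, ramp_up),
        ProtocolSegment("ramp", peak_v, holding, ramp_down),
        _const(holding, post, "hold"),
    ]]
    return VoltageProtocol(
        name="ap_ramp", holding=holding, sweeps=sweeps,
        sweep_variable="", sweep_values=[peak_v],
        segment_roles=["hold", "ramp_up", "ramp_down", "hold"],
        dt=dt, repeats=repeats, p4=True)


def build_reversal_tail(holding=DEFAULT_HOLDING, pre=5.0, step_v=70.0, step=25.0,
                        tail_v=-40.0, tail=10.0, post=5.0, dt=DEFAULT_DT):
    sweeps = [[
        _const(holding, pre, "hold"),
        _const(step_v, step),
        _const(tail_v, tail),
        _const(holding, post, "hold"),
    ]]
    return VoltageProtocol(
        name="reversal_tail", holding=holding, sweeps=sweeps,
        sweep_variable="", sweep_values=[step_v],
        segment_roles=["hold", "step", "tail", "hold"], dt=dt, p4=True)


def build_cm_test(holding=DEFAULT_HOLDING, pre=5.0, step_v=-70.0, step=5.0,
                  post=5.0, dt=DEFAULT_DT):
    sweeps = [[
        _const(holding, pre, "hold"),
        _const(step_v, step),
        _const(holding, post, "hold"),
    ]]
    return VoltageProtocol(
        name="cm_test", holding=holding, sweeps=sweeps,
        sweep_variable="", sweep_values=[step_v],
        segment_roles=["hold", "test", "hold"], dt=dt, p4=False)


_BUILDERS = {
    "step_iv": build_step_iv,
    "deactivation": build_deactivation,
    "closed_state_inactivation": build_closed_state_inactivation,
    "ap_ramp": build_ap_ramp,
    "reversal_tail": build_reversal_tail,
    "cm_test": build_cm_test,
}

PROTOCOL_NAMES = tuple(_BUILDERS)


def build_protocol(name: str, overrides: dict | None = None) -> VoltageProtocol:
    """Build one of the named protocols, optionally overriding defaults.

    Override keys are the keyword arguments of the corresponding builder
    (e.g. ``conditioning_duration`` for the inactivation protocol); unknown
    keys raise :class:`ProtocolError`.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ProtocolError(
            f"unknown protocol {name!r}; choose from {sorted(_BUILDERS)}")
    overrides = dict(overrides or {})
    import inspect
    allowed = set(inspect.signature(builder).parameters)
    bad = set(overrides) - allowed
    if bad:
        raise ProtocolError(f"unknown override(s) for {name!r}: {sorted(bad)}")
    return builder(**overrides)


def p4_subsweep(segments: list[ProtocolSegment], holding: float) -> list[ProtocolSegment]:
    """One -P/4 sub-sweep: every deviation from holding scaled by -1/4."""
    out = []
    for seg in segments:
        v0 = holding - (seg.v_start - holding) / 4.0
        v1 = holding - (seg.v_end - holding) / 4.0
        out.append(ProtocolSegment(seg.kind, v0, v1, seg.duration))
    return out


def expand_p4(protocol: VoltageProtocol) -> VoltageProtocol:
    """Expand a protocol into its explicit -P/4 sub-sweep family.

    For each main sweep four sub-sweeps are emitted whose deviation from
    holding is -1/4 of the main deviation, so the sum of the four sub-sweep
    deviations equals minus the main deviation at every sample.  The
    combine rule (main + sum of sub-sweeps, each after baseline removal at
    holding) cancels any current component linear in voltage deviation;
    it is applied by :func:`cavclamp.analysis.correct_recording`.
    """
    if not protocol.p4:
        raise ProtocolError(f"protocol {protocol.name!r} has no -P/4 policy")
    sweeps, values, groups = [], [], []
    for i, segs in enumerate(protocol.sweeps):
        idx_main = len(sweeps)
        sweeps.append(segs)
        sub = p4_subsweep(segs, protocol.holding)
        subs_idx = []
        for _ in range(4):
            subs_idx.append(len(sweeps))
            sweeps.append(sub)
        v = protocol.sweep_values[i] if protocol.sweep_values else None
        values.extend([v] * 5)
        groups.append([idx_main] + subs_idx)
    return VoltageProtocol(
        name=protocol.name, holding=protocol.holding, sweeps=sweeps,
        sweep_variable=protocol.sweep_variable, sweep_values=values,
        segment_roles=protocol.segment_roles, dt=protocol.dt,
        repeats=protocol.repeats,
        inter_sweep_interval=protocol.inter_sweep_interval,
        p4=False, p4_groups=groups)
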