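"""Steady-state gating curves and voltage-dependent time constants.

The channel model has a single activation gate ``m`` and a single slow
closed-state inactivation gate ``h``.  Both steady states are Boltzmann
functions of membrane potential,

    x_inf(V) = 1 / (1 + exp((vhalf - V) / k)),

a convention under which a positive slope factor ``k`` gives a curve that
increases with depolarization (activation) and a negative ``k`` gives a
decreasing curve (availability).  Time constants are parameterized by a
bell-shaped profile in voltage (:class:`TauProfile`), which is strictly
positive and bounded.

Units throughout: voltages in mV, times in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "TauProfile",
    "GatingParams",
    "boltzmann",
    "m_inf",
    "h_inf",
    "tau_eval",
]


def boltzmann(v, vhalf, slope):
    """Evaluate 1 / (1 + exp((vhalf - v) / slope)).

    ``slope > 0`` yields a sigmoid increasing in ``v``; ``slope < 0`` a
    decreasing one.  Accepts scalars or arrays.
    """
    if slope == 0:
        raise InvalidParameterError("Boltzmann slope factor must be nonzero")
    return 1.0 / (1.0 + np.exp((vhalf - np.asarray(v, dtype=float)) / slope))


def m_inf(v, act_vhalf, act_slope):
    """Steady-state activation; increasing in v for act_slope > 0."""
    return boltzmann(v, act_vhalf, act_slope)


def h_inf(v, inact_vhalf, inact_slope):
    """Steady-state availability; decreasing in v for inact_slope < 0."""
    return boltzmann(v, inact_vhalf, inact_slope)


@dataclass(frozen=True)
class TauProfile:
    """Bell-shaped voltage dependence of a gating time constant.

    tau(V) = tau_min + amp / (exp((V - v_center)/slope_right)
                              + exp(-(V - v_center)/slope_left))

    The value lies in ``(tau_min, tau_min + amp]`` (equal to
    ``tau_min + amp/2`` at ``v_center``, which is the maximum when the two
    limbs are symmetric).  ``tau_min`` and ``amp`` are in ms, the remaining
    fields in mV.
    """

    tau_min: float
    amp: float
    v_center: float
    slope_left: float
    slope_right: float

    def __post_init__(self):
        if self.tau_min <= 0:
            raise InvalidParameterError("tau_min must be > 0")
        if self.amp < 0:
            raise InvalidParameterError("amp must be >= 0")
        if self.slope_left <= 0 or self.slope_right <= 0:
            raise InvalidParameterError("tau profile slopes must be > 0")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        x = v - self.v_center
        tau = self.tau_min + self.amp / (
            np.exp(x / self.slope_right) + np.exp(-x / self.slope_left)
        )
        return float(tau) if np.isscalar(v) or v.ndim == 0 else tau

    def scaled(self, factor: float) -> "TauProfile":
        """Return a copy with tau_min and amp multiplied by ``factor``."""
        if factor <= 0:
            raise InvalidParameterError("tau scale factor must be > 0")
        return replace(self, tau_min=self.tau_min * factor, amp=self.amp * factor)


def tau_eval(v, profile: TauProfile):
    """Evaluate a :class:`TauProfile` at voltage(s) ``v`` (ms)."""
    return profile(v)


@dataclass(frozen=True)
class GatingParams:
    """Generative gating truth for one channel variant.

    ``act_vhalf``/``act_slope`` parameterize the activation curve
    (slope > 0), ``inact_vhalf``/``inact_slope`` the availability curve
    (slope < 0).  ``act_tau`` governs both activation and deactivation of
    the ``m`` gate; ``inact_tau`` the slow ``h`` gate.
    """

    act_vhalf: float
    act_slope: float
    act_tau: TauProfile
    inact_vhalf: float
    inact_slope: float
    inact_tau: TauProfile

    def __post_init__(self):
        if self.act_slope <= 0:
            raise InvalidParameterError("act_slope must be > 0")
        if self.inact_slope >= 0:
            raise InvalidParameterError("inact_slope must be < 0")
        vgrid = np.linspace(-120.0, 90.0, 64)
        for prof, name in ((self.act_tau, "act_tau"), (self.inact_tau, "inact_tau")):
            if np.any(prof(vgrid) <= 0):
                raise InvalidParameterError(f"{name} not strictly positive on [-120, 90] mV")

    def m_inf(self, v):
        return m_inf(v, self.act_vhalf, self.act_slope)

    def h_inf(self, v):
        return h_inf(v, self.inact_vhalf, self.inact_slope)

    def tau_act(self, v):
        return self.act_tau(v)

    def tau_inact(self, v):
        return self.inact_tau(v)

    def min_tau_act(self, v_lo: float = -120.0, v_hi: float = 90.0) -> float:
        vgrid = np.linspace(v_lo, v_hi, 512)
        return float(np.min(self.act_tau(vgrid)))


def _logistic_area(vhalf: float, slope: float, v0: float, v1: float) -> float:
    """Closed-form integral of an increasing Boltzmann over [v0, v1].

    Antiderivative of 1/(1+exp((vhalf-v)/k)) is k*log(1+exp((v-vhalf)/k)).
    Used only as an analytic cross-check oracle.
    """
    k = slope

    def F(v):
        return k * math.log1p(math.exp((v - vhalf) / k))

    return F(v1) - F(v0)
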