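"""Whole-cell parameters and cohort sampling.

A :class:`CellParams` is the full generative description of one recorded
cell: gating parameters, maximal conductance density, reversal potentials,
linear leak, membrane capacitance, access resistance and current noise.
:class:`CohortSpec` draws reproducible cohorts of cells around a base
parameter set, with normal dispersion for voltages and time-constant scale
factors and lognormal dispersion for conductance density and capacitance
(both strictly positive, right-skewed quantities in real data).

Units: mV, ms, pF, MOhm, nS/pF, pA/pF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .gating import GatingParams

__all__ = ["CellParams", "CohortSpec", "sample_cells"]

#: variability keys drawn with an additive normal dispersion (value = sd)
NORMAL_KEYS = (
    "act_vhalf",
    "act_slope",
    "inact_vhalf",
    "inact_slope",
    "tau_act_scale",
    "tau_inact_scale",
    "ra",
)
#: variability keys drawn lognormally (value = sigma of log)
LOGNORMAL_KEYS = ("gmax_density", "cm")


@dataclass(frozen=True)
class CellParams:
    """Generative truth for one simulated cell."""

    gating: GatingParams
    gmax_density: float  # nS/pF
    erev: float  # mV
    gleak_density: float  # nS/pF
    eleak: float  # mV
    cm: float  # pF
    ra: float  # MOhm
    noise_sd: float  # pA/pF per sample
    label: str = ""

    def __post_init__(self):
        if self.cm <= 0:
            raise InvalidParameterError("cm must be > 0")
        if self.ra < 0:
            raise InvalidParameterError("ra must be >= 0")
        if self.gmax_density < 0 or self.gleak_density < 0:
            raise InvalidParameterError("conductance densities must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")

    @property
    def tau_m_us(self) -> float:
        """Membrane charging constant R_a * C_m in microseconds."""
        return self.ra * self.cm

    @property
    def tau_m_ms(self) -> float:
        return self.ra * self.cm * 1e-3

    def to_dict(self) -> dict:
        g = self.gating
        return {
            "label": self.label,
            "act_vhalf": g.act_vhalf,
            "act_slope": g.act_slope,
            "act_tau": vars(g.act_tau).copy(),
            "inact_vhalf": g.inact_vhalf,
            "inact_slope": g.inact_slope,
            "inact_tau": vars(g.inact_tau).copy(),
            "gmax_density": self.gmax_density,
            "erev": self.erev,
            "gleak_density": self.gleak_density,
            "eleak": self.eleak,
            "cm": self.cm,
            "ra": self.ra,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        from .gating import TauProfile

        gating = GatingParams(
            act_vhalf=d["act_vhalf"], act_slope=d["act_slope"],
            act_tau=TauProfile(**d["act_tau"]),
            inact_vhalf=d["inact_vhalf"], inact_slope=d["inact_slope"],
            inact_tau=TauProfile(**d["inact_tau"]))
        return cls(gating=gating, gmax_density=d["gmax_density"], erev=d["erev"],
                   gleak_density=d["gleak_density"], eleak=d["eleak"],
                   cm=d["cm"], ra=d["ra"], noise_sd=d["noise_sd"],
                   label=d.get("label", ""))


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a reproducible cohort of cells.

    ``variability`` maps parameter names to dispersions: sd (same units as
    the parameter) for the normal keys, sigma of log for the lognormal
    keys.  Missing keys mean no dispersion.  Identical spec + seed yields
    an identical cohort.
    """

    n_cells: int
    base: CellParams
    variability: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        for key, val in self.variability.items():
            if key not in NORMAL_KEYS + LOGNORMAL_KEYS:
                raise InvalidParameterError(f"unknown variability key: {key!r}")
            if val < 0:
                raise InvalidParameterError(f"dispersion for {key!r} must be >= 0")


def _draw_cell(base: CellParams, var: dict, rng: np.random.Generator, idx: int) -> CellParams:
    # Draw order is fixed so cohorts are reproducible regardless of which
    # keys carry nonzero dispersion.
    draws = {}
    for key in NORMAL_KEYS:
        draws[key] = rng.normal(0.0, 1.0)
    for key in LOGNORMAL_KEYS:
        draws[key] = rng.normal(0.0, 1.0)

    g = base.gating
    act_vhalf = g.act_vhalf + var.get("act_vhalf", 0.0) * draws["act_vhalf"]
    act_slope = max(g.act_slope + var.get("act_slope", 0.0) * draws["act_slope"], 0.5)
    inact_vhalf = g.inact_vhalf + var.get("inact_vhalf", 0.0) * draws["inact_vhalf"]
    inact_slope = min(g.inact_slope + var.get("inact_slope", 0.0) * draws["inact_slope"], -0.5)
    s_act = max(1.0 + var.get("tau_act_scale", 0.0) * draws["tau_act_scale"], 0.2)
    s_inact = max(1.0 + var.get("tau_inact_scale", 0.0) * draws["tau_inact_scale"], 0.2)
    # recordings with very low access resistance do not occur in practice;
    # the floor also keeps the membrane charging resolvable at the default
    # sampling interval
    ra = max(base.ra + var.get("ra", 0.0) * draws["ra"], 3.0) if base.ra > 0 else 0.0

    # lognormal with unit mean: base * exp(sigma*z - sigma^2/2)
    sg = var.get("gmax_density", 0.0)
    gmax = base.gmax_density * float(np.exp(sg * draws["gmax_density"] - sg * sg / 2.0))
    sc = var.get("cm", 0.0)
    cm = base.cm * float(np.exp(sc * draws["cm"] - sc * sc / 2.0))

    gating = GatingParams(
        act_vhalf=act_vhalf,
        act_slope=act_slope,
        act_tau=g.act_tau.scaled(s_act),
        inact_vhalf=inact_vhalf,
        inact_slope=inact_slope,
        inact_tau=g.inact_tau.scaled(s_inact),
    )
    return replace(base, gating=gating, gmax_density=gmax, cm=cm, ra=ra,
                   label=base.label)


def sample_cells(spec: CohortSpec) -> list[CellParams]:
    """Draw ``spec.n_cells`` cell parameter sets, deterministically in seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return [_draw_cell(spec.base, spec.variability, rng, i) for i in range(spec.n_cells)]
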