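"""Packaged genotype fixtures (wild-type and R1667P parameter sets).

A fixture YAML fully specifies a :class:`~cavclamp.cell.CellParams` plus
the cohort variability dispersions.  ``fast_inact=True`` loads a variant
with the closed-state inactivation time constants divided by 10, paired
with a proportionally shortened (0.5 s) conditioning step so the
inactivation protocol runs at desk scale; the relaxation reached at the
end of conditioning is the same in units of tau.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .cell import CellParams
from .errors import InvalidParameterError
from .gating import GatingParams, TauProfile

__all__ = ["FIXTURE_NAMES", "load_fixture", "load_genotype"]

FIXTURE_NAMES = ("wt", "r1667p")

#: factor between the full (5 s conditioning) and desk-scale (0.5 s)
#: inactivation kinetics
FAST_INACT_FACTOR = 0.1


def _fixture_text(name_or_path) -> str:
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        return p.read_text()
    name = str(name_or_path).lower()
    if name in FIXTURE_NAMES:
        ref = resources.files("cavclamp") / "fixtures" / f"{name}.yaml"
        return ref.read_text()
    raise InvalidParameterError(
        f"unknown genotype fixture {name_or_path!r}; "
        f"use one of {FIXTURE_NAMES} or a YAML path")


def load_fixture(name_or_path, fast_inact: bool = False) -> tuple[CellParams, dict]:
    """Load a genotype fixture; returns (base CellParams, variability dict)."""
    doc = yaml.safe_load(_fixture_text(name_or_path))
    g = doc["gating"]
    inact_tau = TauProfile(**g["inact_tau"])
    if fast_inact:
        inact_tau = inact_tau.scaled(FAST_INACT_FACTOR)
    gating = GatingParams(
        act_vhalf=float(g["act_vhalf"]), act_slope=float(g["act_slope"]),
        act_tau=TauProfile(**g["act_tau"]),
        inact_vhalf=float(g["inact_vhalf"]), inact_slope=float(g["inact_slope"]),
        inact_tau=inact_tau)
    cell = CellParams(
        gating=gating,
        gmax_density=float(doc["gmax_density"]), erev=float(doc["erev"]),
        gleak_density=float(doc["gleak_density"]), eleak=float(doc["eleak"]),
        cm=float(doc["cm"]), ra=float(doc["ra"]),
        noise_sd=float(doc["noise_sd"]), label=str(doc.get("label", name_or_path)))
    variability = {k: float(v) for k, v in (doc.get("variability") or {}).items()}
    return cell, variability


def load_genotype(name_or_path, fast_inact: bool = False) -> CellParams:
    """Load only the base CellParams of a fixture."""
    return load_fixture(name_or_path, fast_inact=fast_inact)[0]
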