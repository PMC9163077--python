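"""Recording data model and text-file persistence.

A :class:`Recording` couples time-sampled command voltage and recorded
current for every sweep of one protocol applied to one cell.  Recordings
round-trip losslessly (to double precision) through an Axon Text File
(ATF 1.0, tab-separated) or a CSV, each with a JSON sidecar that carries
the protocol, per-sweep tags (-P/4 grouping, repeat index) and metadata.
Currents are stored raw; the correction state is flagged in the metadata.

Units are fixed: time ms, command mV, current pA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, ParseError
from .protocols import VoltageProtocol, p4_subsweep

__all__ = ["Sweep", "Recording", "write_recording", "read_recording"]

_FLOAT_FMT = "%.17g"  # exact double round-trip


@dataclass
class Sweep:
    """One sweep: sampled command voltage (mV) and current (pA)."""

    dt: float  # ms
    command: np.ndarray | None
    current: np.ndarray

    def __post_init__(self):
        if self.dt <= 0:
            raise ParseError("sweep dt must be > 0")
        self.current = np.asarray(self.current, dtype=float)
        if self.command is not None:
            self.command = np.asarray(self.command, dtype=float)
            if self.command.shape != self.current.shape:
                raise ParseError("command and current series must have equal length")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def time(self) -> np.ndarray:
        return self.dt * np.arange(self.n_samples)


@dataclass
class Recording:
    """Interchange object between simulator, files and analysis."""

    cell_id: str
    genotype: str
    protocol: VoltageProtocol | None
    sweeps: list
    sweep_tags: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protocol is not None and len(self.sweeps) != len(self.sweep_tags):
            raise ParseError("one tag per stored sweep is required")

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt

    def require_protocol(self) -> VoltageProtocol:
        if self.protocol is None:
            raise AnalysisError(
                f"recording {self.cell_id!r} has an unknown protocol; "
                "this operation needs one")
        return self.protocol

    def is_corrected(self) -> bool:
        return bool(self.metadata.get("corrected", False))

    def sweeps_where(self, **kv) -> list[int]:
        """Indices of stored sweeps whose tags match all given key/values."""
        out = []
        for i, tag in enumerate(self.sweep_tags):
            if all(tag.get(k) == v for k, v in kv.items()):
                out.append(i)
        return out


def _rebuild_command(protocol: VoltageProtocol, tag: dict, dt: float) -> np.ndarray:
    """Reconstruct a stored sweep's command from the protocol and its tag."""
    s = tag["sweep"]
    if tag.get("role") == "p4sub":
        sub = p4_subsweep(protocol.sweeps[s], protocol.holding)
        proto = VoltageProtocol(
            name="_sub", holding=protocol.holding, sweeps=[sub], dt=dt)
        return proto.command(0, dt)
    return protocol.command(s, dt)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(recording: Recording, path) -> tuple[Path, Path | None]:
    """Write a recording as ATF (.atf) or CSV (.csv) plus a JSON sidecar.

    Returns (data_path, sidecar_path).  The data file holds one time
    column plus one current column per stored sweep; the command is
    reconstructed from the protocol in the sidecar on read.
    """
    path = Path(path)
    fmt = path.suffix.lower()
    if fmt not in (".atf", ".csv"):
        raise ParseError(f"unsupported recording format {fmt!r} (use .atf or .csv)")
    n = {s.n_samples for s in recording.sweeps}
    if len(n) != 1:
        raise ParseError("all sweeps must have equal length for columnar output")
    n = n.pop()
    dt = recording.dt
    t = dt * np.arange(n)
    data = np.column_stack([t] + [s.current for s in recording.sweeps])
    titles = ["Time (ms)"] + [f"Trace #{i + 1} (pA)" for i in range(len(recording.sweeps))]

    if fmt == ".atf":
        header_records = [
            f'"cell_id={recording.cell_id}"',
            f'"genotype={recording.genotype}"',
            f'"protocol={recording.protocol.name if recording.protocol else "unknown"}"',
            f'"SweepInterval_s={recording.protocol.inter_sweep_interval if recording.protocol else ""}"',
        ]
        with open(path, "w") as f:
            f.write("ATF\t1.0\n")
            f.write(f"{len(header_records)}\t{len(titles)}\n")
            for rec in header_records:
                f.write(rec + "\n")
            f.write("\t".join(f'"{t_}"' for t_ in titles) + "\n")
            np.savetxt(f, data, fmt=_FLOAT_FMT, delimiter="\t")
    else:
        cols = ["time_ms"] + [f"trace_{i + 1:03d}_pA" for i in range(len(recording.sweeps))]
        with open(path, "w") as f:
            f.write(",".join(cols) + "\n")
            np.savetxt(f, data, fmt=_FLOAT_FMT, delimiter=",")

    sidecar = {
        "format_version": 1,
        "cell_id": recording.cell_id,
        "genotype": recording.genotype,
        "protocol": recording.protocol.to_dict() if recording.protocol else None,
        "sweep_tags": recording.sweep_tags,
        "metadata": recording.metadata,
        "dt": dt,
    }
    sc_path = _sidecar_path(path)
    with open(sc_path, "w") as f:
        json.dump(sidecar, f, indent=1)
    return path, sc_path


def _parse_atf(path: Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise ParseError(f"{path}: line 1: not an ATF file")
    try:
        n_header, n_cols = (int(x) for x in lines[1].split("\t"))
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 2: malformed ATF dimension record")
    title_line = 2 + n_header
    if title_line >= len(lines):
        raise ParseError(f"{path}: line {title_line + 1}: missing column titles")
    titles = [t.strip('"') for t in lines[title_line].split("\t")]
    if len(titles) != n_cols:
        raise ParseError(
            f"{path}: line {title_line + 1}: {len(titles)} column titles, "
            f"header declares {n_cols}")
    rows = []
    for ln, line in enumerate(lines[title_line + 1:], start=title_line + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}: line {ln}: expected {n_cols} columns, found {len(parts)}")
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            raise ParseError(f"{path}: line {ln}: non-numeric data")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return np.asarray(rows), titles


def _parse_csv(path: Path) -> tuple[np.ndarray, list[str]]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several flavours
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a time column and at least one trace column")
    arr = df.to_numpy(dtype=float)
    bad = np.where(np.isnan(arr).any(axis=1))[0]
    if bad.size:
        raise ParseError(f"{path}: line {bad[0] + 2}: incomplete or non-numeric row")
    return arr, list(df.columns)


def read_recording(path) -> Recording:
    """Read an ATF or CSV recording (sidecar optional for CSV).

    Without a sidecar the protocol is unknown: the Recording carries
    ``protocol=None`` and analysis operations that need protocol timing
    refuse it.
    """
    path = Path(path)
    fmt = path.suffix.lower()
    if fmt == ".atf":
        data, titles = _parse_atf(path)
        if "(ms)" not in titles[0]:
            raise ParseError(f"{path}: time column must declare ms units, got {titles[0]!r}")
        for t in titles[1:]:
            if "(pA)" not in t:
                raise ParseError(f"{path}: trace column must declare pA units, got {t!r}")
    elif fmt == ".csv":
        data, titles = _parse_csv(path)
        if not titles[0].endswith("_ms") and "(ms)" not in titles[0]:
            raise ParseError(f"{path}: time column must declare ms units, got {titles[0]!r}")
        for t in titles[1:]:
            if not t.endswith("_pA") and "(pA)" not in t:
                raise ParseError(f"{path}: trace column must declare pA units, got {t!r}")
    else:
        raise ParseError(f"unsupported recording format {fmt!r}")

    t = data[:, 0]
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    dt = float(t[1] - t[0])

    sc_path = _sidecar_path(path)
    if sc_path.exists():
        with open(sc_path) as f:
            sidecar = json.load(f)
        protocol = (VoltageProtocol.from_dict(sidecar["protocol"])
                    if sidecar.get("protocol") else None)
        tags = sidecar.get("sweep_tags", [])
        meta = sidecar.get("metadata", {})
        cell_id = sidecar.get("cell_id", path.stem)
        genotype = sidecar.get("genotype", "unknown")
        dt = sidecar.get("dt", dt)
    elif fmt == ".csv":
        protocol, tags, meta = None, [], {}
        cell_id, genotype = path.stem, "unknown"
    else:
        raise ParseError(f"{path}: missing sidecar {sc_path.name}")

    sweeps = []
    for i in range(data.shape[1] - 1):
        cmd = None
        if protocol is not None and i < len(tags):
            cmd = _rebuild_command(protocol, tags[i], dt)
            if cmd.size != data.shape[0]:
                raise ParseError(
                    f"{path}: trace {i + 1} has {data.shape[0]} samples but the "
                    f"protocol implies {cmd.size}")
        sweeps.append(Sweep(dt=dt, command=cmd, current=data[:, i + 1]))
    if protocol is not None and len(tags) != len(sweeps):
        raise ParseError(f"{path}: sidecar lists {len(tags)} sweeps, file has {len(sweeps)}")
    return Recording(cell_id=cell_id, genotype=genotype, protocol=protocol,
                     sweeps=sweeps, sweep_tags=tags, metadata=meta)
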