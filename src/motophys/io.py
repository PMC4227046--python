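"""File formats and run configuration.

Traces are stored as one delimited text file per sweep (columns: time s,
voltage mV, current nA) grouped in ``<cell_id>/<protocol_id>/`` directories,
each protocol carrying a ``protocol.json`` sidecar with the sampling
interval, units, descriptor, protocol parameters and - for synthetic data -
the ground-truth block. Units are fixed (s, mV, nA, nS, um; mm for total
dendritic length) and validated on read: a sidecar declaring anything else
fails loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .synthgen import DESCRIPTORS, ModelCell, ProtocolSet, Sweep

EXPECTED_UNITS = {"time": "s", "voltage": "mV", "current": "nA"}


@dataclass
class RunConfig:
    """All tunable pipeline knobs, serialized into every output's provenance."""

    seed: int = 1
    n_cells: int = 10
    groups: list[str] = field(default_factory=lambda: [
        "WT:immediate", "WT:delayed", "mSOD1:immediate", "mSOD1:delayed"])
    mode: str = "template"
    # detector thresholds
    dvdt_criterion_mV_per_ms: float = 10.0
    latency_cutoff_s: float = 0.5
    mmo_prominence_mV: float = 1.0
    # protocol constants
    step_fine_nA: float = 0.05
    step_coarse_nA: float = 0.10
    ramp_velocity_nA_per_s: float = 0.1
    iv_pulse_s: float = 0.5
    rheo_pulse_s: float = 5.0
    alpha: float = 0.05
    out_dir: str = "out"

    def __post_init__(self) -> None:
        for name in ("dvdt_criterion_mV_per_ms", "mmo_prominence_mV",
                     "latency_cutoff_s", "ramp_velocity_nA_per_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_protocol(proto: ProtocolSet, cell_dir: str | Path,
                   ground_truth: dict | None = None) -> Path:
    """Write one protocol's sweeps plus its JSON sidecar; returns the dir."""
    pdir = Path(cell_dir) / proto.descriptor
    pdir.mkdir(parents=True, exist_ok=True)
    for k, sweep in enumerate(proto.sweeps):
        arr = np.column_stack([sweep.time, sweep.voltage, sweep.current])
        np.savetxt(pdir / f"sweep_{k:03d}.tsv", arr, delimiter="\t",
                   header="time\tvoltage\tcurrent", comments="")
    sidecar = {
        "descriptor": proto.descriptor,
        "dt": proto.sweeps[0].dt if proto.sweeps else None,
        "units": dict(EXPECTED_UNITS),
        "n_sweeps": len(proto.sweeps),
        "params": _jsonable(proto.params),
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = _jsonable(ground_truth)
    (pdir / "protocol.json").write_text(json.dumps(sidecar, indent=1))
    return pdir


def read_protocol(pdir: str | Path) -> ProtocolSet:
    pdir = Path(pdir)
    sidecar_path = pdir / "protocol.json"
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    units = sidecar.get("units", {})
    if units != EXPECTED_UNITS:
        raise ValidationError(
            f"{sidecar_path}: unit mismatch {units}, expected {EXPECTED_UNITS}")
    descriptor = sidecar.get("descriptor")
    if descriptor not in DESCRIPTORS:
        raise ValidationError(f"{sidecar_path}: unknown descriptor {descriptor!r}")
    dt = float(sidecar["dt"])
    sweeps = []
    for k, f in enumerate(sorted(pdir.glob("sweep_*.tsv"))):
        arr = np.loadtxt(f, delimiter="\t", skiprows=1, ndmin=2)
        if arr.shape[1] != 3:
            raise ValidationError(f"{f}: expected 3 columns (time, voltage, current)")
        t, v, c = arr[:, 0], arr[:, 1], arr[:, 2]
        if v.size != c.size:
            raise ValidationError(f"{f}: voltage/current length mismatch")
        if t.size > 1 and abs((t[1] - t[0]) - dt) > 1e-9:
            raise ValidationError(f"{f}: time step disagrees with sidecar dt")
        sweeps.append(Sweep(dt=dt, voltage=v, current=c, sweep_index=k,
                            protocol_id=descriptor))
    if not sweeps:
        raise ValidationError(f"{pdir}: no sweep files")
    return ProtocolSet(descriptor, sweeps, sidecar.get("params", {}))


def read_traces(root: str | Path) -> dict[str, dict[str, ProtocolSet]]:
    """Map of cell id -> {descriptor -> ProtocolSet} for a trace directory."""
    root = Path(root)
    out: dict[str, dict[str, ProtocolSet]] = {}
    for cell_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        protos = {}
        for pdir in sorted(p for p in cell_dir.iterdir() if p.is_dir()):
            if (pdir / "protocol.json").exists():
                proto = read_protocol(pdir)
                protos[proto.descriptor] = proto
        if protos:
            out[cell_dir.name] = protos
    if not out:
        raise ValidationError(f"no trace protocols found under {root}")
    return out


def write_population(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_population(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def cell_ground_truth(cell: ModelCell) -> dict:
    return _jsonable(dataclasses.asdict(cell))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
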