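"""Configuration loading, trace/metric serialization and run manifests.

Configs are YAML with three optional top-level sections: ``parameters``,
``protocol`` and ``solver`` (plus ``variant``).  Unknown keys anywhere are
rejected with a message naming the key.  Traces round-trip bit-exactly via
HDF5 and to printed precision via CSV.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import Segment, SolverConfig, Trace
from .geometry import build_geometry
from .params import Parameters, _from_mapping
from .protocols import Protocol
from .state import StateLayout
from . import rhs as R


@dataclass(frozen=True)
class RunConfig:
    parameters: Parameters
    protocol: Protocol
    solver: SolverConfig
    variant: str = "vCa"


def load_config(path: str) -> RunConfig:
    """Load a run configuration; empty file means an all-defaults run
    (1 Hz steady pacing of the vCa variant)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"parameters", "protocol", "solver", "variant"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config section(s) {sorted(unknown)}")
    params = _from_mapping(data.get("parameters", {}) or {})
    variant = data.get("variant", "vCa")

    proto_kw = dict(data.get("protocol", {}) or {})
    valid = {f.name for f in dataclasses.fields(Protocol)}
    bad = set(proto_kw) - valid
    if bad:
        raise ValueError(f"{path}: unknown protocol key(s) {sorted(bad)}")
    if "bcl_list" in proto_kw:
        proto_kw["bcl_list"] = tuple(proto_kw["bcl_list"])
    proto_kw.setdefault("variant", variant)
    protocol = Protocol(**proto_kw)

    solver_kw = dict(data.get("solver", {}) or {})
    valid = {f.name for f in dataclasses.fields(SolverConfig)}
    bad = set(solver_kw) - valid
    if bad:
        raise ValueError(f"{path}: unknown solver key(s) {sorted(bad)}")
    solver = SolverConfig(**solver_kw)
    return RunConfig(parameters=params, protocol=protocol, solver=solver,
                     variant=variant)


# ---------------------------------------------------------------------------
# Trace serialization
# ---------------------------------------------------------------------------
def write_trace_csv(tr: Trace, path: str) -> None:
    """Delimited-text export (comma, UTF-8, header with unit annotation)."""
    df = tr.to_dataframe()
    with open(path, "w") as fh:
        fh.write("# atriasim trace; time in ms, V in mV, concentrations in mM\n")
        df.to_csv(fh, index=False)


def read_trace_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trace_hdf5(tr: Trace, path: str) -> None:
    """Binary container: float64 arrays plus parameter/protocol metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=tr.t)
        f.create_dataset("Y", data=tr.Y)
        f.attrs["state_names"] = json.dumps(list(StateLayout.names))
        f.attrs["params_hash"] = tr.params.hash()
        f.attrs["variant"] = tr.variant
        f.attrs["stim_times"] = json.dumps(list(tr.stim_times))


def read_trace_hdf5(path: str) -> Trace:
    import h5py

    with h5py.File(path, "r") as f:
        t = f["t"][:]
        Y = f["Y"][:]
        stim = tuple(json.loads(f.attrs["stim_times"]))
        variant = str(f.attrs["variant"])
    params = Parameters()
    geom = build_geometry()
    seg = Segment(float(t[0]), float(t[-1]) if len(t) > 1 else float(t[0]) + 1,
                  R.default_ctx(), 0.5)
    return Trace(t=t, Y=Y, segments=(seg,), params=params, geom=geom,
                 variant=variant, stim_times=stim)


def write_metrics(metrics: dict, path: str) -> None:
    """Flat key/value record as delimited text (one row)."""
    flat = {k: (float(v) if np.isscalar(v) else json.dumps(v))
            for k, v in metrics.items()}
    pd.DataFrame([flat]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------
def build_manifest(cfg: RunConfig, outputs: dict, wall_s: float,
                   solver_stats: dict | None = None) -> dict:
    return {
        "software_version": __version__,
        "parameter_hash": cfg.parameters.hash(),
        "protocol": cfg.protocol.to_dict(),
        "protocol_hash": cfg.protocol.hash(),
        "solver": dataclasses.asdict(cfg.solver),
        "variant": cfg.variant,
        "wall_time_s": wall_s,
        "outputs": outputs,
        "solver_stats": solver_stats or {},
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
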