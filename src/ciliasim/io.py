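"""Persistence: run records and checkpoints in HDF5, tables as delimited text.

Records are written atomically (temp file + rename) and carry a format
version; loading a truncated or foreign file raises an explicit error rather
than returning silently corrupted data.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import asdict

import h5py
import yaml

from .fluid import EulerianGrid
from .geometry import BundleConfig
from .scenario import DriveSignal, Scenario
from .simulation import GateEvent, RunRecord, Snapshot, RECORD_VERSION


class IntegrityError(RuntimeError):
    pass


class VersionError(RuntimeError):
    pass


def _scenario_to_yaml(sc: Scenario) -> str:
    d = asdict(sc)
    return yaml.safe_dump(d, sort_keys=False)


def _scenario_from_yaml(s: str) -> Scenario:
    d = yaml.safe_load(s)
    drive = DriveSignal(**d.pop("drive"))
    return Scenario(drive=drive, **d)


def _bundle_to_yaml(cfg: BundleConfig) -> str:
    d = asdict(cfg)
    d["row_height_ratios"] = list(d["row_height_ratios"])
    return yaml.safe_dump(d, sort_keys=False)


def _bundle_from_yaml(s: str) -> BundleConfig:
    d = yaml.safe_load(s)
    d["row_height_ratios"] = tuple(d["row_height_ratios"])
    return BundleConfig(**d)


def save_record(record: RunRecord, path: str) -> None:
    """Write a RunRecord to HDF5 atomically."""
    dirname = os.path.dirname(os.path.abspath(path))
    os.makedirs(dirname, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["format"] = "ciliasim-run"
            f.attrs["version"] = record.version
            f.attrs["scenario"] = _scenario_to_yaml(record.scenario)
            f.attrs["bundle_config"] = _bundle_to_yaml(record.bundle_config)
            f.attrs["grid"] = yaml.safe_dump(asdict(record.grid))
            for name in ("times", "theta_deg", "rl_disp", "link_length",
                         "link_tension", "link_rest", "gate_open", "X_all",
                         "X_rest_all", "rest_arclengths"):
                f.create_dataset(name, data=getattr(record, name))
            f.attrs["row_slices"] = yaml.safe_dump(
                [[bid, int(a), int(b)] for bid, a, b in record.row_slices])
            f.attrs["link_meta"] = yaml.safe_dump(
                [dict(kind=m["kind"],
                      endpoints=[list(map(int, e)) for e in m["endpoints"]],
                      rest_length=float(m["rest_length"]),
                      stiffness=float(m["stiffness"]),
                      gated=bool(m["gated"])) for m in record.link_meta])
            snaps = f.create_group("snapshots")
            for i, s in enumerate(record.snapshots):
                g = snaps.create_group(f"{i:05d}")
                g.attrs["t"] = s.t
                g.attrs["theta_deg"] = s.theta_deg
                g.attrs["label"] = s.label
                for name in ("u", "v", "p", "omega"):
                    g.create_dataset(name, data=getattr(s, name))
            f.attrs["gate_events"] = yaml.safe_dump(
                [dict(link_index=e.link_index, kind=e.kind, t_open=float(e.t_open),
                      theta_deg=float(e.theta_deg),
                      position=[float(e.position[0]), float(e.position[1])])
                 for e in record.gate_events])
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def load_record(path: str) -> RunRecord:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "ciliasim-run":
                raise IntegrityError(f"{path}: not a ciliasim run record")
            version = int(f.attrs["version"])
            if version != RECORD_VERSION:
                raise VersionError(
                    f"{path}: record version {version}, expected {RECORD_VERSION}")
            scenario = _scenario_from_yaml(f.attrs["scenario"])
            bundle = _bundle_from_yaml(f.attrs["bundle_config"])
            grid = EulerianGrid(**yaml.safe_load(f.attrs["grid"]))
            arrays = {name: f[name][...] for name in
                      ("times", "theta_deg", "rl_disp", "link_length",
                       "link_tension", "link_rest", "gate_open", "X_all",
                       "X_rest_all", "rest_arclengths")}
            row_slices = [(bid, int(a), int(b)) for bid, a, b in
                          yaml.safe_load(f.attrs["row_slices"])]
            link_meta = [dict(kind=m["kind"],
                              endpoints=tuple(tuple(e) for e in m["endpoints"]),
                              rest_length=m["rest_length"],
                              stiffness=m["stiffness"], gated=m["gated"])
                         for m in yaml.safe_load(f.attrs["link_meta"])]
            snapshots = []
            for key in sorted(f["snapshots"]):
                g = f["snapshots"][key]
                snapshots.append(Snapshot(
                    t=float(g.attrs["t"]), theta_deg=float(g.attrs["theta_deg"]),
                    label=str(g.attrs["label"]),
                    u=g["u"][...], v=g["v"][...], p=g["p"][...],
                    omega=g["omega"][...]))
            gate_events = [GateEvent(e["link_index"], e["kind"], e["t_open"],
                                     e["theta_deg"], tuple(e["position"]))
                           for e in yaml.safe_load(f.attrs["gate_events"])]
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable or truncated HDF5 file: {exc}")
    return RunRecord(scenario=scenario, bundle_config=bundle, grid=grid,
                     link_meta=link_meta, row_slices=row_slices,
                     snapshots=snapshots, gate_events=gate_events, **arrays)


def save_checkpoint(sim_state: dict, path: str) -> None:
    dirname = os.path.dirname(os.path.abspath(path))
    os.makedirs(dirname, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".h5.tmp")
    os.close(fd)
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["format"] = "ciliasim-checkpoint"
            f.attrs["version"] = RECORD_VERSION
            f.attrs["t"] = sim_state["t"]
            f.attrs["step_index"] = sim_state["step_index"]
            f.attrs["auto_armed"] = bool(sim_state["auto_armed"])
            for name in ("u", "v", "p", "auto_peak"):
                f.create_dataset(name, data=sim_state[name])
            g = f.create_group("X")
            for i, X in enumerate(sim_state["X"]):
                g.create_dataset(str(i), data=X)
            f.attrs["gates"] = yaml.safe_dump(
                [[bool(o), None if at is None else float(at), float(th)]
                 for o, at, th in sim_state["gates"]])
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)


def load_checkpoint(path: str) -> dict:
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "ciliasim-checkpoint":
                raise IntegrityError(f"{path}: not a ciliasim checkpoint")
            if int(f.attrs["version"]) != RECORD_VERSION:
                raise VersionError(f"{path}: incompatible checkpoint version")
            return dict(
                t=float(f.attrs["t"]), step_index=int(f.attrs["step_index"]),
                auto_armed=bool(f.attrs["auto_armed"]),
                u=f["u"][...], v=f["v"][...], p=f["p"][...],
                auto_peak=f["auto_peak"][...],
                X=[f["X"][k][...] for k in sorted(f["X"], key=int)],
                gates=[(o, at, th) for o, at, th in yaml.safe_load(f.attrs["gates"])])
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable or truncated HDF5 file: {exc}")


def export_tables(record: RunRecord, outdir: str) -> list[str]:
    """Write the diagnostic tables as tab-separated text files."""
    from . import diagnostics as dg

    os.makedirs(outdir, exist_ok=True)
    written = []
    for tr in dg.tip_link_trace(record):
        path = os.path.join(outdir, f"tip_link_{tr.kind}.tsv")
        tr.table.to_csv(path, sep="\t", index=False)
        written.append(path)
    for kin in dg.row_kinematics(record):
        path = os.path.join(outdir, f"row_{kin.boundary_id}.tsv")
        kin.table.to_csv(path, sep="\t", index=False)
        written.append(path)
    est = dg.transport_estimates()
    path = os.path.join(outdir, "transport_estimates.tsv")
    import pandas as pd
    pd.DataFrame([asdict(est)]).to_csv(path, sep="\t", index=False)
    written.append(path)
    return written
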