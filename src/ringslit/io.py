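"""Trajectory, configuration and report I/O.

Formats
-------
* HDF5 trajectory schema (version 1): ``/config`` (JSON attribute),
  ``/snapshots`` int32 (S, M, N, 3), ``/taus`` int64, ``/counters``
  (JSON attribute), box geometry as root attributes.  Round-trips are
  bit-exact.
* Extended-XYZ export, one frame per snapshot; each atom line carries
  the species tag, position (units of a), ring id and monomer index.
* Run configuration as TOML (read) or JSON (read/write), mirroring
  the physical parameter table (H, M, N, rho_site, kappa_bend,
  crossing rate, steps, seed).
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np

from .engine import Trajectory
from .lattice import GRID_PER_A, MeltState, RunConfig, SlitBox

__all__ = ["write_trajectory", "read_trajectory", "export_xyz",
           "read_config", "write_config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config"] = json.dumps(traj.config.to_dict())
        f.attrs["counters"] = json.dumps(traj.counters)
        f.attrs["seed"] = traj.seed
        box = traj.box
        f.attrs["Lx"] = box.Lx
        f.attrs["Ly"] = box.Ly
        f.attrs["H"] = -1 if box.H is None else box.H
        f.attrs["Lz"] = -1 if box.Lz is None else box.Lz
        if np.abs(traj.sites).max() >= 2 ** 31:   # pragma: no cover
            raise OverflowError("coordinates exceed int32 range")
        f.create_dataset("snapshots", data=traj.sites.astype(np.int32),
                         compression="gzip", compression_opts=4)
        f.create_dataset("taus", data=traj.taus.astype(np.int64))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"trajectory schema mismatch: found "
                f"{f.attrs.get('schema_version')!r}, expected {SCHEMA_VERSION}")
        for key in ("snapshots", "taus"):
            if key not in f:
                raise ValueError(f"truncated trajectory file: missing /{key}")
        cfg = RunConfig.from_dict(json.loads(f.attrs["config"]))
        H = int(f.attrs["H"])
        Lz = int(f.attrs["Lz"])
        box = SlitBox(Lx=int(f.attrs["Lx"]), Ly=int(f.attrs["Ly"]),
                      H=None if H < 0 else H, Lz=None if Lz < 0 else Lz)
        sites = f["snapshots"][...].astype(np.int64)
        taus = f["taus"][...].astype(np.int64)
        if sites.shape[0] != taus.shape[0]:
            raise ValueError("truncated trajectory file: snapshot/tau mismatch")
        return Trajectory(box=box, config=cfg, sites=sites, taus=taus,
                          counters=json.loads(f.attrs["counters"]),
                          seed=int(f.attrs["seed"]))


def export_xyz(traj: Trajectory, path, wrap: bool = False) -> None:
    """Extended-XYZ export (positions in units of a; one frame per
    snapshot; ring id and monomer index per atom line)."""
    path = Path(path)
    box = traj.box
    with open(path, "w") as f:
        for s in range(traj.n_snapshots):
            pos = traj.sites[s]
            if wrap:
                pos = box.wrap(pos)
            M, N, _ = pos.shape
            f.write(f"{M * N}\n")
            lx = box.Lx / GRID_PER_A
            ly = box.Ly / GRID_PER_A
            lz = (box.n_layers) / GRID_PER_A
            f.write(
                f'Lattice="{lx:.6f} 0 0 0 {ly:.6f} 0 0 0 {lz:.6f}" '
                f'Properties=species:S:1:pos:R:3:ring:I:1:monomer:I:1 '
                f"tau={int(traj.taus[s])}\n")
            for r in range(M):
                for m in range(N):
                    x, y, z = pos[r, m] / GRID_PER_A
                    f.write(f"C {x:.6f} {y:.6f} {z:.6f} {r} {m}\n")


def read_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text.decode())
    if "H_over_a" in data and data["H_over_a"] in ("bulk", "none", ""):
        data["H_over_a"] = None
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
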