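"""Trajectory readers and writers: LAMMPS-style text dump and extended XYZ.

Positions are stored in sigma units as absolute coordinates (spherical
confinement, no wrapping or minimum image).  Ring connectivity is
reconstructed from molecule ids and within-molecule id order; hot/cold
labels from the particle type (1 = cold, 2 = hot).  Both formats round-trip
at the declared precision; malformed input raises errors naming the line.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, TextIO

import numpy as np

from .core import Frame, Topology, Trajectory

TYPE_COLD = 1
TYPE_HOT = 2


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


def write_trajectory(traj: Trajectory, path, fmt: Optional[str] = None,
                     precision: int = 10) -> None:
    """Write a trajectory as LAMMPS text dump or extended XYZ.

    Format is inferred from the suffix (.dump / .lammpstrj vs .xyz /
    .extxyz) when not given.  Columns: ``id mol type x y z [vx vy vz]``
    (dump) or per-atom ``species pos mol id [vel]`` (extxyz); type 2 marks
    hot monomers.
    """
    path = Path(path)
    fmt = fmt or _infer_format_from_suffix(path)
    topo = traj.topology
    types = np.where(topo.hot_mask, TYPE_HOT, TYPE_COLD)
    mols = topo.ring_of + 1
    ids = np.arange(topo.n_monomers) + 1
    with open(path, "w") as fh:
        for frame in traj:
            if fmt == "lammps-dump":
                _write_dump_frame(fh, frame, ids, mols, types, precision)
            elif fmt == "extxyz":
                _write_extxyz_frame(fh, frame, ids, mols, types, precision)
            else:
                raise ValueError(f"unknown format {fmt!r}")


def _infer_format_from_suffix(path: Path) -> str:
    if path.suffix in (".xyz", ".extxyz"):
        return "extxyz"
    return "lammps-dump"


def _write_dump_frame(fh: TextIO, frame: Frame, ids, mols, types,
                      precision: int) -> None:
    g = f"%.{precision}g"
    R = frame.box
    has_vel = frame.velocities is not None
    fh.write("ITEM: TIMESTEP\n")
    fh.write((g % frame.time) + "\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{frame.n_monomers}\n")
    fh.write("ITEM: BOX BOUNDS ff ff ff\n")
    for _ in range(3):
        fh.write((g % -R) + " " + (g % R) + "\n")
    cols = "id mol type x y z" + (" vx vy vz" if has_vel else "")
    fh.write(f"ITEM: ATOMS {cols}\n")
    for k in range(frame.n_monomers):
        x, y, z = frame.positions[k]
        line = f"{ids[k]} {mols[k]} {types[k]} {g % x} {g % y} {g % z}"
        if has_vel:
            vx, vy, vz = frame.velocities[k]
            line += f" {g % vx} {g % vy} {g % vz}"
        fh.write(line + "\n")


def _write_extxyz_frame(fh: TextIO, frame: Frame, ids, mols, types,
                        precision: int) -> None:
    g = f"%.{precision}g"
    has_vel = frame.velocities is not None
    props = "species:S:1:pos:R:3:mol:I:1:id:I:1"
    if has_vel:
        props += ":vel:R:3"
    fh.write(f"{frame.n_monomers}\n")
    fh.write(f'Time={g % frame.time} SphereRadius={g % frame.box} '
             f'Properties={props}\n')
    for k in range(frame.n_monomers):
        sp = "H" if types[k] == TYPE_HOT else "C"
        x, y, z = frame.positions[k]
        line = f"{sp} {g % x} {g % y} {g % z} {mols[k]} {ids[k]}"
        if has_vel:
            vx, vy, vz = frame.velocities[k]
            line += f" {g % vx} {g % vy} {g % vz}"
        fh.write(line + "\n")


def read_trajectory(path, fmt: Optional[str] = None,
                    ) -> tuple[Trajectory, Topology]:
    """Read a trajectory; format auto-detected from content when unspecified.

    Frames must be in time order with consistent atom counts; atom lines may
    appear in any id order within a frame (they are re-sorted by id).
    Returns ``(trajectory, topology)``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if fmt is None:
        fmt = "lammps-dump" if first.startswith("ITEM:") else "extxyz"
    frames, metas = (_read_dump(path) if fmt == "lammps-dump"
                     else _read_extxyz(path))
    if not frames:
        raise TrajectoryFormatError(f"{path}: no complete frames")
    topo = _topology_from_meta(metas[0], path)
    times = np.array([f["time"] for f in frames])
    if np.any(np.diff(times) <= 0) and len(times) > 1:
        raise TrajectoryFormatError(f"{path}: non-monotonic frame times")
    n = frames[0]["pos"].shape[0]
    for k, f in enumerate(frames):
        if f["pos"].shape[0] != n:
            raise TrajectoryFormatError(
                f"{path}: frame {k} has {f['pos'].shape[0]} atoms, expected {n}")
    has_vel = all(f["vel"] is not None for f in frames)
    traj = Trajectory(
        times=times,
        positions=np.stack([f["pos"] for f in frames]),
        topology=topo,
        box=frames[0]["box"],
        velocities=np.stack([f["vel"] for f in frames]) if has_vel else None,
    )
    return traj, topo


def _topology_from_meta(meta: dict, path) -> Topology:
    mols = meta["mol"]
    types = meta["type"]
    M = int(mols.max())
    counts = np.bincount(mols - 1, minlength=M)
    if len(set(counts.tolist())) > 1:
        raise TrajectoryFormatError(f"{path}: rings of unequal length {set(counts)}")
    N = int(counts[0])
    order = np.lexsort((np.arange(len(mols)), mols))
    if not np.array_equal(mols[order], np.repeat(np.arange(1, M + 1), N)):
        raise TrajectoryFormatError(f"{path}: molecule ids are not grouped")
    return Topology(M=M, N=N, hot_mask=(types == TYPE_HOT))


def _read_dump(path) -> tuple[list[dict], list[dict]]:
    frames: list[dict] = []
    metas: list[dict] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nl = len(lines)
    while i < nl:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise TrajectoryFormatError(f"{path}:{i + 1}: expected ITEM: TIMESTEP")
        try:
            time = float(lines[i + 1])
            if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise TrajectoryFormatError(
                    f"{path}:{i + 3}: expected ITEM: NUMBER OF ATOMS")
            natoms = int(lines[i + 3])
            if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
                raise TrajectoryFormatError(f"{path}:{i + 5}: expected ITEM: BOX BOUNDS")
            box_hi = float(lines[i + 5].split()[1])
            header = lines[i + 8]
            if not header.startswith("ITEM: ATOMS"):
                raise TrajectoryFormatError(f"{path}:{i + 9}: expected ITEM: ATOMS")
            cols = header.split()[2:]
            need = {"id", "mol", "type", "x", "y", "z"}
            if not need.issubset(cols):
                raise TrajectoryFormatError(
                    f"{path}:{i + 9}: missing columns {need - set(cols)}")
            ci = {c: k for k, c in enumerate(cols)}
            has_vel = {"vx", "vy", "vz"}.issubset(cols)
            body = lines[i + 9 : i + 9 + natoms]
            if len(body) < natoms:
                raise _truncated(path, len(frames))
            data = np.array([ln.split() for ln in body], dtype=object)
            if data.shape[1] != len(cols):
                raise TrajectoryFormatError(
                    f"{path}:{i + 10}: wrong number of columns in atom line")
        except (IndexError, ValueError) as err:
            if isinstance(err, TrajectoryFormatError):
                raise
            raise _truncated(path, len(frames)) from err
        ids = data[:, ci["id"]].astype(int)
        order = np.argsort(ids)
        if not np.array_equal(np.sort(ids), np.arange(1, natoms + 1)):
            raise TrajectoryFormatError(f"{path}:{i + 10}: atom ids are not 1..N")
        pos = data[:, [ci["x"], ci["y"], ci["z"]]].astype(float)[order]
        vel = (data[:, [ci["vx"], ci["vy"], ci["vz"]]].astype(float)[order]
               if has_vel else None)
        frames.append({"time": time, "pos": pos, "vel": vel, "box": box_hi})
        metas.append({"mol": data[:, ci["mol"]].astype(int)[order],
                      "type": data[:, ci["type"]].astype(int)[order]})
        i += 9 + natoms
    return frames, metas


def _truncated(path, nframes: int) -> TrajectoryFormatError:
    return TrajectoryFormatError(
        f"{path}: truncated file; last complete frame is "
        f"{nframes - 1 if nframes else 'none'}")


def _read_extxyz(path) -> tuple[list[dict], list[dict]]:
    frames: list[dict] = []
    metas: list[dict] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nl = len(lines)
    while i < nl:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i])
        except ValueError:
            raise TrajectoryFormatError(f"{path}:{i + 1}: expected atom count")
        if i + 1 >= nl:
            raise _truncated(path, len(frames))
        comment = lines[i + 1]
        kv = dict(re.findall(r'(\w+)=("[^"]*"|\S+)', comment))
        time = float(kv.get("Time", len(frames)))
        box = float(kv.get("SphereRadius", "nan"))
        has_vel = "vel" in kv.get("Properties", "")
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise _truncated(path, len(frames))
        toks = [ln.split() for ln in body]
        width = 6 + (3 if has_vel else 0)
        for k, t in enumerate(toks):
            if len(t) != width:
                raise TrajectoryFormatError(
                    f"{path}:{i + 3 + k}: expected {width} columns, got {len(t)}")
        arr = np.array(toks, dtype=object)
        ids = arr[:, 5].astype(int)
        order = np.argsort(ids)
        if not np.array_equal(np.sort(ids), np.arange(1, natoms + 1)):
            raise TrajectoryFormatError(f"{path}:{i + 3}: atom ids are not 1..N")
        pos = arr[:, 1:4].astype(float)[order]
        vel = arr[:, 6:9].astype(float)[order] if has_vel else None
        species = arr[:, 0].astype(str)[order]
        frames.append({"time": time, "pos": pos, "vel": vel, "box": box})
        metas.append({"mol": arr[:, 4].astype(int)[order],
                      "type": np.where(species == "H", TYPE_HOT, TYPE_COLD)})
        i += 2 + natoms
    return frames, metas
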