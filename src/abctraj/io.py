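"""Reading and writing structures, trajectories, selection schemes and tables.

The on-disk trajectory format is multi-model PDB (text, fixed columns).  PDB
cannot carry masses, charges, vdW radii or segment roles, so ``write_structure``
emits a JSON sidecar (``<path>.meta.json``) that ``read_structure`` picks up
when present; otherwise those fields are filled from the bundled element table
and every segment role defaults to "unassigned".
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from ._elements import element_mass, element_vdw, guess_element
from .topology import Segment, SelectionScheme, Topology, Trajectory

log = logging.getLogger("abctraj")


class ParseError(ValueError):
    """Malformed structure file; message names the offending line."""


class ConfigError(ValueError):
    """Malformed selection-scheme / run configuration."""


# ---------------------------------------------------------------- PDB write

def write_structure(path, topology: Topology, coords: np.ndarray,
                    box=(120.0, 120.0, 180.0), sidecar: bool = True) -> None:
    """Write a single- or multi-model PDB (coords: (N,3) or (F,N,3))."""
    path = Path(path)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        for m, frame in enumerate(coords, start=1):
            if len(coords) > 1:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(topology.n_atoms):
                name = str(topology.name[i])
                pdb_name = name if len(name) == 4 else f" {name:<3s}"
                rid = int(topology.resid[i])
                fh.write(
                    "ATOM  {serial:5d} {name:4s} {res:<4s}{chain}{rid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
                    .format(serial=i + 1, name=pdb_name,
                            res=str(topology.resname[rid - 1])[:4], chain="A",
                            rid=rid, x=frame[i, 0], y=frame[i, 1], z=frame[i, 2],
                            occ=1.0, b=0.0, el=str(topology.element[i])[:2]))
            if len(coords) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    if sidecar:
        meta = {
            "mass": np.asarray(topology.mass, float).tolist(),
            "charge": np.asarray(topology.charge, float).tolist(),
            "vdw": np.asarray(topology.vdw, float).tolist(),
            "segments": [
                {"name": s.name, "role": s.role,
                 "resids": np.asarray(s.resids, int).tolist()}
                for s in topology.segments
            ],
        }
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(meta, fh)


# ----------------------------------------------------------------- PDB read

def _parse_models(path) -> tuple[list[dict], list[np.ndarray], tuple[float, float, float]]:
    atoms: list[dict] = []
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    serials: set[int] = set()
    first_model_done = False
    box = (120.0, 120.0, 180.0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: malformed CRYST1 record")
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    resid = int(line[22:26])
                    xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    element = line[76:78].strip() or guess_element(name)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: malformed ATOM record")
                if not first_model_done:
                    if serial in serials:
                        raise ParseError(f"{path}:{lineno}: duplicated atom serial {serial}")
                    serials.add(serial)
                    atoms.append({"name": name, "resname": resname,
                                  "resid": resid, "element": element})
                current.append(xyz)
            elif rec.startswith("ENDMDL") or rec.startswith("END"):
                if current:
                    frames.append(np.array(current))
                    current = []
                    first_model_done = True
    if current:
        frames.append(np.array(current))
    if not atoms:
        raise ParseError(f"{path}: no ATOM records found")
    return atoms, frames, box


def _topology_from_atoms(atoms: list[dict], meta: dict | None) -> Topology:
    names = np.array([a["name"] for a in atoms], dtype=object)
    elements = np.array([a["element"] for a in atoms], dtype=object)
    resid_raw = [a["resid"] for a in atoms]
    # renumber residues 1..R in file order, preserving the original labels
    resid = np.zeros(len(atoms), dtype=int)
    resnames: list[str] = []
    prev = None
    for i, (r, a) in enumerate(zip(resid_raw, atoms)):
        if prev is None or r != prev:
            resnames.append(a["resname"])
            prev = r
        resid[i] = len(resnames)
    if meta is not None:
        mass = np.asarray(meta["mass"], float)
        charge = np.asarray(meta["charge"], float)
        vdw = np.asarray(meta["vdw"], float)
        segments = [Segment(s["name"], s["role"], np.asarray(s["resids"], int))
                    for s in meta.get("segments", [])]
    else:
        mass = np.array([element_mass(e) for e in elements])
        charge = np.zeros(len(atoms))
        vdw = np.array([element_vdw(e) for e in elements])
        segments = []
    return Topology(name=names, element=elements, mass=mass, charge=charge,
                    vdw=vdw, resid=resid, resname=np.array(resnames, dtype=object),
                    segments=segments)


def read_structure(path, format: str = "pdb") -> tuple[Topology, np.ndarray]:
    """Read a structure; returns the Topology and the first frame's coords (Å)."""
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    atoms, frames, _box = _parse_models(path)
    meta = None
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    topo = _topology_from_atoms(atoms, meta)
    topo.validate()
    return topo, frames[0]


def read_trajectory(path, topology: Topology, stride: int = 1,
                    frame_time: float = 100.0) -> Trajectory:
    """Load a multi-model PDB as a Trajectory, strided from frame 0."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    atoms, frames, box = _parse_models(Path(path))
    if len(atoms) != topology.n_atoms:
        raise ValueError(f"atom-count mismatch: file has {len(atoms)}, "
                         f"topology has {topology.n_atoms}")
    coords = np.stack(frames[::stride])
    return Trajectory(coords, np.asarray(box, float), frame_time * stride)


# ---------------------------------------------------------- selection scheme

def _expand_ranges(value, key: str) -> list[int]:
    items = value if isinstance(value, list) else [value]
    out: list[int] = []
    for item in items:
        if isinstance(item, int):
            out.append(item)
        elif isinstance(item, str):
            if "-" in item:
                lo_s, hi_s = item.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
                if hi < lo:
                    raise ConfigError(f"group {key!r}: reversed range {item!r}")
                out.extend(range(lo, hi + 1))
            else:
                out.append(int(item))
        else:
            raise ConfigError(f"group {key!r}: cannot interpret {item!r}")
    return out


def parse_selection_scheme(source) -> SelectionScheme:
    """Parse a YAML selection scheme (path or string) into a SelectionScheme.

    Values are residue ids, "lo-hi" range strings, or lists of either.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("selection scheme must be a mapping of group -> residues")
    groups = {str(k): _expand_ranges(v, str(k)) for k, v in data.items()}
    return SelectionScheme(groups)


def write_selection_scheme(path, scheme: SelectionScheme) -> None:
    data = {k: list(v) for k, v in scheme.groups.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
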