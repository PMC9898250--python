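"""Core in-memory containers: Topology, Trajectory, SelectionScheme, ResultTable.

Conventions used throughout the package:

* coordinates in Å, 1-based residue numbering;
* the membrane normal is the z axis, with the bilayer centre near z = 0
  (defined operationally from the phosphate-marker z-density midpoint);
* orthorhombic periodic boxes; inter-atomic distances use the minimal-image
  convention, centre-of-mass vectors are computed on whole (unwrapped) groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class TopologyError(ValueError):
    """Inconsistent topology (ids, masses, residue membership...)."""


class SelectionError(ValueError):
    """Selection scheme refers to groups/residues that do not exist."""


# Half-transporter helix partitions for the intracellular and extracellular
# opening angles.  The IC opening contrasts TMH1,2,3,6,10,11 against
# TMH4,5,7,8,9,12; the EC opening contrasts TMH1,2,9,10,11,12 against
# TMH3,4,5,6,7,8.
IC_HALF_A = (1, 2, 3, 6, 10, 11)
IC_HALF_B = (4, 5, 7, 8, 9, 12)
EC_HALF_A = (1, 2, 9, 10, 11, 12)
EC_HALF_B = (3, 4, 5, 6, 7, 8)


@dataclass
class Segment:
    name: str
    role: str            # e.g. "tmh", "nbd", "l0", "lipid", "ligand", "unassigned"
    resids: np.ndarray   # 1-based residue ids belonging to this segment


@dataclass
class Topology:
    """Atom/residue/segment bookkeeping for one molecular system.

    Per-atom arrays all have length ``n_atoms``; ``resid`` maps each atom to
    its 1-based residue id.  ``atom_id`` is 1-based and contiguous.
    """

    name: np.ndarray         # atom names, dtype=object / str
    element: np.ndarray
    mass: np.ndarray         # amu
    charge: np.ndarray       # e
    vdw: np.ndarray          # Å
    resid: np.ndarray        # per-atom residue id (1-based)
    resname: np.ndarray      # per-residue names, length n_residues
    segments: list[Segment] = field(default_factory=list)

    # ---------------------------------------------------------------- basic
    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def n_residues(self) -> int:
        return len(self.resname)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(1, self.n_atoms + 1)

    def validate(self) -> None:
        n = self.n_atoms
        for arr, label in ((self.element, "element"), (self.mass, "mass"),
                           (self.charge, "charge"), (self.vdw, "vdw"),
                           (self.resid, "resid")):
            if len(arr) != n:
                raise TopologyError(f"{label} array length {len(arr)} != n_atoms {n}")
        if np.any(np.asarray(self.mass) <= 0):
            raise TopologyError("all masses must be > 0")
        if np.any(np.asarray(self.vdw) < 0):
            raise TopologyError("vdW radii must be >= 0")
        resids = np.asarray(self.resid)
        if resids.min(initial=1) < 1 or resids.max(initial=1) > self.n_residues:
            raise TopologyError("atom resid outside [1, n_residues]")
        seen: dict[int, str] = {}
        for seg in self.segments:
            for r in np.asarray(seg.resids):
                if r < 1 or r > self.n_residues:
                    raise TopologyError(f"segment {seg.name} references residue {r} "
                                        f"outside topology")
                if r in seen and seen[r] != seg.name:
                    raise TopologyError(f"residue {r} assigned to both {seen[r]} "
                                        f"and {seg.name}")
                seen[int(r)] = seg.name

    # ------------------------------------------------------------ selection
    def atoms_of_residues(self, resids: Iterable[int]) -> np.ndarray:
        """0-based atom indices of the given residue ids."""
        wanted = np.isin(self.resid, np.fromiter(resids, dtype=int))
        return np.flatnonzero(wanted)

    def atoms_named(self, resids: Iterable[int], names: Sequence[str]) -> np.ndarray:
        idx = self.atoms_of_residues(resids)
        mask = np.isin(np.asarray(self.name, dtype=object)[idx], list(names))
        return idx[mask]

    def heavy_atoms(self, idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            idx = np.arange(self.n_atoms)
        mask = np.asarray(self.element, dtype=object)[idx] != "H"
        return idx[mask]

    def segment_of_residue(self, resid: int) -> Segment | None:
        for seg in self.segments:
            if resid in seg.resids:
                return seg
        return None

    def ca_index(self, resid: int) -> int:
        idx = self.atoms_named([resid], ["CA"])
        if len(idx) == 0:
            raise TopologyError(f"residue {resid} ({self.resname[resid - 1]}) has no CA atom")
        return int(idx[0])


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å) with orthorhombic box lengths."""

    coords: np.ndarray      # (n_frames, n_atoms, 3)
    box: np.ndarray         # (n_frames, 3) box lengths in Å
    frame_time: float = 100.0   # ps between stored frames

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.coords[i]

    @classmethod
    def from_frame(cls, frame: np.ndarray, box: Sequence[float],
                   frame_time: float = 100.0) -> "Trajectory":
        return cls(np.asarray(frame, dtype=float)[None, :, :], np.asarray(box, float),
                   frame_time)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary orthorhombic image."""
    return delta - box * np.round(delta / box)


class SelectionScheme:
    """Named residue groups powering descriptors and network node definitions.

    Groups are mappings ``name -> tuple of residue ids``; ordered groups such
    as the Walker-A-glycine / signature-serine anchor pairs keep their order.
    Required TMH groups are ``tmh{1..12}_ic`` / ``tmh{1..12}_ec``; NBD groups
    are ``nbd1``, ``nbd2``, ``nbd1_lobe``, ``nbd2_lobe``.
    """

    TMH_GROUPS = tuple(f"tmh{i}_{side}" for i in range(1, 13) for side in ("ic", "ec"))

    def __init__(self, groups: Mapping[str, Sequence[int]]):
        self.groups: dict[str, tuple[int, ...]] = {
            k: tuple(int(r) for r in v) for k, v in groups.items()
        }

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def group(self, name: str) -> tuple[int, ...]:
        try:
            return self.groups[name]
        except KeyError:
            raise SelectionError(f"selection scheme has no group {name!r}") from None

    def union(self, names: Iterable[str]) -> tuple[int, ...]:
        out: list[int] = []
        seen: set[int] = set()
        for n in names:
            for r in self.group(n):
                if r not in seen:
                    seen.add(r)
                    out.append(r)
        return tuple(out)

    # Derived unions used by the descriptor definitions -------------------
    def ec_whole(self) -> tuple[int, ...]:
        return self.union(f"tmh{i}_ec" for i in range(1, 13))

    def ic_half(self, which: str) -> tuple[int, ...]:
        helices = IC_HALF_A if which == "A" else IC_HALF_B
        return self.union(f"tmh{i}_ic" for i in helices)

    def ec_half(self, which: str) -> tuple[int, ...]:
        helices = EC_HALF_A if which == "A" else EC_HALF_B
        return self.union(f"tmh{i}_ec" for i in helices)

    def nbd_both(self) -> tuple[int, ...]:
        return self.union(["nbd1", "nbd2"])

    def validate(self, topology: Topology,
                 required: Iterable[str] | None = None) -> None:
        """Check that referenced residues exist and invariant group structure
        holds; ``required`` groups must additionally be present and non-empty."""
        missing_res: list[tuple[str, int]] = []
        for name, resids in self.groups.items():
            for r in resids:
                if r < 1 or r > topology.n_residues:
                    missing_res.append((name, r))
        if missing_res:
            raise SelectionError(f"residues absent from topology: {missing_res}")
        if required is not None:
            for name in required:
                if name not in self.groups or len(self.groups[name]) == 0:
                    raise SelectionError(f"required group {name!r} missing or empty")
        # IC halves of the two half-transporters must not share residues
        if all(f"tmh{i}_ic" in self.groups for i in range(1, 13)):
            a, b = set(self.ic_half("A")), set(self.ic_half("B"))
            if a & b:
                raise SelectionError(f"IC half-groups overlap on residues {sorted(a & b)}")


@dataclass
class ResultTable:
    """Long-format analysis results: one row per (system, replica, frame, metric)."""

    df: pd.DataFrame

    COLUMNS = ("system", "replica", "frame", "metric", "value", "unit")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "ResultTable":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df)

    def aggregate_over_replicas(self) -> pd.DataFrame:
        """Mean and sd per metric with replicas treated as independent samples:
        average within each replica first, then n/mean/sd across replica means."""
        per_rep = (self.df.groupby(["system", "metric", "unit", "replica"])["value"]
                   .mean().reset_index())
        agg = (per_rep.groupby(["system", "metric", "unit"])["value"]
               .agg(n="count", mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
               .reset_index())
        return agg

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ResultTable":
        return cls(pd.read_csv(path, sep="\t"))
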