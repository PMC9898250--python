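"""Synthetic pseudo-transporters, membranes, ligands and trajectories.

These generators build systems whose ground truth is known by construction —
prescribed opening angles and NBD geometry, prescribed inter-group correlation,
prescribed lipid tail order — so that every analysis stage of the package can
be validated without running molecular dynamics.  There is no force field and
no integrator here: frames are drawn from explicit geometric/statistical
models, which is exactly what makes the estimators testable.

Pseudo-atoms carry uniform mass 12 amu in the transporter fixtures so that
mass-weighted and geometric centres of mass coincide; ligand charges are round
values so interaction-energy oracles are hand-checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .topology import (IC_HALF_A, IC_HALF_B, EC_HALF_A, EC_HALF_B,
                       Segment, SelectionScheme, Topology, Trajectory)


class ConstructionError(ValueError):
    """Requested geometry is infeasible (box too small, packing too dense...)."""


# ------------------------------------------------------------------- helices

def make_helix(n_res: int, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0)):
    """Ideal α-helix backbone: rise 1.5 Å/residue, 100° twist/residue,
    2.3 Å radius.  Returns (coords (3*n_res, 3), names) with one pseudo-Cα
    per residue plus N/C backbone dummies.
    """
    if n_res < 4:
        raise ValueError(f"a helix needs >= 4 residues, got {n_res}")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis vector must be non-zero")
    axis = axis / norm

    rise, twist, radius = 1.5, math.radians(100.0), 2.3
    local = np.zeros((3 * n_res, 3))
    names: list[str] = []
    for k in range(n_res):
        phi = k * twist
        ca = np.array([radius * math.cos(phi), radius * math.sin(phi), k * rise])
        # backbone dummies flanking the Cα along the helix axis
        local[3 * k] = ca + np.array([0.0, 0.0, -0.5])
        local[3 * k + 1] = ca
        local[3 * k + 2] = ca + np.array([0.0, 0.0, 0.5])
        names.extend(["N", "CA", "C"])

    # rotate local z onto the requested axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    coords = local @ rot.T + np.asarray(origin, dtype=float)
    return coords, names


# --------------------------------------------------------------- transporter

@dataclass
class TransporterSpec:
    """Target descriptor values for a pseudo-transporter."""

    ic_angle: float = 30.0        # degrees, intracellular opening
    ec_angle: float = 10.0        # degrees, extracellular opening
    nbd_distance: float = 40.0    # Å between NBD centres of mass
    nbd_twist: float = 60.0       # degrees, signed rocking-twist dihedral
    helix_length: int = 12        # residues per TMH (split into IC/EC halves)
    noise_sigma: float = 0.0      # Å, per-atom isotropic jitter
    seed: int = 0
    box: tuple[float, float, float] = (120.0, 120.0, 180.0)

    def validate(self) -> None:
        for a, label in ((self.ic_angle, "ic_angle"), (self.ec_angle, "ec_angle")):
            if not 0.0 <= a < 180.0:
                raise ValueError(f"{label} must be in [0, 180), got {a}")
        if self.nbd_distance <= 0:
            raise ValueError("nbd_distance must be > 0")
        if not -180.0 < self.nbd_twist <= 180.0:
            raise ValueError("nbd_twist must be in (-180, 180]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.helix_length < 8:
            raise ValueError("helix_length must be >= 8")


# vertical placement of the descriptor anchor planes (Å, bilayer-centred)
_Z_EC, _Z_IC, _Z_NBD = 20.0, -20.0, -40.0
_LOBE_OFFSET = 6.0


def _zero_sum_spread(n: int, scale: float) -> np.ndarray:
    """n deterministic offsets along y summing to zero."""
    vals = np.linspace(-1.0, 1.0, n) * scale
    out = np.zeros((n, 3))
    out[:, 1] = vals - vals.mean()
    return out


def _cloud(center: np.ndarray, n: int, spread: float = 2.0) -> np.ndarray:
    """n points with exactly zero-mean deterministic offsets around center."""
    dirs = np.zeros((n, 3))
    for i in range(n // 2):
        axis = i % 3
        dirs[2 * i, axis] = spread * (1.0 + 0.1 * i)
        dirs[2 * i + 1, axis] = -spread * (1.0 + 0.1 * i)
    # odd leftover point sits on the centre itself
    return center + dirs


def make_transporter(spec: TransporterSpec):
    """Build a pseudo-transporter realising the spec's descriptor targets.

    Returns ``(topology, frame, scheme)``.  In the noise-free limit the
    descriptor module recovers ic/ec angle, NBD distance and twist exactly:
    group centres of mass are placed analytically and each atom cloud has
    exactly zero-mean offsets.
    """
    spec.validate()
    if spec.nbd_distance + 2 * _LOBE_OFFSET > min(spec.box[:2]):
        raise ConstructionError(
            f"NBD distance {spec.nbd_distance} Å does not fit in box {spec.box}")

    n_ec = spec.helix_length // 2
    n_ic = spec.helix_length - n_ec
    w_ec = (_Z_EC - _Z_NBD) * math.tan(math.radians(spec.ec_angle) / 2.0)
    u_ic = (_Z_EC - _Z_IC) * math.tan(math.radians(spec.ic_angle) / 2.0)

    ec_y = {h: dy for half in (EC_HALF_A, EC_HALF_B)
            for h, dy in zip(half, _zero_sum_spread(6, 12.0)[:, 1])}
    ic_y = {h: dy for half in (IC_HALF_A, IC_HALF_B)
            for h, dy in zip(half, _zero_sum_spread(6, 12.0)[:, 1])}
    ec_x = {h: (-w_ec if h in EC_HALF_A else w_ec) for h in range(1, 13)}
    ic_x = {h: (-u_ic if h in IC_HALF_A else u_ic) for h in range(1, 13)}

    coords: list[np.ndarray] = []
    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    segments: list[Segment] = []
    groups: dict[str, list[int]] = {}
    next_res = 1

    def add_residues(res_coords: Sequence[np.ndarray], res_names: Sequence[Sequence[str]],
                     res_labels: Sequence[str]) -> list[int]:
        nonlocal next_res
        ids = []
        for rc, rn, label in zip(res_coords, res_names, res_labels):
            for xyz, nm in zip(rc, rn):
                coords.append(np.asarray(xyz, float))
                names.append(nm)
                resids.append(next_res)
            resnames.append(label)
            ids.append(next_res)
            next_res += 1
        return ids

    def add_helix_segment(com_target: np.ndarray, n_res: int) -> list[int]:
        h_coords, h_names = make_helix(n_res)
        h_coords = h_coords - h_coords.mean(axis=0) + com_target
        per_res = [h_coords[3 * k:3 * k + 3] for k in range(n_res)]
        per_names = [h_names[3 * k:3 * k + 3] for k in range(n_res)]
        return add_residues(per_res, per_names, ["ALA"] * n_res)

    for h in range(1, 13):
        ic_ids = add_helix_segment(
            np.array([ic_x[h], ic_y[h], _Z_IC]), n_ic)
        ec_ids = add_helix_segment(
            np.array([ec_x[h], ec_y[h], _Z_EC]), n_ec)
        groups[f"tmh{h}_ic"] = ic_ids
        groups[f"tmh{h}_ec"] = ec_ids
        segments.append(Segment(f"TMH{h}", "tmh", np.array(ic_ids + ec_ids)))

    # --- NBDs: lobe + core point clouds with analytic centres of mass
    d, tau = spec.nbd_distance, math.radians(spec.nbd_twist)
    n1 = np.array([-d / 2.0, 0.0, _Z_NBD])
    n2 = np.array([d / 2.0, 0.0, _Z_NBD])
    l1 = n1 + np.array([0.0, _LOBE_OFFSET, 0.0])
    l2 = n2 + np.array([0.0, _LOBE_OFFSET * math.cos(tau), _LOBE_OFFSET * math.sin(tau)])
    m = 10  # atoms per sub-cloud

    def add_nbd(tag: str, center: np.ndarray, lobe_center: np.ndarray):
        lobe_pts = _cloud(lobe_center, m)
        core_pts = _cloud(2 * center - lobe_center, m)
        labels = ["GLY"] + ["ASN"] * (m - 2) + ["SER"]
        lobe_ids = add_residues([p[None, :] for p in lobe_pts], [["CA"]] * m, labels)
        core_ids = add_residues([p[None, :] for p in core_pts], [["CA"]] * m,
                                ["ASN"] * m)
        groups[tag] = lobe_ids + core_ids
        groups[f"{tag}_lobe"] = lobe_ids
        segments.append(Segment(tag.upper(), "nbd", np.array(lobe_ids + core_ids)))
        return lobe_ids

    lobe1 = add_nbd("nbd1", n1, l1)
    lobe2 = add_nbd("nbd2", n2, l2)
    gly1, ser1 = lobe1[0], lobe1[-1]     # Walker A Gly / signature Ser of NBD1
    gly2, ser2 = lobe2[0], lobe2[-1]
    groups["gs_nbs1"] = [gly1, ser2]     # Walker A Gly (NBD1) – signature Ser (NBD2)
    groups["gs_nbs2"] = [gly2, ser1]
    groups["nbs1"] = [gly1, ser2] + lobe1[1:3]
    groups["nbs2"] = [gly2, ser1] + lobe2[1:3]

    # --- L0 lasso and coupling helices as small tagged clouds
    l0_pts = _cloud(np.array([0.0, 18.0, _Z_IC]), 4, spread=1.5)
    l0_ids = add_residues([p[None, :] for p in l0_pts], [["CA"]] * 4, ["LEU"] * 4)
    groups["l0"] = l0_ids
    segments.append(Segment("L0", "l0", np.array(l0_ids)))

    ch_anchor = {"ch_2_3": n1 + np.array([0, -8.0, 8.0]),
                 "ch_10_11": n1 + np.array([0, 8.0, 8.0]),
                 "ch_4_5": n2 + np.array([0, 8.0, 8.0]),
                 "ch_8_9": n2 + np.array([0, -8.0, 8.0])}
    for tag, center in ch_anchor.items():
        pts = _cloud(center, 2, spread=1.0)
        ids = add_residues([p[None, :] for p in pts], [["CA"]] * 2, ["PRO"] * 2)
        groups[tag] = ids
        segments.append(Segment(tag.upper(), "ch", np.array(ids)))

    groups["binding_pocket"] = [groups["tmh4_ic"][0], groups["tmh5_ic"][0],
                                groups["tmh7_ic"][0], groups["tmh8_ic"][0]]

    frame = np.vstack(coords)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frame = frame + rng.normal(0.0, spec.noise_sigma, size=frame.shape)

    n_atoms = len(names)
    topo = Topology(
        name=np.array(names, dtype=object),
        element=np.array(["C"] * n_atoms, dtype=object),
        mass=np.full(n_atoms, 12.0),
        charge=np.zeros(n_atoms),
        vdw=np.full(n_atoms, 1.7),
        resid=np.array(resids, dtype=int),
        resname=np.array(resnames, dtype=object),
        segments=segments,
    )
    topo.validate()
    scheme = SelectionScheme(groups)
    scheme.validate(topo)
    return topo, frame, scheme


# --------------------------------------------------------------- trajectories

def make_trajectory(states, n_frames: int, noise_sigma: float,
                    correlated_modes=None, seed: int = 0,
                    box=(120.0, 120.0, 180.0), frame_time: float = 100.0
                    ) -> Trajectory:
    """Draw frames i.i.d. from a weighted mixture of reference frames.

    ``states``: list of ``(frame, weight)``; weights must be >= 0 and sum to 1.
    Each atom receives isotropic Gaussian jitter of sd ``noise_sigma``.
    ``correlated_modes``: list of ``(atom_idx_a, atom_idx_b, rho)``; the two
    atom sets share a latent Gaussian displacement scaled so that the expected
    Pearson correlation of their per-frame fluctuations equals ``rho``
    (|rho| < 1 requires noise_sigma > 0; |rho| = 1 makes the displacement
    purely latent).
    """
    if not states:
        raise ValueError("state list must not be empty")
    frames = [np.asarray(f, dtype=float) for f, _w in states]
    weights = np.array([w for _f, w in states], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("state weights must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    n_atoms = frames[0].shape[0]
    which = rng.choice(len(frames), size=n_frames, p=weights)
    coords = np.stack([frames[i] for i in which])
    noise = rng.normal(0.0, noise_sigma, size=coords.shape) if noise_sigma > 0 \
        else np.zeros_like(coords)

    for a_idx, b_idx, rho in (correlated_modes or []):
        if abs(rho) > 1:
            raise ValueError(f"|rho| must be <= 1, got {rho}")
        a_idx = np.asarray(a_idx, dtype=int)
        b_idx = np.asarray(b_idx, dtype=int)
        latent = rng.normal(0.0, 1.0, size=(n_frames, 1, 3))
        if abs(abs(rho) - 1.0) < 1e-12:
            noise[:, a_idx, :] = noise_sigma * latent
            noise[:, b_idx, :] = math.copysign(1.0, rho) * noise_sigma * latent
        else:
            if noise_sigma == 0 and rho != 0:
                raise ValueError("correlated modes with |rho| < 1 require noise_sigma > 0")
            s = noise_sigma * math.sqrt(abs(rho) / (1.0 - abs(rho)))
            noise[:, a_idx, :] += s * latent
            noise[:, b_idx, :] += math.copysign(1.0, rho) * s * latent

    return Trajectory(coords + noise, np.asarray(box, float), frame_time)


# ------------------------------------------------------------------ membrane

@dataclass
class MembraneSpec:
    """Pseudo-bilayer with controllable species composition and tail order."""

    fractions: dict = field(default_factory=lambda: {"pc": 0.5, "pe": 0.25, "sterol": 0.25})
    n_per_leaflet: int = 64
    tail_length: int = 8          # carbons per tail
    order: float = 0.3            # target |S_CD| in [0, 0.5]
    box: tuple[float, float, float] = (100.0, 100.0, 80.0)
    head_z: float = 19.0          # Å, phosphate-marker plane per leaflet

    def validate(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions must sum to 1, got {total}")
        if self.n_per_leaflet <= 0:
            raise ValueError("n_per_leaflet must be > 0")
        if not 0.0 <= self.order <= 0.5:
            raise ValueError("order must be in [0, 0.5]")
        if self.box[0] * self.box[1] < 60.0 * self.n_per_leaflet:
            raise ConstructionError(
                f"box xy area {self.box[0] * self.box[1]:.0f} Å² cannot pack "
                f"{self.n_per_leaflet} lipids at >= 60 Å² per lipid")


def _species_counts(fractions: dict, n: int) -> dict:
    counts = {k: int(round(v * n)) for k, v in fractions.items()}
    # fix rounding drift on the most abundant species
    drift = n - sum(counts.values())
    if drift != 0:
        key = max(counts, key=counts.get)
        counts[key] += drift
    return counts


def make_membrane(spec: MembraneSpec, seed: int = 0):
    """Two leaflets of pseudo-lipids; tail C–H orientations drawn so the
    ensemble S_CD equals -spec.order at every carbon (mixture of exactly
    bilayer-perpendicular C–H with probability 2*order, isotropic otherwise).

    Returns ``(topology, frame)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    counts = _species_counts(spec.fractions, spec.n_per_leaflet)
    p_perp = 2.0 * spec.order

    n_side = math.ceil(math.sqrt(spec.n_per_leaflet))
    dx, dy = spec.box[0] / n_side, spec.box[1] / n_side

    coords: list[np.ndarray] = []
    names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    species_res: dict[str, list[int]] = {"pc": [], "pe": [], "sterol": []}
    next_res = 1

    def sample_ch() -> np.ndarray:
        if rng.random() < p_perp:
            phi = rng.uniform(0.0, 2.0 * math.pi)
            return np.array([math.cos(phi), math.sin(phi), 0.0])
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    for leaflet in (1.0, -1.0):
        species_list = [s for s, c in counts.items() for _ in range(c)]
        rng.shuffle(species_list)
        for i, sp in enumerate(species_list):
            cx = (i % n_side + 0.5) * dx - spec.box[0] / 2.0
            cy = (i // n_side + 0.5) * dy - spec.box[1] / 2.0
            rid = next_res
            if sp == "sterol":
                # rigid body: OH bead + 4 ring beads stacked toward the centre
                pts = [np.array([cx, cy, leaflet * (spec.head_z - 4.0)])]
                nm, el = ["O3"], ["O"]
                for k in range(4):
                    pts.append(np.array([cx, cy, leaflet * (spec.head_z - 6.5 - 2.0 * k)]))
                    nm.append(f"R{k + 1}")
                    el.append("C")
                resnames.append("CHL")
            else:
                pts = [np.array([cx, cy, leaflet * spec.head_z])]
                nm, el = ["P"], ["P"]
                for tail, xoff in (("A", -0.75), ("B", 0.75)):
                    for k in range(1, spec.tail_length + 1):
                        c = np.array([cx + xoff, cy,
                                      leaflet * (spec.head_z - 2.0 - 1.25 * k)])
                        pts.append(c)
                        nm.append(f"C{k}{tail}")
                        el.append("C")
                        for hj in (1, 2):
                            pts.append(c + 1.09 * sample_ch())
                            nm.append(f"H{k}{tail}{hj}")
                            el.append("H")
                resnames.append("PC" if sp == "pc" else "PE")
            for p_, n_, e_ in zip(pts, nm, el):
                coords.append(p_)
                names.append(n_)
                elements.append(e_)
                resids.append(rid)
            species_res[sp].append(rid)
            next_res += 1

    from ._elements import element_mass, element_vdw
    n_atoms = len(names)
    topo = Topology(
        name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        mass=np.array([element_mass(e) for e in elements]),
        charge=np.zeros(n_atoms),
        vdw=np.array([element_vdw(e) for e in elements]),
        resid=np.array(resids, dtype=int),
        resname=np.array(resnames, dtype=object),
        segments=[Segment(lbl, "lipid", np.array(res))
                  for sp, lbl in (("pc", "PC"), ("pe", "PE"), ("sterol", "CHL"))
                  if (res := species_res[sp])],
    )
    topo.validate()
    return topo, np.vstack(coords)


# ------------------------------------------------------------------- ligands

@dataclass
class Ligand:
    """Pseudo-molecule with tagged sub-bodies, charges and H-bond chemistry."""

    topology: Topology
    coords: np.ndarray
    donors: list              # (donor_heavy_idx, hydrogen_idx) pairs
    acceptors: list           # heavy-atom indices
    rings: dict               # ring name -> atom index array
    eps: np.ndarray           # LJ well depth per atom, kcal/mol
    sigma: np.ndarray         # LJ sigma per atom, Å

    @property
    def sub_bodies(self) -> list[str]:
        return [str(r) for r in self.topology.resname]


def make_ligand(kind: str, pose=(0.0, 0.0, 0.0)) -> Ligand:
    """Build an ATP-like / LTX-like / sterol-like pseudo-ligand.

    Sub-body split mirrors the coarse node model used in the allosteric
    analysis: ATP-like -> purine + ribose + triphosphate; LTX-like ->
    glutathione + tail + acid; sterol-like -> one body.
    """
    pose = np.asarray(pose, dtype=float)
    atoms: list[tuple[str, str, float, np.ndarray, str]] = []  # name, el, q, xyz, resname
    donors_names: list[tuple[str, str]] = []
    acceptors_names: list[str] = []
    rings: dict[str, list[str]] = {}

    if kind == "atp_like":
        # purine: 6-bead aromatic ring, centroid at local origin
        ring = []
        for i in range(6):
            phi = math.pi / 3.0 * i
            el = "N" if i % 2 else "C"
            nm = f"{el}P{i + 1}"
            atoms.append((nm, el, 0.0, 1.4 * np.array([math.cos(phi), math.sin(phi), 0.0]),
                          "PUR"))
            ring.append(nm)
        atoms.append(("N6", "N", 0.0, np.array([0.0, 2.8, 0.0]), "PUR"))
        atoms.append(("H61", "H", 0.0, np.array([0.0, 3.8, 0.0]), "PUR"))
        donors_names.append(("N6", "H61"))
        acceptors_names += ["NP2", "NP4"]
        rings["purine"] = ring
        for i in range(3):   # ribose
            atoms.append((f"RB{i + 1}", "C", 0.0,
                          np.array([3.0 + 1.4 * i, 0.0, 0.0]), "RIB"))
        atoms.append(("O2'", "O", 0.0, np.array([4.4, 1.2, 0.0]), "RIB"))
        atoms.append(("HO2", "H", 0.0, np.array([4.4, 2.2, 0.0]), "RIB"))
        donors_names.append(("O2'", "HO2"))
        acceptors_names.append("O2'")
        for i, nm in enumerate(("PA", "PB", "PG")):   # triphosphate, -1 e per bead
            atoms.append((nm, "P", -1.0,
                          np.array([7.5 + 1.8 * i, 0.0, 0.0]), "PPP"))
            acceptors_names.append(nm)
        seg_role = "atp"
    elif kind == "ltx_like":
        for i, (nm, el, q) in enumerate((("SG", "S", 0.0), ("NG", "N", 0.0),
                                         ("OG1", "O", -1.0), ("OG2", "O", -1.0))):
            atoms.append((nm, el, q, np.array([1.5 * i, 0.0, 0.0]), "GSH"))
        atoms.append(("HNG", "H", 0.0, np.array([1.5, 1.0, 0.0]), "GSH"))
        donors_names.append(("NG", "HNG"))
        acceptors_names += ["OG1", "OG2"]
        for i in range(4):
            atoms.append((f"CT{i + 1}", "C", 0.0,
                          np.array([6.0 + 1.4 * i, 0.5 * (i % 2), 0.0]), "TAIL"))
        atoms.append(("OA1", "O", -1.0, np.array([12.0, 0.0, 0.0]), "ACID"))
        atoms.append(("OA2", "O", 0.0, np.array([12.8, 1.0, 0.0]), "ACID"))
        acceptors_names += ["OA1", "OA2"]
        seg_role = "ltx"
    elif kind == "sterol_like":
        atoms.append(("O3", "O", 0.0, np.array([0.0, 0.0, 0.0]), "CHL"))
        atoms.append(("HO3", "H", 0.0, np.array([0.0, 0.0, 1.0]), "CHL"))
        donors_names.append(("O3", "HO3"))
        acceptors_names.append("O3")
        ring = []
        for i in range(5):
            phi = 2.0 * math.pi / 5.0 * i
            nm = f"R{i + 1}"
            atoms.append((nm, "C", 0.0,
                          np.array([1.2 * math.cos(phi), 1.2 * math.sin(phi), -2.0]),
                          "CHL"))
            ring.append(nm)
        rings["sterol"] = ring
        seg_role = "sterol"
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")

    names = np.array([a[0] for a in atoms], dtype=object)
    elements = np.array([a[1] for a in atoms], dtype=object)
    charges = np.array([a[2] for a in atoms], dtype=float)
    coords = np.vstack([a[3] for a in atoms]) + pose
    res_labels: list[str] = []
    resid = np.zeros(len(atoms), dtype=int)
    for i, a in enumerate(atoms):
        if not res_labels or res_labels[-1] != a[4]:
            res_labels.append(a[4])
        resid[i] = len(res_labels)

    from ._elements import element_mass, element_vdw
    topo = Topology(
        name=names, element=elements,
        mass=np.array([element_mass(e) for e in elements]),
        charge=charges,
        vdw=np.array([element_vdw(e) for e in elements]),
        resid=resid, resname=np.array(res_labels, dtype=object),
        segments=[Segment(kind.upper(), seg_role,
                          np.arange(1, len(res_labels) + 1))],
    )
    topo.validate()

    name_to_idx = {str(n): i for i, n in enumerate(names)}
    donors = [(name_to_idx[d], name_to_idx[h]) for d, h in donors_names]
    acceptors = [name_to_idx[a] for a in acceptors_names]
    ring_idx = {k: np.array([name_to_idx[n] for n in v]) for k, v in rings.items()}
    # toy LJ parameters: eps 0.1 kcal/mol heavy atoms, 0.02 for H; sigma ~ vdW
    eps = np.where(elements == "H", 0.02, 0.1).astype(float)
    sigma = np.asarray(topo.vdw, float) * 2.0 / (2.0 ** (1.0 / 6.0))
    return Ligand(topo, coords, donors, acceptors, ring_idx, eps, sigma)


# ----------------------------------------------------------------- combining

def merge_systems(*systems):
    """Concatenate (topology, coords) pairs into one system, renumbering
    residues; returns (topology, coords)."""
    names, elements, mass, charge, vdw = [], [], [], [], []
    resid, resnames, segments, frames = [], [], [], []
    res_offset = 0
    for topo, coords in systems:
        names.append(np.asarray(topo.name, dtype=object))
        elements.append(np.asarray(topo.element, dtype=object))
        mass.append(np.asarray(topo.mass, float))
        charge.append(np.asarray(topo.charge, float))
        vdw.append(np.asarray(topo.vdw, float))
        resid.append(np.asarray(topo.resid, int) + res_offset)
        resnames.append(np.asarray(topo.resname, dtype=object))
        for seg in topo.segments:
            segments.append(Segment(seg.name, seg.role,
                                    np.asarray(seg.resids, int) + res_offset))
        frames.append(np.asarray(coords, float))
        res_offset += topo.n_residues
    merged = Topology(
        name=np.concatenate(names), element=np.concatenate(elements),
        mass=np.concatenate(mass), charge=np.concatenate(charge),
        vdw=np.concatenate(vdw), resid=np.concatenate(resid),
        resname=np.concatenate(resnames), segments=segments,
    )
    merged.validate()
    return merged, np.vstack(frames)
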