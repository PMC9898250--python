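"""ABC-transporter conformational descriptors.

The opening of the two transporter gates is measured as angles between
centre-of-mass (COM) vectors over fixed half-transporter helix groups:

* IC angle — the intracellular opening for substrate entry: the angle between
  two vectors starting at the COM of the whole extracellular region and
  directed toward the IC regions of TMH1,2,3,6,10,11 and TMH4,5,7,8,9,12;
* EC angle — the extracellular opening for substrate release: the angle
  between two vectors starting at the COM of both NBDs and directed toward
  the EC regions of TMH1,2,9,10,11,12 and TMH3,4,5,6,7,8; the EC distance is
  the distance between those two EC half-group COMs;
* NBD distance — between the two NBD COMs; NBD rocking-twist — the signed
  dihedral COM(lobe1)–COM(NBD1)–COM(NBD2)–COM(lobe2), right-handed about the
  NBD1→NBD2 axis;
* the NBS Gly–Ser distances pair the Walker A glycine of one NBD with the
  ABC-signature serine of the other (Cα–Cα, minimal image).

All descriptors are invariant to global rotation and translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import (SelectionScheme, Topology, Trajectory, ResultTable,
                       minimum_image)

BACKBONE_NAMES = ("N", "CA", "C", "O")


class DegenerateGeometryError(ValueError):
    """A descriptor's defining vectors vanish or collapse."""


# ------------------------------------------------------------------ COM math

def _group_atoms(topology: Topology, resids, selection: str = "backbone") -> np.ndarray:
    idx = topology.atoms_of_residues(resids)
    if selection == "backbone":
        mask = np.isin(np.asarray(topology.name, dtype=object)[idx], BACKBONE_NAMES)
        if mask.any():
            idx = idx[mask]
    return idx


def center_of_mass(frame: np.ndarray, topology: Topology, atom_idx,
                   mass_weighted: bool = True) -> np.ndarray:
    """Σ m_i r_i / Σ m_i over the atom set (or plain mean when unweighted).

    ``frame`` may be (N, 3) or (F, N, 3); the COM is returned per frame.
    """
    atom_idx = np.asarray(atom_idx, dtype=int)
    if atom_idx.size == 0:
        raise ValueError("centre of mass of an empty atom set")
    coords = np.asarray(frame, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    sub = coords[:, atom_idx, :]
    if mass_weighted:
        w = np.asarray(topology.mass, float)[atom_idx]
        com = (sub * w[None, :, None]).sum(axis=1) / w.sum()
    else:
        com = sub.mean(axis=1)
    return com[0] if single else com


def _scheme_com(coords: np.ndarray, topology: Topology, scheme_resids,
                mass_weighted: bool, selection: str) -> np.ndarray:
    idx = _group_atoms(topology, scheme_resids, selection)
    return center_of_mass(coords, topology, idx, mass_weighted)


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-10) or np.any(n2 < 1e-10):
        raise DegenerateGeometryError("zero-length descriptor vector (coincident COMs)")
    cosang = np.clip((v1 * v2).sum(axis=-1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral in degrees, right-handed about the p1→p2 axis.

    Accepts points of shape (3,) or (F, 3).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    u1, u2, u3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or \
       np.any(np.linalg.norm(n2, axis=-1) < 1e-10):
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    u2n = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    y = (np.cross(n1, n2) * u2n).sum(axis=-1)
    x = (n1 * n2).sum(axis=-1)
    return np.degrees(np.arctan2(y, x))


# --------------------------------------------------------------- descriptors

def ic_angle(frame, topology: Topology, scheme: SelectionScheme,
             mass_weighted: bool = True, selection: str = "backbone"):
    """Intracellular opening angle (degrees)."""
    e = _scheme_com(frame, topology, scheme.ec_whole(), mass_weighted, selection)
    ia = _scheme_com(frame, topology, scheme.ic_half("A"), mass_weighted, selection)
    ib = _scheme_com(frame, topology, scheme.ic_half("B"), mass_weighted, selection)
    return _angle_between(ia - e, ib - e)


def ec_angle_and_distance(frame, topology: Topology, scheme: SelectionScheme,
                          mass_weighted: bool = True, selection: str = "backbone"):
    """Extracellular opening angle (degrees) and EC half-group distance (Å)."""
    n = _scheme_com(frame, topology, scheme.nbd_both(), mass_weighted, selection)
    ea = _scheme_com(frame, topology, scheme.ec_half("A"), mass_weighted, selection)
    eb = _scheme_com(frame, topology, scheme.ec_half("B"), mass_weighted, selection)
    # coincident EC halves: opening fully closed -> (0°, 0 Å)
    sep = np.linalg.norm(ea - eb, axis=-1)
    if np.all(sep < 1e-10):
        zero = np.zeros_like(sep)
        return zero, zero
    return _angle_between(ea - n, eb - n), sep


def nbd_distance_and_twist(frame, topology: Topology, scheme: SelectionScheme,
                           mass_weighted: bool = True, selection: str = "backbone"):
    """NBD COM distance (Å) and signed rocking-twist dihedral (degrees)."""
    c1 = _scheme_com(frame, topology, scheme.group("nbd1"), mass_weighted, selection)
    c2 = _scheme_com(frame, topology, scheme.group("nbd2"), mass_weighted, selection)
    l1 = _scheme_com(frame, topology, scheme.group("nbd1_lobe"), mass_weighted, selection)
    l2 = _scheme_com(frame, topology, scheme.group("nbd2_lobe"), mass_weighted, selection)
    return np.linalg.norm(c2 - c1, axis=-1), dihedral(l1, c1, c2, l2)


def nbs_gs_distances(frame, topology: Topology, scheme: SelectionScheme,
                     box=None):
    """Cα–Cα Walker-A-Gly / signature-Ser distances for NBS1 and NBS2 (Å),
    minimal image when a box is given."""
    coords = np.asarray(frame, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    out = []
    for grp in ("gs_nbs1", "gs_nbs2"):
        ra, rb = scheme.group(grp)
        ia, ib = topology.ca_index(ra), topology.ca_index(rb)
        delta = coords[:, ib, :] - coords[:, ia, :]
        if box is not None:
            delta = minimum_image(delta, np.asarray(box, float))
        out.append(np.linalg.norm(delta, axis=-1))
    d1, d2 = out
    return (float(d1[0]), float(d2[0])) if single else (d1, d2)


def helix_tilt(frame: np.ndarray, topology: Topology, resids,
               normal=(0.0, 0.0, 1.0)) -> float:
    """Angle between the helix principal axis (oriented IC→EC, i.e. with
    increasing residue order) and the reference normal, folded to [0°, 90°]."""
    ca_idx = topology.atoms_named(resids, ["CA"])
    if len(ca_idx) < 4:
        raise ValueError(f"helix needs >= 4 Cα atoms, found {len(ca_idx)}")
    pts = np.asarray(frame, float)[ca_idx]
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred
    if np.linalg.norm(cov) < 1e-12:
        raise DegenerateGeometryError("all helix Cα coincide")
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if np.dot(axis, pts[-1] - pts[0]) < 0:
        axis = -axis
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    cosang = abs(float(np.dot(axis, normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------- superposition

def superpose_and_rmsd(mobile: np.ndarray, reference: np.ndarray,
                       atom_idx=None):
    """Least-squares rigid superposition (Kabsch, proper rotation enforced).

    Returns (rotation (3,3), translation (3,), rmsd Å) such that
    ``mobile @ R.T + t`` best fits ``reference`` on the atom set.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if atom_idx is None:
        atom_idx = np.arange(len(mobile))
    atom_idx = np.asarray(atom_idx, int)
    if len(atom_idx) < 3:
        raise ValueError("superposition needs >= 3 atoms")
    m = mobile[atom_idx]
    r = reference[atom_idx]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - r) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def align_frames(coords: np.ndarray, reference: np.ndarray,
                 atom_idx=None) -> np.ndarray:
    """Superpose every frame of (F, N, 3) onto the reference frame."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = superpose_and_rmsd(coords[f], reference, atom_idx)
        out[f] = coords[f] @ rot.T + trans
    return out


def rmsf(trajectory: Trajectory, atom_idx, align_idx=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after alignment to the
    trajectory-average structure (average recomputed once after a first
    alignment pass)."""
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    atom_idx = np.asarray(atom_idx, int)
    if align_idx is None:
        align_idx = atom_idx
    coords = trajectory.coords
    mean0 = coords.mean(axis=0)
    aligned = align_frames(coords, mean0, align_idx)
    mean1 = aligned.mean(axis=0)
    aligned = align_frames(aligned, mean1, align_idx)
    mean2 = aligned.mean(axis=0)
    dev = aligned[:, atom_idx, :] - mean2[atom_idx]
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


# ------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    components: np.ndarray               # (K, 3M) unit-norm eigenvectors
    explained_variance_ratio: np.ndarray
    domain_contributions: pd.DataFrame   # rows = components, cols = domains
    atom_idx: np.ndarray

    def summary(self) -> pd.DataFrame:
        df = self.domain_contributions.copy()
        df.insert(0, "explained_variance", self.explained_variance_ratio)
        return df


_PCA_DOMAINS = {
    "TMD1": [f"tmh{i}_{s}" for i in range(1, 7) for s in ("ic", "ec")],
    "TMD2": [f"tmh{i}_{s}" for i in range(7, 13) for s in ("ic", "ec")],
    "NBD1": ["nbd1"],
    "NBD2": ["nbd2"],
}


def pca_abc_core(trajectory: Trajectory, topology: Topology,
                 scheme: SelectionScheme, n_components: int = 3) -> PCAResult:
    """PCA of the ABC core (backbone of TMH1–12 + NBD1 + NBD2) after
    superposition of every frame on the core's average structure.

    Per-domain contribution of component k is the summed squared loading over
    the domain's Cartesian triplets (contributions over TMD1/TMD2/NBD1/NBD2
    sum to 1 for each component).
    """
    domain_resids = {d: scheme.union(gs) for d, gs in _PCA_DOMAINS.items()}
    core_resids = []
    for rs in domain_resids.values():
        core_resids.extend(rs)
    idx = _group_atoms(topology, core_resids, "backbone")

    coords = trajectory.coords
    mean0 = coords.mean(axis=0)
    aligned = align_frames(coords, mean0, idx)
    x = aligned[:, idx, :].reshape(trajectory.n_frames, -1)
    x = x - x.mean(axis=0)
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    lam = s ** 2
    total = lam.sum()
    if total <= 0:
        raise ValueError("trajectory has no variance on the ABC core")
    rank = int((lam > 1e-12 * lam[0]).sum())
    k = min(n_components, rank)
    if k < n_components:
        import warnings
        warnings.warn(f"requested {n_components} components, covariance rank is {rank}")
    comps = vt[:k]
    evr = lam[:k] / total

    # map each atom of the core to its domain
    atom_domain = np.empty(len(idx), dtype=object)
    for d, rs in domain_resids.items():
        mask = np.isin(np.asarray(topology.resid)[idx], list(rs))
        atom_domain[mask] = d
    contrib = {}
    for d in _PCA_DOMAINS:
        cols = np.flatnonzero(atom_domain == d)
        cart = np.concatenate([3 * cols, 3 * cols + 1, 3 * cols + 2])
        contrib[d] = (comps[:, cart] ** 2).sum(axis=1)
    df = pd.DataFrame(contrib, index=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(comps, evr, df, idx)


# --------------------------------------------------- reference-space mapping

#: conformation classes used when building the reference ABC space
CONFORMATION_CLASSES = ("IF open", "IF occluded", "OF", "UR turnover")


def descriptor_vector(frame, topology: Topology, scheme: SelectionScheme) -> dict:
    """The four projection coordinates of one frame."""
    ic = ic_angle(frame, topology, scheme)
    ec, _ecd = ec_angle_and_distance(frame, topology, scheme)
    d, tw = nbd_distance_and_twist(frame, topology, scheme)
    return {"ic_angle": float(ic), "ec_angle": float(ec),
            "nbd_distance": float(d), "nbd_twist": float(tw)}


def project_reference_space(references, trajectory: Trajectory | None = None,
                            topology: Topology | None = None,
                            scheme: SelectionScheme | None = None) -> pd.DataFrame:
    """Joint table of reference structures and trajectory frames in the
    (IC angle, EC angle, NBD distance, NBD twist) descriptor space.

    ``references``: iterable of (label, conformation_class, topology, frame,
    scheme); a reference whose scheme is None is skipped with a warning.
    """
    import warnings
    rows = []
    for label, conf, topo_r, frame_r, scheme_r in references:
        if scheme_r is None:
            warnings.warn(f"no selection scheme for reference {label!r}; skipped")
            continue
        vec = descriptor_vector(frame_r, topo_r, scheme_r)
        rows.append({"label": label, "class": conf, "frame": -1, **vec})
    if trajectory is not None:
        ic = ic_angle(trajectory.coords, topology, scheme)
        ec, _d = ec_angle_and_distance(trajectory.coords, topology, scheme)
        dist, tw = nbd_distance_and_twist(trajectory.coords, topology, scheme)
        for f in range(trajectory.n_frames):
            rows.append({"label": "trajectory", "class": "MD", "frame": f,
                         "ic_angle": float(ic[f]), "ec_angle": float(ec[f]),
                         "nbd_distance": float(dist[f]), "nbd_twist": float(tw[f])})
    return pd.DataFrame(rows, columns=["label", "class", "frame", "ic_angle",
                                       "ec_angle", "nbd_distance", "nbd_twist"])


# ---------------------------------------------------------------- series

def descriptor_series(trajectory: Trajectory, topology: Topology,
                      scheme: SelectionScheme, system: str = "synthetic",
                      replica: int = 0) -> ResultTable:
    """Per-frame descriptor table (one row per frame per metric)."""
    coords = trajectory.coords
    ic = ic_angle(coords, topology, scheme)
    ec, ecd = ec_angle_and_distance(coords, topology, scheme)
    dist, tw = nbd_distance_and_twist(coords, topology, scheme)
    g1, g2 = nbs_gs_distances(coords, topology, scheme, box=trajectory.box)
    metrics = {
        "ic_angle": (ic, "deg"), "ec_angle": (ec, "deg"),
        "ec_distance": (ecd, "A"), "nbd_distance": (dist, "A"),
        "nbd_twist": (tw, "deg"), "d_gs_nbs1": (g1, "A"), "d_gs_nbs2": (g2, "A"),
    }
    records = []
    for name, (vals, unit) in metrics.items():
        vals = np.broadcast_to(np.asarray(vals, float), (trajectory.n_frames,))
        for f in range(trajectory.n_frames):
            records.append((system, replica, f, name, float(vals[f]), unit))
    return ResultTable.from_records(records)
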