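"""Lipid bilayer structure analyses.

Order parameters S_CD(k) = <(3 cos²θ - 1)/2> over frames, lipids and the H
atoms of carbon k, with θ the angle between the C–H bond and the bilayer
normal (z); leaflet-resolved 2D densities of head-group markers; per-lipid
protein-contact occupancies with 50%/80% hotspot thresholds; a gridded
leaflet-to-leaflet thickness field; and a simplified continuum deformation
free energy

    ΔG = ∫ [ (K_A/2) (2u/h0)² + (K_C/2) (∇²u)² ] dA ,   u = (h - h0)/2,

with compression modulus K_A, bending modulus K_C and periodic central
differences for the Laplacian.  The functional is a positive-definite
quadratic form, so ΔG >= 0 for any non-flat field; negative deformation free
energies only arise as differences against a user-supplied reference energy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import Topology, Trajectory

log = logging.getLogger("abctraj")

TAIL_TAGS = {"sn1": "A", "sn2": "B"}
HEAD_MARKERS = {"PC": "P", "PE": "P", "CHL": "O3"}

# defaults in Å-based units: K_A in kcal/mol/Å² (0.6 ≙ 60 kcal/mol/nm²),
# K_C in kcal/mol·Å² (2000 ≙ 20 kcal/mol·nm²)
DEFAULT_KA = 0.6
DEFAULT_KC = 2000.0


def bilayer_center(frame: np.ndarray, topology: Topology) -> float:
    """z of the bilayer centre from the phosphate-marker z-density midpoint."""
    p_idx = np.flatnonzero(np.asarray(topology.name, dtype=object) == "P")
    if len(p_idx) == 0:
        raise ValueError("no phosphate markers (atoms named 'P') found")
    z = np.asarray(frame, float)[p_idx, 2]
    split = z.mean()
    upper, lower = z[z >= split], z[z < split]
    if len(upper) == 0 or len(lower) == 0:
        raise ValueError("could not separate two leaflets from phosphate z values")
    return float(0.5 * (upper.mean() + lower.mean()))


# --------------------------------------------------------------- S_CD

def order_parameters(trajectory: Trajectory, topology: Topology,
                     species: str = "PC", tail: str = "sn1",
                     normal=(0.0, 0.0, 1.0)) -> pd.DataFrame:
    """S_CD per carbon for one species' sn1 ('A') or sn2 ('B') tail.

    Returns a DataFrame (carbon, s_cd, n_samples); carbons without attached
    hydrogens are skipped and logged.
    """
    if tail not in TAIL_TAGS:
        raise ValueError(f"tail must be one of {sorted(TAIL_TAGS)}")
    tag = TAIL_TAGS[tail]
    resids = [r for r in range(1, topology.n_residues + 1)
              if topology.resname[r - 1] == species]
    if not resids:
        raise ValueError(f"no residues of species {species!r}")
    names = np.asarray(topology.name, dtype=object)
    res_of = np.asarray(topology.resid, int)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)

    carbon_re = re.compile(rf"^C(\d+){tag}$")
    carbons: dict[int, dict[int, int]] = {}       # k -> resid -> atom idx
    hydros: dict[int, dict[int, list[int]]] = {}  # k -> resid -> [h idx]
    resset = set(resids)
    for i, nm in enumerate(names):
        rid = int(res_of[i])
        if rid not in resset:
            continue
        m = carbon_re.match(str(nm))
        if m:
            carbons.setdefault(int(m.group(1)), {})[rid] = i
            continue
        mh = re.match(rf"^H(\d+){tag}\d$", str(nm))
        if mh:
            hydros.setdefault(int(mh.group(1)), {}).setdefault(rid, []).append(i)

    rows = []
    coords = trajectory.coords
    for k in sorted(carbons):
        c_map = carbons[k]
        h_map = hydros.get(k, {})
        pairs = [(c_map[r], h) for r in c_map for h in h_map.get(r, [])]
        if not pairs:
            log.warning("carbon C%d%s has no attached hydrogens; skipped", k, tag)
            continue
        c_idx = np.array([p[0] for p in pairs])
        h_idx = np.array([p[1] for p in pairs])
        vec = coords[:, h_idx, :] - coords[:, c_idx, :]
        cos = (vec @ normal) / np.linalg.norm(vec, axis=-1)
        s_cd = float((1.5 * cos ** 2 - 0.5).mean())
        rows.append({"carbon": k, "s_cd": s_cd,
                     "n_samples": int(cos.size)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------- densities

def density_2d(trajectory: Trajectory, topology: Topology, species: str,
               leaflet: str = "upper", grid_spacing: float = 2.0,
               center_z: float | None = None):
    """Time-averaged xy density (counts/Å²/frame) of the species' head marker
    in one leaflet.  Returns (grid, x_edges, y_edges)."""
    import warnings
    marker = HEAD_MARKERS.get(species)
    names = np.asarray(topology.name, dtype=object)
    res_of = np.asarray(topology.resid, int)
    idx = np.array([i for i in range(topology.n_atoms)
                    if names[i] == marker
                    and topology.resname[res_of[i] - 1] == species], dtype=int)
    box = trajectory.box[0]
    nx = max(int(round(box[0] / grid_spacing)), 1)
    ny = max(int(round(box[1] / grid_spacing)), 1)
    x_edges = np.linspace(-box[0] / 2, box[0] / 2, nx + 1)
    y_edges = np.linspace(-box[1] / 2, box[1] / 2, ny + 1)
    grid = np.zeros((nx, ny))
    if len(idx) == 0:
        warnings.warn(f"species {species!r} absent; returning empty grid")
        return grid, x_edges, y_edges
    if center_z is None:
        center_z = bilayer_center(trajectory.coords[0], topology) \
            if (names == "P").any() else 0.0
    sign = 1.0 if leaflet == "upper" else -1.0
    for f in range(trajectory.n_frames):
        pos = trajectory.coords[f, idx, :]
        keep = sign * (pos[:, 2] - center_z) > 0
        h, _, _ = np.histogram2d(pos[keep, 0], pos[keep, 1],
                                 bins=[x_edges, y_edges])
        grid += h
    cell_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    return grid / (trajectory.n_frames * cell_area), x_edges, y_edges


# --------------------------------------------------------------- occupancy

def occupancy_hotspots(trajectory: Trajectory, topology: Topology,
                       protein_idx, cutoff: float = 6.0,
                       thresholds=(0.5, 0.8),
                       species: tuple = ("PC", "PE", "CHL")) -> pd.DataFrame:
    """Fraction of frames each lipid molecule keeps heavy-atom contact with
    the protein selection; hotspots reported against each threshold.

    Returns a DataFrame (lipid_resid, species, fraction, hotspot_50/80...,
    touching_residues).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    protein_idx = topology.heavy_atoms(np.asarray(protein_idx, int))
    res_of = np.asarray(topology.resid, int)
    lipid_res = [r for r in range(1, topology.n_residues + 1)
                 if topology.resname[r - 1] in species]
    lipid_atoms = {r: topology.heavy_atoms(topology.atoms_of_residues([r]))
                   for r in lipid_res}
    contact = {r: 0 for r in lipid_res}
    touching: dict[int, set] = {r: set() for r in lipid_res}
    for f in range(trajectory.n_frames):
        tree = cKDTree(trajectory.coords[f, protein_idx, :])
        for r, idx in lipid_atoms.items():
            pairs = tree.query_ball_point(trajectory.coords[f, idx, :], cutoff)
            hit = [j for sub in pairs for j in sub]
            if hit:
                contact[r] += 1
                touching[r].update(int(res_of[protein_idx[j]]) for j in hit)
    rows = []
    for r in lipid_res:
        frac = contact[r] / trajectory.n_frames
        row = {"lipid_resid": r, "species": str(topology.resname[r - 1]),
               "fraction": frac}
        for t in thresholds:
            row[f"hotspot_{int(round(t * 100))}"] = bool(frac >= t)
        row["touching_residues"] = sorted(touching[r])
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- thickness

@dataclass
class ThicknessField:
    thickness: np.ndarray       # (nx, ny) Å
    interpolated: np.ndarray    # flagged cells filled from neighbours
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.thickness.mean())


def thickness_map(trajectory: Trajectory, topology: Topology,
                  grid_spacing: float = 10.0) -> ThicknessField:
    """Distance between the two leaflets' phosphate-marker mean-z surfaces,
    gridded over xy; cells missing one leaflet are interpolated from their
    neighbours and flagged."""
    names = np.asarray(topology.name, dtype=object)
    p_idx = np.flatnonzero(names == "P")
    if len(p_idx) == 0:
        raise ValueError("no phosphate markers found")
    center = bilayer_center(trajectory.coords[0], topology)
    box = trajectory.box[0]
    nx = max(int(round(box[0] / grid_spacing)), 1)
    ny = max(int(round(box[1] / grid_spacing)), 1)
    x_edges = np.linspace(-box[0] / 2, box[0] / 2, nx + 1)
    y_edges = np.linspace(-box[1] / 2, box[1] / 2, ny + 1)
    z_sum = {s: np.zeros((nx, ny)) for s in (1, -1)}
    counts = {s: np.zeros((nx, ny)) for s in (1, -1)}
    for f in range(trajectory.n_frames):
        pos = trajectory.coords[f, p_idx, :]
        up = pos[:, 2] > center
        for s, sel in ((1, up), (-1, ~up)):
            if not sel.any():
                continue
            xi = np.clip(np.digitize(pos[sel, 0], x_edges) - 1, 0, nx - 1)
            yi = np.clip(np.digitize(pos[sel, 1], y_edges) - 1, 0, ny - 1)
            np.add.at(z_sum[s], (xi, yi), pos[sel, 2])
            np.add.at(counts[s], (xi, yi), 1.0)
    if counts[1].sum() == 0 or counts[-1].sum() == 0:
        raise ValueError("one leaflet is empty; thickness undefined")
    with np.errstate(invalid="ignore"):
        upper = z_sum[1] / counts[1]
        lower = z_sum[-1] / counts[-1]
    thickness = upper - lower
    bad = ~np.isfinite(thickness)
    if bad.any():
        good_mean = float(thickness[~bad].mean())
        filled = thickness.copy()
        for i, j in np.argwhere(bad):
            neigh = [thickness[(i + di) % nx, (j + dj) % ny]
                     for di in (-1, 0, 1) for dj in (-1, 0, 1)
                     if (di, dj) != (0, 0)]
            neigh = [v for v in neigh if np.isfinite(v)]
            filled[i, j] = float(np.mean(neigh)) if neigh else good_mean
        thickness = filled
    return ThicknessField(thickness, bad, x_edges, y_edges)


# --------------------------------------------------------- deformation energy

def deformation_energy(thickness: np.ndarray, h0: float,
                       k_a: float = DEFAULT_KA, k_c: float = DEFAULT_KC,
                       dx: float = 10.0, dy: float = 10.0,
                       reference_energy: float = 0.0) -> float:
    """Continuum elastic deformation free energy of a thickness field.

    ``thickness`` is the gridded leaflet-to-leaflet distance h(x, y); h0 the
    unperturbed thickness; K_A (kcal/mol/Å²) and K_C (kcal/mol·Å²) the
    compression and bending moduli.  ΔG is the discrete quadrature of the
    two-term functional minus ``reference_energy`` (the same functional of a
    reference field, zero for a flat membrane).
    """
    h = np.asarray(thickness, dtype=float)
    if h.ndim != 2 or min(h.shape) < 4:
        raise ValueError("thickness grid must be 2D with >= 4 cells per side")
    if k_a <= 0 or k_c <= 0 or h0 <= 0:
        raise ValueError("moduli and reference thickness must be > 0")
    u = (h - h0) / 2.0
    lap = ((np.roll(u, 1, axis=0) - 2 * u + np.roll(u, -1, axis=0)) / dx ** 2
           + (np.roll(u, 1, axis=1) - 2 * u + np.roll(u, -1, axis=1)) / dy ** 2)
    dens = 0.5 * k_a * (2.0 * u / h0) ** 2 + 0.5 * k_c * lap ** 2
    return float(dens.sum() * dx * dy - reference_energy)
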