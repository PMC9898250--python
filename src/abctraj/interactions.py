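"""Hydrogen bonds, ligand–site potentials and π-stacking distances.

An H-bond is counted in a frame when the heavy donor–acceptor distance is at
most 3.5 Å and the donor–H···acceptor angle (vertex at the hydrogen) is at
least 120°.  Ligand–site Coulomb and Lennard-Jones sums use plain truncation
at the cutoff (no switching), minimal-image distances, k_e = 332.06
kcal·Å·mol⁻¹·e⁻² and Lorentz–Berthelot combination; these pairwise sums are
comparative tools, not converged electrostatics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .topology import Topology, Trajectory, minimum_image

log = logging.getLogger("abctraj")

KE_KCAL = 332.06          # Coulomb constant, kcal·Å/(mol·e²)
DEFAULT_D_CUT = 3.5       # Å donor–acceptor
DEFAULT_A_CUT = 120.0     # degrees at the hydrogen
DEFAULT_NB_CUTOFF = 10.0  # Å non-bonded truncation


def hbond_present(d_a_distance, d_h_a_angle, d_cut: float = DEFAULT_D_CUT,
                  a_cut: float = DEFAULT_A_CUT):
    """The H-bond decision function (distance AND angle criterion)."""
    return (np.asarray(d_a_distance) <= d_cut) & (np.asarray(d_h_a_angle) >= a_cut)


def detect_hbonds(trajectory: Trajectory, donors, acceptors,
                  d_cut: float = DEFAULT_D_CUT, a_cut: float = DEFAULT_A_CUT,
                  use_box: bool = True) -> pd.DataFrame:
    """Per-pair H-bond fractions over frames.

    ``donors``: iterable of (donor_heavy_idx, hydrogen_idx); a donor whose
    hydrogen index is None is skipped with a log message.  Returns a
    DataFrame (donor, hydrogen, acceptor, fraction, n_frames).
    """
    coords = trajectory.coords
    box = trajectory.box if use_box else None
    rows = []
    for d, h in donors:
        if h is None:
            log.warning("donor atom %s has no hydrogen; skipped", d)
            continue
        for a in acceptors:
            if a == d:
                continue
            da = coords[:, a, :] - coords[:, d, :]
            hd = coords[:, d, :] - coords[:, h, :]
            ha = coords[:, a, :] - coords[:, h, :]
            if box is not None:
                da = minimum_image(da, box)
                hd = minimum_image(hd, box)
                ha = minimum_image(ha, box)
            dist = np.linalg.norm(da, axis=1)
            cosang = (hd * ha).sum(axis=1) / (
                np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            present = hbond_present(dist, angle, d_cut, a_cut)
            rows.append({"donor": int(d), "hydrogen": int(h), "acceptor": int(a),
                         "fraction": float(present.mean()),
                         "n_frames": trajectory.n_frames})
    return pd.DataFrame(rows)


def aggregate_hbond_replicas(replica_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Fractions computed per replica independently, then averaged across
    replicas with the sd taken over replica values."""
    stacked = pd.concat(
        [t.assign(replica=i) for i, t in enumerate(replica_tables)], ignore_index=True)
    agg = (stacked.groupby(["donor", "hydrogen", "acceptor"])["fraction"]
           .agg(n="count", mean="mean",
                sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
           .reset_index())
    return agg


def interaction_energy(trajectory: Trajectory, charges, eps, sigma,
                       idx_a, idx_b, dielectric: float = 1.0,
                       cutoff: float = DEFAULT_NB_CUTOFF,
                       use_box: bool = True) -> pd.DataFrame:
    """Per-frame Coulomb and Lennard-Jones sums between two selections.

    E_coul = Σ k_e q_i q_j / (ε_r r_ij);  E_LJ = Σ 4 ε_ij [(σ_ij/r)¹² - (σ_ij/r)⁶]
    over inter-selection pairs within the cutoff (minimal image).
    """
    idx_a = np.asarray(idx_a, int)
    idx_b = np.asarray(idx_b, int)
    charges = np.asarray(charges, float)
    eps = np.asarray(eps, float)
    sigma = np.asarray(sigma, float)
    for arr, label in ((charges, "charge"), (eps, "epsilon"), (sigma, "sigma")):
        needed = np.concatenate([idx_a, idx_b])
        bad = needed[~np.isfinite(arr[needed])]
        if len(bad):
            raise ValueError(f"missing {label} parameters for atoms {bad.tolist()}")
    qq = KE_KCAL * np.outer(charges[idx_a], charges[idx_b]) / dielectric
    eij = np.sqrt(np.outer(eps[idx_a], eps[idx_b]))
    sij = 0.5 * (sigma[idx_a][:, None] + sigma[idx_b][None, :])
    rows = []
    for f in range(trajectory.n_frames):
        delta = (trajectory.coords[f, idx_a, :][:, None, :]
                 - trajectory.coords[f, idx_b, :][None, :, :])
        if use_box:
            delta = minimum_image(delta, trajectory.box[f])
        r = np.linalg.norm(delta, axis=2)
        within = (r <= cutoff) & (r > 1e-10)
        coul = float((qq[within] / r[within]).sum())
        sr6 = (sij[within] / r[within]) ** 6
        lj = float((4.0 * eij[within] * (sr6 ** 2 - sr6)).sum())
        rows.append({"frame": f, "coulomb": coul, "vdw": lj})
    return pd.DataFrame(rows)


def pi_stacking(trajectory: Trajectory, ring_a_idx, ring_b_idx) -> np.ndarray:
    """Per-frame distance between the two rings' heavy-atom centroids (Å)."""
    ring_a_idx = np.asarray(ring_a_idx, int)
    ring_b_idx = np.asarray(ring_b_idx, int)
    if len(ring_a_idx) < 5 or len(ring_b_idx) < 5:
        raise ValueError("each ring needs >= 5 atoms")
    ca = trajectory.coords[:, ring_a_idx, :].mean(axis=1)
    cb = trajectory.coords[:, ring_b_idx, :].mean(axis=1)
    return np.linalg.norm(ca - cb, axis=1)
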