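"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (plain loops, exhaustive enumeration,
closed forms) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ----------------------------------------------------- descriptor geometry

def com_naive(points, masses=None):
    points = [np.asarray(p, float) for p in points]
    if masses is None:
        masses = [1.0] * len(points)
    total = sum(masses)
    acc = np.zeros(3)
    for p, m in zip(points, masses):
        acc += m * p
    return acc / total


def angle_naive(v1, v2):
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def dihedral_naive(p0, p1, p2, p3):
    """Signed dihedral, right-handed about the p1→p2 axis."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    axis = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), axis))
    return math.degrees(math.atan2(y, x))


def _group_points(frame, topology, resids, backbone=("N", "CA", "C", "O")):
    pts, masses = [], []
    rid_set = set(int(r) for r in resids)
    names = list(topology.name)
    has_backbone = any(names[i] in backbone and int(topology.resid[i]) in rid_set
                       for i in range(topology.n_atoms))
    for i in range(topology.n_atoms):
        if int(topology.resid[i]) in rid_set:
            if has_backbone and names[i] not in backbone:
                continue
            pts.append(frame[i])
            masses.append(float(topology.mass[i]))
    return pts, masses


def scheme_com_naive(frame, topology, resids):
    pts, masses = _group_points(frame, topology, resids)
    return com_naive(pts, masses)


def ic_angle_naive(frame, topology, scheme):
    e = scheme_com_naive(frame, topology, scheme.ec_whole())
    ia = scheme_com_naive(frame, topology, scheme.ic_half("A"))
    ib = scheme_com_naive(frame, topology, scheme.ic_half("B"))
    return angle_naive(ia - e, ib - e)


def ec_angle_and_distance_naive(frame, topology, scheme):
    n = scheme_com_naive(frame, topology, scheme.nbd_both())
    ea = scheme_com_naive(frame, topology, scheme.ec_half("A"))
    eb = scheme_com_naive(frame, topology, scheme.ec_half("B"))
    return angle_naive(ea - n, eb - n), float(np.linalg.norm(ea - eb))


def nbd_distance_and_twist_naive(frame, topology, scheme):
    c1 = scheme_com_naive(frame, topology, scheme.group("nbd1"))
    c2 = scheme_com_naive(frame, topology, scheme.group("nbd2"))
    l1 = scheme_com_naive(frame, topology, scheme.group("nbd1_lobe"))
    l2 = scheme_com_naive(frame, topology, scheme.group("nbd2_lobe"))
    return float(np.linalg.norm(c2 - c1)), dihedral_naive(l1, c1, c2, l2)


def gs_distances_naive(frame, topology, scheme, box):
    out = []
    for grp in ("gs_nbs1", "gs_nbs2"):
        ra, rb = scheme.group(grp)
        ia = [i for i in range(topology.n_atoms)
              if int(topology.resid[i]) == ra and topology.name[i] == "CA"][0]
        ib = [i for i in range(topology.n_atoms)
              if int(topology.resid[i]) == rb and topology.name[i] == "CA"][0]
        d = np.asarray(frame[ib], float) - np.asarray(frame[ia], float)
        for k in range(3):
            d[k] -= box[k] * round(d[k] / box[k])
        out.append(float(np.linalg.norm(d)))
    return tuple(out)


# ------------------------------------------- resistor networks (Kirchhoff)

def effective_conductance_kirchhoff(g: np.ndarray, source: int, sink: int) -> float:
    """Effective conductance between two nodes by exhaustive enumeration of
    weighted spanning trees and source/sink-separating 2-forests."""
    n = g.shape[0]
    edges = [(i, j, g[i, j]) for i in range(n) for j in range(i + 1, n)
             if g[i, j] > 0]

    def components(edge_subset):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j, _w in edge_subset:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        return [find(x) for x in range(n)]

    tree_sum = 0.0
    forest_sum = 0.0
    for k, size in ((n - 1, "tree"), (n - 2, "forest")):
        for subset in itertools.combinations(edges, k):
            comp = components(subset)
            n_comp = len(set(comp))
            weight = 1.0
            for _i, _j, w in subset:
                weight *= w
            if size == "tree" and n_comp == 1:
                tree_sum += weight
            elif size == "forest" and n_comp == 2 and comp[source] != comp[sink]:
                forest_sum += weight
    if forest_sum == 0.0:
        return math.inf
    return tree_sum / forest_sum


def best_bipartition_modularity(adj: np.ndarray):
    """Exhaustive max-modularity bipartition of a small weighted graph."""
    n = adj.shape[0]
    two_m = adj.sum()
    deg = adj.sum(axis=1)

    def modularity(labels):
        q = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += adj[i, j] - deg[i] * deg[j] / two_m
        return q / two_m

    best_q, best_labels = -np.inf, None
    for bits in range(1 << (n - 1)):     # fix node 0's side to kill symmetry
        labels = [0] + [(bits >> k) & 1 for k in range(n - 1)]
        q = modularity(labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


# -------------------------------------------------------- continuum elastic

def sinusoid_deformation_closed_form(a: float, wavelength: float, area: float,
                                     h0: float, k_a: float, k_c: float) -> float:
    """ΔG of u(x) = a sin(2πx/L): quadrature of sin² gives A/2 of each term."""
    k = 2.0 * math.pi / wavelength
    return 0.5 * area * (k_a * (2.0 * a / h0) ** 2 / 2.0 + k_c * k ** 4 * a ** 2 / 2.0)


# ------------------------------------------------------- pairwise energies

def pair_energy_naive(coords_a, coords_b, q_a, q_b, eps_a, eps_b, sig_a, sig_b,
                      dielectric=1.0, cutoff=1e9):
    ke = 332.06
    coul = lj = 0.0
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            r = float(np.linalg.norm(np.asarray(coords_a[i]) - np.asarray(coords_b[j])))
            if r > cutoff or r < 1e-10:
                continue
            coul += ke * q_a[i] * q_b[j] / (dielectric * r)
            sij = 0.5 * (sig_a[i] + sig_b[j])
            eij = math.sqrt(eps_a[i] * eps_b[j])
            sr6 = (sij / r) ** 6
            lj += 4.0 * eij * (sr6 * sr6 - sr6)
    return coul, lj
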