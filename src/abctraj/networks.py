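"""Correlation networks and allosteric-pathway analysis.

Coarse node model: one node per protein residue anchored on its Cα; three
nodes per phospholipid (polar head plus each tail); ATP-like ligands split
into purine / ribose / triphosphate nodes, LTX-like substrates into
glutathione / tail / acid nodes; sterols and ions are one node each.

DCCM is the normalised covariance of node anchor displacements.  Mutual
information between nodes uses the Gaussian closed form MI = -1/2 ln(1 - ρ²)
with ρ the normalised displacement cross-correlation (an optional histogram
estimator is available).  The communication efficiency between a source and a
sink residue set treats the graph of conductances g_ij = MI_ij × contact_ij
as a resistor network: efficiency is the effective conductance between the
two sets (short-circuited into super-nodes), and each node's betweenness is
the total current flowing through it under unit injected current.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree

from .descriptors import align_frames
from .topology import Topology, Trajectory

log = logging.getLogger("abctraj")

KIND_CLASS = {"residue": "protein", "lipid_head": "lipid", "lipid_tail": "lipid",
              "sterol": "lipid", "atp_part": "ligand", "ltx_part": "ligand",
              "ion": "ion"}


@dataclass
class Node:
    node_id: int
    kind: str
    resid: int
    segment: str
    member_atoms: np.ndarray
    anchor: int                 # atom index used for displacement statistics


def build_nodes(topology: Topology) -> list[Node]:
    """Coarse nodes from a topology's residues and segment roles."""
    role_of_res: dict[int, tuple[str, str]] = {}
    for seg in topology.segments:
        for r in np.asarray(seg.resids, int):
            role_of_res[int(r)] = (seg.role, seg.name)
    names = np.asarray(topology.name, dtype=object)
    nodes: list[Node] = []

    def anchor_from(idx: np.ndarray, preferred: tuple[str, ...]) -> int:
        for nm in preferred:
            hit = idx[names[idx] == nm]
            if len(hit):
                return int(hit[0])
        return int(idx[0])

    for r in range(1, topology.n_residues + 1):
        idx = topology.atoms_of_residues([r])
        role, seg_name = role_of_res.get(r, ("unassigned", "unassigned"))
        resname = str(topology.resname[r - 1])
        if role == "lipid" and resname in ("PC", "PE"):
            head = idx[names[idx] == "P"]
            nodes.append(Node(len(nodes), "lipid_head", r, seg_name, head,
                              int(head[0])))
            for tag in ("A", "B"):
                tail = np.array([i for i in idx if _tail_tag(str(names[i])) == tag])
                if len(tail):
                    carbons = np.array([i for i in tail if str(names[i]).startswith("C")])
                    anchor = int(carbons[len(carbons) // 2]) if len(carbons) else int(tail[0])
                    nodes.append(Node(len(nodes), "lipid_tail", r, seg_name, tail, anchor))
        elif resname == "CHL" or role == "sterol":
            nodes.append(Node(len(nodes), "sterol", r, seg_name, idx,
                              anchor_from(idx, ("O3", "R1"))))
        elif role == "atp":
            nodes.append(Node(len(nodes), "atp_part", r, seg_name, idx,
                              anchor_from(idx, ("NP1", "RB1", "PA"))))
        elif role == "ltx":
            nodes.append(Node(len(nodes), "ltx_part", r, seg_name, idx,
                              anchor_from(idx, ("SG", "CT1", "OA1"))))
        elif role == "ion":
            nodes.append(Node(len(nodes), "ion", r, seg_name, idx, int(idx[0])))
        else:
            nodes.append(Node(len(nodes), "residue", r, seg_name, idx,
                              anchor_from(idx, ("CA",))))
    return nodes


def _tail_tag(name: str) -> str | None:
    import re
    m = re.match(r"^[CH](\d+)([AB])\d?$", name)
    return m.group(2) if m else None


# ------------------------------------------------------------------- DCCM

def _anchor_displacements(trajectory: Trajectory, nodes: list[Node],
                          align_idx=None) -> np.ndarray:
    coords = trajectory.coords
    if align_idx is not None:
        coords = align_frames(coords, coords.mean(axis=0), np.asarray(align_idx, int))
    anchors = np.array([n.anchor for n in nodes])
    x = coords[:, anchors, :]
    return x - x.mean(axis=0)


def dccm(trajectory: Trajectory, nodes: list[Node], align_idx=None) -> np.ndarray:
    """Normalised dynamic cross-correlation matrix over node anchors:
    C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)."""
    if trajectory.n_frames < 2:
        raise ValueError("DCCM needs >= 2 frames")
    dx = _anchor_displacements(trajectory, nodes, align_idx)
    cov = np.einsum("fid,fjd->ij", dx, dx) / dx.shape[0]
    var = np.diag(cov).copy()
    dead = var <= 1e-14
    if dead.any():
        log.warning("%d zero-variance nodes in DCCM", int(dead.sum()))
        var[dead] = 1.0
    c = cov / np.sqrt(np.outer(var, var))
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


# --------------------------------------------------------------- contact map

def contact_map(trajectory: Trajectory, topology: Topology, nodes: list[Node],
                cutoff: float = 4.5, restrictions: bool = True) -> np.ndarray:
    """Fraction of frames with any heavy-atom pair of two nodes within the
    cutoff.  With restrictions on, pairs within the same residue and
    sequence-neighbouring residue pairs are zeroed (the notSameResidue /
    notNeighboring* exclusions of common network tooling)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = len(nodes)
    atom_node = np.full(topology.n_atoms, -1, dtype=int)
    for node in nodes:
        heavy = topology.heavy_atoms(node.member_atoms)
        atom_node[heavy] = node.node_id
    used = np.flatnonzero(atom_node >= 0)
    counts = np.zeros((n, n))
    for f in range(trajectory.n_frames):
        pos = trajectory.coords[f, used, :]
        tree = cKDTree(pos)
        seen = set()
        for a, b in tree.query_pairs(cutoff):
            na, nb = atom_node[used[a]], atom_node[used[b]]
            if na != nb:
                seen.add((min(na, nb), max(na, nb)))
        for na, nb in seen:
            counts[na, nb] += 1
            counts[nb, na] += 1
    frac = counts / trajectory.n_frames
    if restrictions:
        for i, j in combinations(range(n), 2):
            ni, nj = nodes[i], nodes[j]
            if ni.resid == nj.resid or (
                    ni.kind == "residue" and nj.kind == "residue"
                    and abs(ni.resid - nj.resid) <= 1):
                frac[i, j] = frac[j, i] = 0.0
    np.fill_diagonal(frac, 0.0)
    return frac


# -------------------------------------------------------------- communities

def communities(corr: np.ndarray, contacts: np.ndarray,
                contact_threshold: float = 0.75):
    """Girvan–Newman community detection on the contact-filtered correlation
    graph (edge distance -log|C_ij|), returning the partition of maximal
    modularity and its score."""
    n = corr.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        if contacts[i, j] >= contact_threshold and abs(corr[i, j]) > 1e-12:
            w = abs(corr[i, j])
            g.add_edge(i, j, corr=w, distance=-np.log(min(w, 1.0 - 1e-12)))
    if g.number_of_edges() == 0:
        return [], 0.0

    def heaviest(graph):
        bet = nx.edge_betweenness_centrality(graph, weight="distance")
        return max(bet, key=bet.get)

    candidates = [tuple(nx.connected_components(g))]
    for part in nx.community.girvan_newman(g, most_valuable_edge=heaviest):
        candidates.append(part)
        if len(part) >= min(n, 8):
            break
    best, best_q = None, -np.inf
    for part in candidates:
        comm = [set(c) for c in part]
        q = nx.community.modularity(g, comm, weight="corr")
        if q > best_q:
            best, best_q = comm, q
    return best, float(best_q)


# ------------------------------------------------------- mutual information

def mutual_information(trajectory: Trajectory, nodes: list[Node],
                       align_idx=None, estimator: str = "gaussian",
                       bins: int = 24) -> np.ndarray:
    """Pairwise MI (nats) of node displacements.

    The default Gaussian closed form is MI = -1/2 ln(1 - ρ²) with ρ the
    normalised displacement cross-correlation; ``estimator="histogram"``
    bins the x-projections of the displacements instead.
    """
    if trajectory.n_frames < 100:
        warnings.warn("fewer than 100 frames: MI estimates will be noisy")
    if estimator == "gaussian":
        rho = dccm(trajectory, nodes, align_idx)
        off = rho - np.eye(len(nodes))
        mi = -0.5 * np.log(np.clip(1.0 - off ** 2, 1e-12, 1.0))
        np.fill_diagonal(mi, 0.0)
        return mi
    if estimator != "histogram":
        raise ValueError(f"unknown MI estimator {estimator!r}")
    dx = _anchor_displacements(trajectory, nodes, align_idx)[:, :, 0]
    n = dx.shape[1]
    mi = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        pxy, _, _ = np.histogram2d(dx[:, i], dx[:, j], bins=bins)
        pxy = pxy / pxy.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nzero = pxy > 0
        mi[i, j] = mi[j, i] = float(
            (pxy[nzero] * np.log(pxy[nzero] / (px @ py)[nzero])).sum())
    return mi


# ---------------------------------------------------------------- allostery

@dataclass
class AllosteryResult:
    efficiency: float
    betweenness: np.ndarray        # per node, total current through it
    nodes: list[Node]
    source_idx: np.ndarray
    sink_idx: np.ndarray
    connected: bool

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": [n.node_id for n in self.nodes],
            "kind": [n.kind for n in self.nodes],
            "segment": [n.segment for n in self.nodes],
            "betweenness": self.betweenness,
        })


def allosteric_efficiency(mi: np.ndarray, contacts: np.ndarray,
                          nodes: list[Node], source_idx, sink_idx
                          ) -> AllosteryResult:
    """Effective conductance between a source and a sink node set on the
    g = MI × contact resistor network, plus per-node current betweenness.

    Source and sink sets are short-circuited into super-nodes; unit current
    is injected and the node potentials solved from the graph Laplacian.
    Disconnected source/sink gives efficiency 0 and zero betweenness.
    """
    source_idx = np.asarray(source_idx, dtype=int)
    sink_idx = np.asarray(sink_idx, dtype=int)
    if len(source_idx) == 0 or len(sink_idx) == 0:
        raise ValueError("source and sink sets must be non-empty")
    if set(source_idx) & set(sink_idx):
        raise ValueError("source and sink sets must be disjoint")
    n = mi.shape[0]
    g = np.asarray(mi, float) * np.asarray(contacts, float)
    g = 0.5 * (g + g.T)
    np.fill_diagonal(g, 0.0)

    # connectivity check on the positive-conductance graph
    gx = nx.from_numpy_array(g * (g > 0))
    src0, snk0 = int(source_idx[0]), int(sink_idx[0])
    reach = nx.node_connected_component(gx, src0) if n else set()
    if not (set(sink_idx) & reach):
        return AllosteryResult(0.0, np.zeros(n), nodes, source_idx, sink_idx, False)

    # merge: map every source node to super-node S, every sink node to T
    group = np.arange(n)
    group[source_idx] = source_idx[0]
    group[sink_idx] = sink_idx[0]
    labels = np.unique(group)
    pos = {lab: k for k, lab in enumerate(labels)}
    m = len(labels)
    gm = np.zeros((m, m))
    for i in range(n):
        for j in range(i + 1, n):
            if g[i, j] > 0:
                a, b = pos[group[i]], pos[group[j]]
                if a != b:
                    gm[a, b] += g[i, j]
                    gm[b, a] += g[i, j]
    lap = np.diag(gm.sum(axis=1)) - gm
    s, t = pos[source_idx[0]], pos[sink_idx[0]]
    # solve only inside the source's connected component (isolated nodes and
    # detached islands carry no current and would make the system singular)
    comp = nx.node_connected_component(nx.from_numpy_array(gm * (gm > 0)), s)
    keep = [k for k in sorted(comp) if k != t]     # ground the sink
    b = np.zeros(m)
    b[s] = 1.0
    x_red = np.linalg.solve(lap[np.ix_(keep, keep)], b[keep])
    x = np.zeros(m)
    x[keep] = x_red
    efficiency = float(1.0 / x[s]) if x[s] > 0 else 0.0

    # potentials per original node; edge currents; node through-currents
    phi = x[[pos[group[i]] for i in range(n)]]
    currents = g * (phi[:, None] - phi[None, :])
    through = 0.5 * np.abs(currents).sum(axis=1)
    # source/sink members also carry their injected share
    for i in source_idx:
        through[i] = 0.5 * (np.abs(currents[i]).sum() + abs(currents[i].sum()))
    for i in sink_idx:
        through[i] = 0.5 * (np.abs(currents[i]).sum() + abs(currents[i].sum()))
    return AllosteryResult(efficiency, through, nodes, source_idx, sink_idx, True)


def flow_decomposition(result: AllosteryResult) -> dict[str, pd.DataFrame]:
    """Betweenness summed by component class (protein/lipid/ligand/ion) and
    by segment (TMHs, NBDs, CHs, L0, ...); nodes without a segment tag land
    in "unassigned"."""
    bet = result.betweenness
    by_class: dict[str, float] = {}
    by_segment: dict[str, float] = {}
    for node, v in zip(result.nodes, bet):
        cls = KIND_CLASS.get(node.kind, "other")
        by_class[cls] = by_class.get(cls, 0.0) + float(v)
        seg = node.segment or "unassigned"
        by_segment[seg] = by_segment.get(seg, 0.0) + float(v)
    cls_df = pd.DataFrame(sorted(by_class.items()), columns=["class", "betweenness"])
    seg_df = pd.DataFrame(sorted(by_segment.items()), columns=["segment", "betweenness"])
    return {"by_class": cls_df, "by_segment": seg_df}
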