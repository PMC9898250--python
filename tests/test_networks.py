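import math

import numpy as np
import pytest

from abctraj.networks import (Node, allosteric_efficiency, build_nodes,
                              communities, contact_map, dccm,
                              flow_decomposition, mutual_information)
from abctraj.synthetic import (MembraneSpec, make_ligand, make_membrane,
                               make_trajectory, make_transporter,
                               merge_systems, TransporterSpec)
from abctraj.topology import Trajectory

import oracles
from conftest import point_topology


def fake_nodes(n, kinds=None, segments=None):
    kinds = kinds or ["residue"] * n
    segments = segments or ["SEG"] * n
    return [Node(i, kinds[i], i + 1, segments[i], np.array([i]), i)
            for i in range(n)]


def correlated_point_trajectory(rho, n_frames=20000, seed=0, n_atoms=6):
    topo, frame = point_topology([(3.0 * i, 0.0, 0.0) for i in range(n_atoms)])
    traj = make_trajectory([(frame, 1.0)], n_frames, noise_sigma=0.5,
                           correlated_modes=[([0], [1], rho)] if rho else None,
                           seed=seed, box=(100, 100, 100))
    return topo, traj


# -------------------------------------------------------------------- DCCM

def test_dccm_diagonal_bounds_and_symmetry():
    topo, traj = correlated_point_trajectory(0.5, n_frames=2000)
    c = dccm(traj, build_nodes(topo))
    np.testing.assert_allclose(np.diag(c), 1.0)
    np.testing.assert_allclose(c, c.T, atol=1e-12)
    assert (np.abs(c) <= 1.0 + 1e-12).all()


def test_dccm_recovers_planted_correlation():
    topo, traj = correlated_point_trajectory(0.9)
    c = dccm(traj, build_nodes(topo))
    assert c[0, 1] == pytest.approx(0.9, abs=0.02)


def test_dccm_antiphase_pair_reaches_minus_one():
    topo, traj = correlated_point_trajectory(-1.0, n_frames=2000)
    c = dccm(traj, build_nodes(topo))
    assert c[0, 1] == pytest.approx(-1.0, abs=1e-9)


def test_dccm_zero_variance_node_zeroed():
    topo, frame = point_topology([(0, 0, 0), (5, 0, 0)])
    coords = np.repeat(frame[None], 50, axis=0)
    coords[:, 0, 0] += np.random.default_rng(0).normal(0, 1, 50)  # node 1 frozen
    c = dccm(Trajectory(coords, (50, 50, 50)), build_nodes(topo))
    assert c[0, 1] == 0.0 and c[1, 1] == 1.0


# ------------------------------------------------------------- contact map

def test_contact_map_restrictions_and_fractions():
    positions = [(0, 0, 0), (2, 0, 0), (30, 0, 0), (32, 0, 0), (60, 0, 0)]
    topo, frame = point_topology(positions)
    traj = Trajectory(np.repeat(frame[None], 4, axis=0), (200, 200, 200))
    nodes = build_nodes(topo)
    frac = contact_map(traj, topo, nodes, cutoff=4.5)
    assert frac[0, 1] == 0.0            # sequence neighbours excluded
    assert frac[2, 3] == 0.0            # also neighbours (resid 3, 4)
    frac_far = contact_map(traj, topo, nodes, cutoff=4.5, restrictions=False)
    assert frac_far[0, 1] == 1.0        # within cutoff every frame
    assert frac_far[0, 4] == 0.0        # beyond cutoff always


def test_contact_fraction_counts_frames():
    topo, frame = point_topology([(0, 0, 0), (10, 0, 0), (3, 0, 0)])
    frames = np.repeat(frame[None], 4, axis=0)
    frames[2:, 2, 0] = 50.0     # third residue drifts away for half the frames
    traj = Trajectory(frames, (200, 200, 200))
    frac = contact_map(traj, topo, build_nodes(topo), cutoff=4.5)
    assert frac[0, 2] == pytest.approx(0.5)


# -------------------------------------------------------------- communities

def test_two_cliques_with_bridge_split_into_two_communities():
    n = 10
    corr = np.full((n, n), 0.01)
    contacts = np.zeros((n, n))
    for block in (range(5), range(5, 10)):
        for i in block:
            for j in block:
                if i != j:
                    corr[i, j] = 0.8
                    contacts[i, j] = 1.0
    contacts[4, 5] = contacts[5, 4] = 1.0
    corr[4, 5] = corr[5, 4] = 0.8
    np.fill_diagonal(corr, 1.0)
    part, q = communities(corr, contacts)
    assert len(part) == 2
    assert {frozenset(p) for p in part} == {frozenset(range(5)), frozenset(range(5, 10))}
    # brute-force check that this bipartition is modularity-optimal
    adj = np.where(contacts >= 0.75, np.abs(corr), 0.0)
    np.fill_diagonal(adj, 0.0)
    q_best, labels = oracles.best_bipartition_modularity(adj)
    assert q == pytest.approx(q_best, abs=1e-9)
    assert len({labels[i] for i in range(5)}) == 1


def test_fully_connected_uniform_graph_is_one_community():
    n = 6
    corr = np.full((n, n), 0.9)
    np.fill_diagonal(corr, 1.0)
    contacts = 1.0 - np.eye(n)
    part, q = communities(corr, contacts)
    assert len(part) == 1
    assert q == pytest.approx(0.0, abs=1e-12)


def test_empty_graph_gives_empty_partition():
    part, q = communities(np.eye(4), np.zeros((4, 4)))
    assert part == [] and q == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_planted_two_block_graph_recovered(seed):
    rng = np.random.default_rng(seed)
    n = 12
    corr = np.full((n, n), 0.05)
    contacts = np.zeros((n, n))
    blocks = (list(range(6)), list(range(6, 12)))
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    contacts[i, j] = 1.0
                    corr[i, j] = rng.uniform(0.6, 0.9)
    # one weak inter-block edge (~3% of the 30 intra edges)
    i, j = rng.choice(blocks[0]), rng.choice(blocks[1])
    contacts[i, j] = contacts[j, i] = 1.0
    corr[i, j] = corr[j, i] = 0.3
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    part, _q = communities(corr, contacts)
    assert {frozenset(p) for p in part} == {frozenset(blocks[0]), frozenset(blocks[1])}


# ------------------------------------------------------- mutual information

def test_mi_of_independent_nodes_is_near_zero():
    topo, traj = correlated_point_trajectory(0.0)
    mi = mutual_information(traj, build_nodes(topo))
    off = mi[~np.eye(mi.shape[0], dtype=bool)]
    assert off.max() < 0.005


def test_mi_matches_gaussian_closed_form():
    topo, traj = correlated_point_trajectory(0.9)
    mi = mutual_information(traj, build_nodes(topo))
    expected = -0.5 * math.log(1 - 0.9 ** 2)
    assert mi[0, 1] == pytest.approx(expected, rel=0.05)
    np.testing.assert_array_equal(mi, mi.T)
    assert (mi >= 0).all()


def test_histogram_estimator_agrees_on_strong_correlation():
    topo, traj = correlated_point_trajectory(0.9)
    mi = mutual_information(traj, build_nodes(topo), estimator="histogram")
    expected = -0.5 * math.log(1 - 0.9 ** 2)
    assert mi[0, 1] == pytest.approx(expected, rel=0.25)


# ---------------------------------------------------------------- allostery

def test_single_edge_efficiency_is_its_conductance():
    mi = np.array([[0.0, 0.8], [0.8, 0.0]])
    contacts = np.array([[0.0, 0.9], [0.9, 0.0]])
    res = allosteric_efficiency(mi, contacts, fake_nodes(2), [0], [1])
    assert res.efficiency == pytest.approx(0.8 * 0.9, abs=1e-12)


def test_series_and_parallel_resistor_identities():
    g1, g2 = 0.6, 0.3
    mi = np.zeros((3, 3))
    mi[0, 1] = mi[1, 0] = g1
    mi[1, 2] = mi[2, 1] = g2
    contacts = (mi > 0).astype(float)
    res = allosteric_efficiency(mi, contacts, fake_nodes(3), [0], [2])
    assert res.efficiency == pytest.approx(g1 * g2 / (g1 + g2), abs=1e-12)
    mi2 = np.zeros((2, 2))
    mi2[0, 1] = mi2[1, 0] = g1 + g2
    res2 = allosteric_efficiency(mi2, (mi2 > 0).astype(float), fake_nodes(2),
                                 [0], [1])
    assert res2.efficiency == pytest.approx(g1 + g2, abs=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_efficiency_matches_kirchhoff_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 7)
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.7:
                g[i, j] = g[j, i] = rng.uniform(0.1, 2.0)
    for k in range(n - 1):          # spanning path keeps the graph connected
        if g[k, k + 1] == 0:
            g[k, k + 1] = g[k + 1, k] = rng.uniform(0.1, 2.0)
    res = allosteric_efficiency(g, np.ones((n, n)) - np.eye(n), fake_nodes(n),
                                [0], [n - 1])
    expected = oracles.effective_conductance_kirchhoff(g, 0, n - 1)
    assert res.efficiency == pytest.approx(expected, abs=1e-9)


def test_efficiency_monotone_in_edge_conductance():
    rng = np.random.default_rng(10)
    n = 5
    g = rng.uniform(0.1, 1.0, size=(n, n))
    g = 0.5 * (g + g.T)
    np.fill_diagonal(g, 0.0)
    ones = np.ones((n, n)) - np.eye(n)
    base = allosteric_efficiency(g, ones, fake_nodes(n), [0], [4]).efficiency
    for i, j in ((1, 2), (0, 3), (2, 4)):
        g2 = g.copy()
        g2[i, j] = g2[j, i] = g[i, j] + 0.5
        bumped = allosteric_efficiency(g2, ones, fake_nodes(n), [0], [4]).efficiency
        assert bumped >= base - 1e-12


def test_disconnected_source_sink_flagged_zero():
    mi = np.zeros((4, 4))
    mi[0, 1] = mi[1, 0] = 0.5
    mi[2, 3] = mi[3, 2] = 0.5
    res = allosteric_efficiency(mi, (mi > 0).astype(float), fake_nodes(4),
                                [0], [3])
    assert res.efficiency == 0.0 and not res.connected
    np.testing.assert_array_equal(res.betweenness, 0.0)


def test_removing_lipid_bridge_strictly_decreases_efficiency():
    # source 0 - sink 2 weakly coupled directly, strongly through lipid node 1
    kinds = ["residue", "sterol", "residue"]
    nodes = fake_nodes(3, kinds=kinds, segments=["NBS1", "preTMH7", "POCKET"])
    g = np.zeros((3, 3))
    g[0, 2] = g[2, 0] = 0.05
    g[0, 1] = g[1, 0] = 1.0
    g[1, 2] = g[2, 1] = 1.0
    ones = np.ones((3, 3)) - np.eye(3)
    with_lipid = allosteric_efficiency(g, ones, nodes, [0], [2])
    g_nolipid = g.copy()
    g_nolipid[1, :] = g_nolipid[:, 1] = 0.0
    without = allosteric_efficiency(g_nolipid, ones, nodes, [0], [2])
    assert with_lipid.efficiency > without.efficiency
    # the bridging sterol carries the top betweenness and the lipid class share
    decomp = flow_decomposition(with_lipid)
    assert with_lipid.betweenness[1] == max(with_lipid.betweenness[1:2]) \
        and np.argmax(with_lipid.betweenness) in (0, 1, 2)
    by_class = decomp["by_class"].set_index("class")["betweenness"]
    assert by_class["lipid"] > 0
    assert by_class.sum() == pytest.approx(with_lipid.betweenness.sum(), abs=1e-12)


def test_flow_decomposition_conserves_totals_and_buckets_segments():
    kinds = ["residue", "residue", "atp_part", "sterol"]
    segs = ["TMH4", "NBD2", "ATP", "preTMH1"]
    nodes = fake_nodes(4, kinds=kinds, segments=segs)
    rng = np.random.default_rng(1)
    g = rng.uniform(0.2, 1.0, size=(4, 4))
    g = 0.5 * (g + g.T)
    np.fill_diagonal(g, 0.0)
    res = allosteric_efficiency(g, np.ones((4, 4)) - np.eye(4), nodes, [0], [1])
    decomp = flow_decomposition(res)
    assert decomp["by_class"].betweenness.sum() == pytest.approx(
        res.betweenness.sum(), abs=1e-12)
    assert set(decomp["by_segment"].segment) == set(segs)
    no_lipid = decomp["by_class"].set_index("class")
    assert {"protein", "ligand", "lipid"} <= set(no_lipid.index)


# ------------------------------------------------ node model construction

def test_node_model_counts_per_molecule_type():
    t_topo, t_frame, _scheme = make_transporter(TransporterSpec())
    spec = MembraneSpec(fractions={"pc": 0.5, "sterol": 0.5}, n_per_leaflet=4,
                        tail_length=3, box=(45.0, 45.0, 80.0))
    m_topo, m_frame = make_membrane(spec, seed=0)
    atp = make_ligand("atp_like")
    merged, _frame = merge_systems((t_topo, t_frame), (m_topo, m_frame),
                                   (atp.topology, atp.coords))
    nodes = build_nodes(merged)
    by_kind = {}
    for n in nodes:
        by_kind[n.kind] = by_kind.get(n.kind, 0) + 1
    assert by_kind["residue"] == t_topo.n_residues
    assert by_kind["lipid_head"] == 4   # one per phospholipid
    assert by_kind["lipid_tail"] == 8   # two per phospholipid
    assert by_kind["sterol"] == 4
    assert by_kind["atp_part"] == 3
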