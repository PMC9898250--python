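import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abctraj import descriptors as desc
from abctraj.synthetic import TransporterSpec, make_transporter, make_trajectory
from abctraj.topology import Trajectory

import oracles
from conftest import point_scheme_system, point_topology


# -------------------------------------------------------------------- COM

def test_center_of_mass_hand_arithmetic():
    topo, frame = point_topology([(0, 0, 0), (2, 0, 0)], masses=[1.0, 3.0])
    unweighted = desc.center_of_mass(frame, topo, [0, 1], mass_weighted=False)
    weighted = desc.center_of_mass(frame, topo, [0, 1], mass_weighted=True)
    np.testing.assert_allclose(unweighted, [1.0, 0.0, 0.0])
    np.testing.assert_allclose(weighted, [1.5, 0.0, 0.0])
    single = desc.center_of_mass(frame, topo, [1])
    np.testing.assert_allclose(single, [2.0, 0.0, 0.0])


def test_center_of_mass_empty_set_rejected(transporter):
    _s, topo, frame, _ = transporter
    with pytest.raises(ValueError, match="empty"):
        desc.center_of_mass(frame, topo, [])


# ------------------------------------------------------- hand-oracle angles

def test_ic_angle_hand_geometry():
    """IC half COMs at (±10, 0, −20) seen from the EC COM at (0, 0, 20)."""
    topo, frame, scheme = point_scheme_system(
        ic_a=(-10, 0, -20), ic_b=(10, 0, -20), ec_all=(0, 0, 20))
    expected = math.degrees(2 * math.atan(10 / 40))
    assert desc.ic_angle(frame, topo, scheme) == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(28.0725, abs=1e-3)


def test_ec_angle_and_distance_hand_geometry():
    topo, frame, scheme = point_scheme_system(
        ic_a=(0, 0, -20), ic_b=(0, 1, -20),
        ec_all={"A": (-5, 0, 20), "B": (5, 0, 20)},
        nbd1=(0, 0, -20), nbd2=(0, 0, -20))
    ang, dist = desc.ec_angle_and_distance(frame, topo, scheme)
    assert ang == pytest.approx(math.degrees(2 * math.atan(5 / 40)), abs=1e-9)
    assert dist == pytest.approx(10.0, abs=1e-9)


@pytest.mark.parametrize("p3,expected", [
    ((5, 1, 0), 0.0),      # cis-planar
    ((5, -1, 0), 180.0),   # trans-planar
    ((5, 0, 1), 90.0),     # right-handed quarter turn
])
def test_nbd_twist_dihedral_sign_convention(p3, expected):
    topo, frame, scheme = point_scheme_system(
        ic_a=(0, 0, -20), ic_b=(1, 0, -20), ec_all=(0, 0, 20),
        nbd1=(0, 0, 0), nbd2=(5, 0, 0), nbd1_lobe=(0, 1, 0), nbd2_lobe=p3)
    dist, twist = desc.nbd_distance_and_twist(frame, topo, scheme)
    assert dist == pytest.approx(5.0, abs=1e-12)
    assert abs(twist) == pytest.approx(abs(expected), abs=1e-9)
    if expected not in (0.0, 180.0):
        assert twist == pytest.approx(expected, abs=1e-9)


def test_gs_distance_uses_minimal_image(transporter):
    _s, topo, frame, scheme = transporter
    shifted = frame.copy()
    ra = scheme.group("gs_nbs1")[0]
    ia = topo.ca_index(ra)
    box = np.array([120.0, 120.0, 180.0])
    shifted[ia] += box            # same physical position, next periodic image
    d_ref = desc.nbs_gs_distances(frame, topo, scheme, box=box)
    d_img = desc.nbs_gs_distances(shifted, topo, scheme, box=box)
    assert d_img[0] == pytest.approx(d_ref[0], abs=1e-9)


# ---------------------------------------------- oracle & invariance sweeps

def test_descriptors_match_naive_oracles_on_random_frames(transporter):
    _s, topo, frame, scheme = transporter
    rng = np.random.default_rng(7)
    box = np.array([120.0, 120.0, 180.0])
    for _ in range(25):
        f = frame + rng.normal(0, 1.0, size=frame.shape)
        assert desc.ic_angle(f, topo, scheme) == pytest.approx(
            oracles.ic_angle_naive(f, topo, scheme), abs=1e-9)
        ec, ecd = desc.ec_angle_and_distance(f, topo, scheme)
        ec_o, ecd_o = oracles.ec_angle_and_distance_naive(f, topo, scheme)
        assert ec == pytest.approx(ec_o, abs=1e-9)
        assert ecd == pytest.approx(ecd_o, abs=1e-9)
        d, tw = desc.nbd_distance_and_twist(f, topo, scheme)
        d_o, tw_o = oracles.nbd_distance_and_twist_naive(f, topo, scheme)
        assert d == pytest.approx(d_o, abs=1e-9)
        assert tw == pytest.approx(tw_o, abs=1e-9)
        g = desc.nbs_gs_distances(f, topo, scheme, box=box)
        g_o = oracles.gs_distances_naive(f, topo, scheme, box)
        assert g[0] == pytest.approx(g_o[0], abs=1e-9)
        assert g[1] == pytest.approx(g_o[1], abs=1e-9)


def test_descriptors_invariant_under_rigid_motion(transporter):
    _s, topo, frame, scheme = transporter
    ref = desc.descriptor_vector(frame, topo, scheme)
    rng = np.random.default_rng(13)
    for _ in range(20):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, size=3)
        moved = frame @ rot.T + t
        vec = desc.descriptor_vector(moved, topo, scheme)
        for key in ref:
            assert vec[key] == pytest.approx(ref[key], abs=1e-9), key


# ------------------------------------------------------------- helix tilt

def test_helix_tilt_reference_cases(transporter):
    from abctraj.synthetic import make_helix
    for axis, expected in (((0, 0, 1), 0.0), ((1, 0, 0), 90.0),
                           ((1, 0, 1), 45.0)):
        coords, names = make_helix(37, axis=axis)
        topo, frame = point_topology(list(coords), names=list(names))
        ca_res = [i + 1 for i, nm in enumerate(names) if nm == "CA"]
        tilt = desc.helix_tilt(frame, topo, ca_res)
        assert tilt == pytest.approx(expected, abs=0.5)


# ------------------------------------------------------- superposition/RMSD

def test_superpose_recovers_rotated_copy(transporter):
    _s, topo, frame, _ = transporter
    rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
    moved = frame @ rot.T + np.array([5.0, -3.0, 8.0])
    r, t, rmsd = desc.superpose_and_rmsd(moved, frame)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


def test_rmsd_of_single_atom_shift():
    rng = np.random.default_rng(0)
    ref = rng.uniform(-10, 10, size=(100, 3))
    # displace one atom along a direction that the fit cannot absorb
    mob = ref.copy()
    mob[0] += np.array([0.0, 0.0, 1.0])
    _r, _t, rmsd = desc.superpose_and_rmsd(mob, ref)
    assert rmsd == pytest.approx(0.1, abs=5e-3)   # sqrt(1/100) minus fit slack
    _r2, _t2, rmsd2 = desc.superpose_and_rmsd(ref, mob)
    assert rmsd2 == pytest.approx(rmsd, abs=1e-9)


# -------------------------------------------------------------------- RMSF

def test_rmsf_static_trajectory_is_zero(transporter):
    _s, topo, frame, _ = transporter
    traj = Trajectory(np.repeat(frame[None], 5, axis=0), (120, 120, 180))
    vals = desc.rmsf(traj, np.arange(topo.n_atoms))
    np.testing.assert_allclose(vals, 0.0, atol=1e-9)


def test_rmsf_gaussian_jitter_matches_sigma_sqrt3():
    rng = np.random.default_rng(5)
    n_atoms = 300   # large rigid body so the 6 fitted dof stay negligible
    base = rng.uniform(-20, 20, size=(n_atoms, 3))
    sigma = 0.5
    coords = base[None] + rng.normal(0, sigma, size=(2000, n_atoms, 3))
    traj = Trajectory(coords, (120, 120, 180))
    vals = desc.rmsf(traj, np.arange(n_atoms))
    assert vals.mean() == pytest.approx(sigma * math.sqrt(3), rel=0.02)


def test_rmsf_alignment_removes_rigid_tumble():
    rng = np.random.default_rng(8)
    base = rng.uniform(-20, 20, size=(30, 3))
    jitter = rng.normal(0, 0.5, size=(800, 30, 3))
    plain = base[None] + jitter
    tumbled = np.empty_like(plain)
    for f in range(plain.shape[0]):
        rot = Rotation.random(random_state=rng).as_matrix()
        tumbled[f] = plain[f] @ rot.T + rng.uniform(-5, 5, 3)
    v1 = desc.rmsf(Trajectory(plain, (120, 120, 180)), np.arange(30))
    v2 = desc.rmsf(Trajectory(tumbled, (120, 120, 180)), np.arange(30))
    assert np.abs(v1.mean() - v2.mean()) / v1.mean() < 0.01


def test_rmsf_single_frame_rejected(transporter):
    _s, topo, frame, _ = transporter
    traj = Trajectory(frame[None], (120, 120, 180))
    with pytest.raises(ValueError, match="frames"):
        desc.rmsf(traj, np.arange(topo.n_atoms))


# --------------------------------------------------------------------- PCA

def test_pca_single_moving_domain_assigns_variance_to_nbd2(transporter):
    _s, topo, frame, scheme = transporter
    nbd2_atoms = topo.atoms_of_residues(scheme.group("nbd2"))
    rng = np.random.default_rng(2)
    amp = rng.normal(0, 2.0, size=400)
    coords = np.repeat(frame[None], 400, axis=0)
    coords[:, nbd2_atoms, 0] += amp[:, None]
    result = desc.pca_abc_core(Trajectory(coords, (120, 120, 180)), topo, scheme,
                               n_components=3)
    assert result.explained_variance_ratio[0] > 0.95
    # superposition spreads some counter-motion over the other domains,
    # but NBD2 must dominate the first component
    row = result.domain_contributions.loc["PC1"]
    assert row["NBD2"] > 0.8 and row.idxmax() == "NBD2"
    assert row.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_two_orthogonal_equal_modes_split_variance(transporter):
    _s, topo, frame, scheme = transporter
    nbd1_atoms = topo.atoms_of_residues(scheme.group("nbd1"))
    nbd2_atoms = topo.atoms_of_residues(scheme.group("nbd2"))
    rng = np.random.default_rng(3)
    n = 2000
    coords = np.repeat(frame[None], n, axis=0)
    coords[:, nbd1_atoms, 0] += rng.normal(0, 2.0, size=n)[:, None]
    coords[:, nbd2_atoms, 1] += rng.normal(0, 2.0, size=n)[:, None]
    result = desc.pca_abc_core(Trajectory(coords, (120, 120, 180)), topo, scheme, 2)
    r = result.explained_variance_ratio
    assert r[0] == pytest.approx(r[1], rel=0.2)
    assert r[0] + r[1] > 0.95


# --------------------------------------------------------- reference space

def test_reference_space_projection_recovers_build_targets():
    rows = []
    for label, ic, d in (("A", 30.0, 40.0), ("B", 50.0, 60.0)):
        topo, frame, scheme = make_transporter(
            TransporterSpec(ic_angle=ic, nbd_distance=d))
        rows.append((label, "IF open", topo, frame, scheme))
    df = desc.project_reference_space(rows)
    assert df.loc[df.label == "A", "ic_angle"].iloc[0] == pytest.approx(30.0, abs=1e-6)
    assert df.loc[df.label == "B", "nbd_distance"].iloc[0] == pytest.approx(60.0, abs=1e-6)


def test_reference_space_trajectory_cloud_centres_on_targets(transporter):
    spec, topo, frame, scheme = transporter
    traj = make_trajectory([(frame, 1.0)], 400, noise_sigma=0.5, seed=4)
    df = desc.project_reference_space([], trajectory=traj, topology=topo,
                                      scheme=scheme)
    assert len(df) == 400
    assert df.ic_angle.mean() == pytest.approx(spec.ic_angle, abs=0.3)
    assert df.nbd_distance.mean() == pytest.approx(spec.nbd_distance, abs=0.3)


def test_reference_space_empty_input_gives_empty_table():
    df = desc.project_reference_space([])
    assert df.empty
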