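import numpy as np
import pytest

from abctraj.synthetic import TransporterSpec, make_transporter
from abctraj.topology import Segment, SelectionScheme, Topology


@pytest.fixture(scope="session")
def transporter():
    """Noise-free pseudo-transporter at the canonical targets
    (IC 30°, EC 10°, d_NBD 40 Å, twist 60°)."""
    spec = TransporterSpec(ic_angle=30.0, ec_angle=10.0, nbd_distance=40.0,
                           nbd_twist=60.0, seed=0)
    topo, frame, scheme = make_transporter(spec)
    return spec, topo, frame, scheme


def point_topology(positions, names=None, resnames=None, masses=None, vdw=1.7):
    """One single-atom residue per position — minimal systems for geometry
    tests."""
    n = len(positions)
    names = names or ["CA"] * n
    resnames = resnames or ["ALA"] * n
    masses = masses if masses is not None else [12.0] * n
    topo = Topology(
        name=np.array(names, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        mass=np.asarray(masses, float),
        charge=np.zeros(n),
        vdw=np.full(n, float(vdw)),
        resid=np.arange(1, n + 1),
        resname=np.array(resnames, dtype=object),
        segments=[Segment("PT", "unassigned", np.arange(1, n + 1))],
    )
    topo.validate()
    return topo, np.asarray(positions, dtype=float)


def point_scheme_system(ic_a, ic_b, ec_all, nbd1=None, nbd2=None,
                        nbd1_lobe=None, nbd2_lobe=None):
    """Topology + scheme where each descriptor group is a set of single-atom
    residues at explicit positions (hand-oracle geometry)."""
    groups: dict[str, list[int]] = {}
    positions: list = []

    def add(group_positions):
        ids = []
        for p in group_positions:
            positions.append(p)
            ids.append(len(positions))
        return ids

    ic_half_a = {1, 2, 3, 6, 10, 11}
    ec_half_a = {1, 2, 9, 10, 11, 12}
    for h in range(1, 13):
        groups[f"tmh{h}_ic"] = add([ic_a if h in ic_half_a else ic_b])
        if isinstance(ec_all, dict):   # distinct EC half positions
            groups[f"tmh{h}_ec"] = add([ec_all["A" if h in ec_half_a else "B"]])
        else:
            groups[f"tmh{h}_ec"] = add([ec_all])
    for key, val in (("nbd1", nbd1), ("nbd2", nbd2),
                     ("nbd1_lobe", nbd1_lobe), ("nbd2_lobe", nbd2_lobe)):
        if val is not None:
            groups[key] = add([val])
    topo, frame = point_topology(positions)
    return topo, frame, SelectionScheme(groups)
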