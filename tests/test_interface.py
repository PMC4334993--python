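import numpy as np
import pytest

from kirdock._chemdata import vdw_radius
from kirdock.dockengine import DockConfig, dock_rigid
from kirdock.errors import AddressingError
from kirdock.fixtures import make_peptide
from kirdock.interface import (
    InterfaceThresholds,
    RingDefinition,
    classify_footprint,
    contact_rings,
    detect_hbonds,
    detect_salt_bridges,
    posed_ligand_atoms,
    residue_sasa,
    sasa,
)
from kirdock.structio import AtomRecord, StructureBundle


def _atom(name, element, coords, resname="ALA", chain="A", seq=1):
    return AtomRecord(serial=1, name=name, element=element,
                      residue_name=resname, chain_id=chain, residue_seq=seq,
                      coords=np.asarray(coords, float))


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_isolated_atom_analytic_sphere():
    atoms = [_atom("C", "C", [0, 0, 0])]
    area = sasa(atoms, probe=1.4, n_points=960)[0]
    expected = 4 * np.pi * (vdw_radius("C") + 1.4) ** 2
    assert area == pytest.approx(expected, rel=0.01)


def test_fully_caged_atom_zero():
    center = [_atom("C", "C", [0, 0, 0])]
    cage = []
    golden = np.pi * (3 - np.sqrt(5))
    for i in range(40):  # tight cage of large neighbors
        z = 1 - 2 * (i + 0.5) / 40
        r = np.sqrt(1 - z * z)
        theta = golden * i
        cage.append(_atom("S", "S", 2.0 * np.array(
            [r * np.cos(theta), r * np.sin(theta), z]), seq=2 + i))
    areas = sasa(center + cage, probe=1.4, n_points=960)
    assert areas[0] == 0.0


def test_two_overlapping_spheres_vs_monte_carlo():
    atoms = [_atom("C", "C", [0, 0, 0]), _atom("O", "O", [2.0, 0, 0], seq=2)]
    areas = sasa(atoms, probe=1.4, n_points=1920)

    rng = np.random.default_rng(42)
    for index, other in ((0, 1), (1, 0)):
        radius = vdw_radius(atoms[index].element) + 1.4
        other_radius = vdw_radius(atoms[other].element) + 1.4
        points = rng.normal(size=(10 ** 6, 3))
        points /= np.linalg.norm(points, axis=1)[:, None]
        points = atoms[index].coords + radius * points
        exposed = np.sum(
            np.linalg.norm(points - atoms[other].coords, axis=1) > other_radius)
        oracle = 4 * np.pi * radius ** 2 * exposed / 10 ** 6
        assert areas[index] == pytest.approx(oracle, rel=0.02)


def test_doubling_points_small_change():
    # a lone atom's area is sampling-exact: doubling changes nothing
    single = [_atom("C", "C", [0, 0, 0])]
    assert sasa(single, n_points=960)[0] == \
        pytest.approx(sasa(single, n_points=1920)[0], rel=1e-12)
    # occluded-pair areas converge ~O(1/n)
    atoms = [_atom("C", "C", [0, 0, 0]), _atom("N", "N", [1.8, 0.4, 0], seq=2)]
    coarse = sasa(atoms, n_points=960)
    fine = sasa(atoms, n_points=1920)
    for a, b in zip(coarse, fine):
        assert abs(a - b) / max(b, 1e-9) < 0.02


def test_complex_sasa_not_larger_than_parts(toy_channel, toy_peptide):
    rec_atoms = toy_channel.structure.model(0)
    lig_atoms = toy_peptide.model(0)
    combined = sasa(list(rec_atoms) + list(lig_atoms), n_points=240)
    separate = np.concatenate([sasa(rec_atoms, n_points=240),
                               sasa(lig_atoms, n_points=240)])
    assert combined.sum() <= separate.sum() + 1e-6


# ---------------------------------------------------------------------------
# footprint
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def docked(toy_channel, toy_peptide):
    config = DockConfig(rotation_step=90.0, top_n=10, contact_pool=20)
    poselist = dock_rigid(toy_channel.structure, toy_peptide, config)
    atoms = posed_ligand_atoms(toy_peptide, poselist.poses[0],
                               centroid=poselist.ligand_centroid)
    return toy_channel, atoms


def test_far_ligand_no_interfacing(toy_channel, toy_peptide):
    lig = [a.moved(a.coords + np.array([100.0, 0, 0]))
           for a in toy_peptide.model(0)]
    rows = classify_footprint(toy_channel.structure, lig,
                              InterfaceThresholds(sasa_points=240))
    assert all(r.category in ("inaccessible", "solvent-accessible")
               for r in rows)
    assert all(r.buried_area == 0.0 for r in rows)


def test_docked_peptide_buries_pocket_residues(docked):
    toy_channel, lig_atoms = docked
    rows = classify_footprint(toy_channel.structure, lig_atoms,
                              InterfaceThresholds(sasa_points=240))
    interfacing = [r for r in rows if r.category in ("interfacing",
                                                     "bonded-link")]
    assert interfacing
    assert all(r.buried_area > 1.0 for r in interfacing)


def test_footprint_matches_direct_delta_sasa(docked):
    toy_channel, lig_atoms = docked
    thresholds = InterfaceThresholds(sasa_points=240)
    rows = classify_footprint(toy_channel.structure, lig_atoms, thresholds)
    rec_atoms = toy_channel.structure.model(0)
    free = residue_sasa(rec_atoms, sasa(rec_atoms, n_points=240))
    complex_areas = sasa(list(rec_atoms) + list(lig_atoms), n_points=240)
    bound = residue_sasa(rec_atoms, complex_areas[:len(rec_atoms)])
    for row in rows:
        key = (row.chain, row.residue_seq, "")
        delta = max(0.0, free[key] - bound[key])
        assert row.buried_area == pytest.approx(delta, abs=0.015)
        assert (delta > thresholds.interfacing_delta_sasa) == \
            (row.category in ("interfacing", "bonded-link"))


def test_footprint_categories_are_the_four_classes(docked):
    toy_channel, lig_atoms = docked
    rows = classify_footprint(toy_channel.structure, lig_atoms,
                              InterfaceThresholds(sasa_points=240))
    allowed = {"inaccessible", "solvent-accessible", "interfacing",
               "bonded-link"}
    assert {r.category for r in rows} <= allowed


# ---------------------------------------------------------------------------
# hydrogen bonds / salt bridges
# ---------------------------------------------------------------------------

def _nh_donor_residue(offset=np.zeros(3)):
    """Backbone N-H donor with its CA neighbor defining the H direction."""
    return [
        _atom("N", "N", np.array([0.0, 0, 0]) + offset, "GLY", "A", 1),
        _atom("CA", "C", np.array([-1.45, 0, 0]) + offset, "GLY", "A", 1),
    ]


def _carbonyl_acceptor(x, chain="B"):
    return [
        _atom("C", "C", [x + 1.23, 0, 0], "GLY", chain, 1),
        _atom("O", "O", [x, 0, 0], "GLY", chain, 1),
    ]


def test_ideal_hbond_detected():
    donor = _nh_donor_residue()
    acceptor = _carbonyl_acceptor(2.9)     # N...O = 2.9 A, angle 180
    records = detect_hbonds(donor, acceptor)
    assert len(records) == 1
    assert records[0].kind == "hbond"
    assert records[0].distance == pytest.approx(2.9)
    assert records[0].angle == pytest.approx(180.0, abs=1.0)


def test_distant_pair_not_detected():
    assert detect_hbonds(_nh_donor_residue(), _carbonyl_acceptor(5.0)) == []


def test_wrong_angle_not_detected():
    # acceptor behind the donor, opposite the idealized hydrogen
    donor = _nh_donor_residue()
    acceptor = [
        _atom("C", "C", [-4.3, 0, 1.0], "GLY", "B", 1),
        _atom("O", "O", [-3.1, 0, 0.4], "GLY", "B", 1),
    ]
    assert detect_hbonds(donor, acceptor) == []


def test_hbond_count_matches_independent_criteria(docked):
    toy_channel, lig_atoms = docked
    rec_atoms = toy_channel.structure.model(0)
    records = detect_hbonds(rec_atoms, lig_atoms)

    # independent check: every record satisfies the declared criteria
    for r in records:
        assert r.distance <= 3.5
        assert r.angle >= 120.0
        assert r.receptor_residue[0] != r.ligand_residue[0]


def test_salt_bridge_detected():
    lys = [
        _atom("CE", "C", [-1.5, 0, 0], "LYS", "A", 1),
        _atom("NZ", "N", [0.0, 0, 0], "LYS", "A", 1),
    ]
    glu = [
        _atom("CD", "C", [4.2, 0, 0], "GLU", "B", 1),
        _atom("OE1", "O", [3.0, 0, 0], "GLU", "B", 1),
        _atom("OE2", "O", [4.8, 1.0, 0], "GLU", "B", 1),
    ]
    records = detect_salt_bridges(lys, glu)
    assert any(r.distance == pytest.approx(3.0) for r in records)


def test_same_sign_not_salt_bridge():
    a = [_atom("CE", "C", [-1.5, 0, 0], "LYS", "A", 1),
         _atom("NZ", "N", [0, 0, 0], "LYS", "A", 1)]
    b = [_atom("CE", "C", [4.5, 0, 0], "LYS", "B", 1),
         _atom("NZ", "N", [3.0, 0, 0], "LYS", "B", 1)]
    assert detect_salt_bridges(a, b) == []


def test_salt_bridge_cutoff():
    asp = [_atom("CB", "C", [-1.5, 0, 0], "ASP", "A", 1),
           _atom("CG", "C", [-0.8, 0, 0], "ASP", "A", 1),
           _atom("OD1", "O", [0.0, 0, 0], "ASP", "A", 1),
           _atom("OD2", "O", [-1.0, 1.1, 0], "ASP", "A", 1)]
    arg = [_atom("NE", "N", [6.2, 0, 0], "ARG", "B", 1),
           _atom("CZ", "C", [5.6, 0.6, 0], "ARG", "B", 1),
           _atom("NH1", "N", [4.5, 0, 0], "ARG", "B", 1),
           _atom("NH2", "N", [6.0, 1.8, 0], "ARG", "B", 1)]
    assert detect_salt_bridges(asp, arg, d_max=4.0) == []
    assert detect_salt_bridges(asp, arg, d_max=5.0) != []


def test_contact_detection_symmetric(docked):
    toy_channel, lig_atoms = docked
    rec_atoms = toy_channel.structure.model(0)
    ab = detect_hbonds(rec_atoms, lig_atoms)
    ba = detect_hbonds(lig_atoms, rec_atoms)
    assert len(ab) == len(ba)
    assert {(r.receptor_residue, r.ligand_residue, r.distance) for r in ab} \
        == {(r.ligand_residue, r.receptor_residue, r.distance) for r in ba}

    sab = detect_salt_bridges(rec_atoms, lig_atoms)
    sba = detect_salt_bridges(lig_atoms, rec_atoms)
    assert {(r.receptor_residue, r.ligand_residue, r.distance) for r in sab} \
        == {(r.ligand_residue, r.receptor_residue, r.distance) for r in sba}


def test_bonded_link_residues_have_contacts(docked):
    toy_channel, lig_atoms = docked
    thresholds = InterfaceThresholds(sasa_points=240)
    rows = classify_footprint(toy_channel.structure, lig_atoms, thresholds)
    rec_atoms = toy_channel.structure.model(0)
    contacts = detect_hbonds(rec_atoms, lig_atoms) + \
        detect_salt_bridges(rec_atoms, lig_atoms)
    linked = {r.receptor_residue for r in contacts}
    for row in rows:
        if row.category == "bonded-link":
            assert (row.chain, row.residue_seq, "") in linked


# ---------------------------------------------------------------------------
# contact rings
# ---------------------------------------------------------------------------

def test_ring_diameter_twice_radial_placement(toy_channel):
    rings = contact_rings(toy_channel.structure, toy_channel.rings)
    by_name = {r.name: r for r in rings}
    params = toy_channel.params
    assert by_name["turret"].diameter == pytest.approx(2 * params.turret.radius,
                                                       abs=1e-9)
    assert by_name["mid"].diameter == pytest.approx(2 * params.mid.radius,
                                                    abs=1e-9)
    assert by_name["pore"].diameter == pytest.approx(2 * params.pore.radius,
                                                     abs=1e-9)
    assert by_name["turret"].depth == pytest.approx(params.turret.depth)


def test_ring_diameter_matches_independent_recompute(toy_channel):
    rings = contact_rings(toy_channel.structure, toy_channel.rings)
    residues = toy_channel.structure.residues(0)
    for ring, definition in zip(rings, toy_channel.rings):
        positions = {}
        for r in residues:
            if r.residue_seq == definition.residue_seq:
                positions[r.chain_id] = r.atom(definition.atom_name).coords
        expected = np.mean([
            np.linalg.norm(positions["A"] - positions["C"]),
            np.linalg.norm(positions["B"] - positions["D"]),
        ])
        assert ring.diameter == pytest.approx(expected, abs=1e-9)


def test_ring_reports_ligand_contacts(docked):
    toy_channel, lig_atoms = docked
    rings = contact_rings(toy_channel.structure, toy_channel.rings, lig_atoms)
    assert all(r.ligand_contacts is not None for r in rings)
    assert sum(r.ligand_contacts for r in rings) > 0


def test_missing_ring_position_rejected(toy_channel):
    with pytest.raises(AddressingError):
        contact_rings(toy_channel.structure,
                      [RingDefinition("bogus", 999, "CA")])
    with pytest.raises(AddressingError):
        contact_rings(toy_channel.structure,
                      [RingDefinition("bogus", 2, "XX")])
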