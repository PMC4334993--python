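import numpy as np
import pytest

from kirdock._chemdata import CONTACT_TABLE, vdw_radius
from kirdock.dockengine import (
    DockConfig,
    assign_charges,
    build_grids,
    contact_energy,
    dock_rigid,
    read_poselist,
    rotation_set,
    scan_translations,
)
from kirdock.errors import GridError, ParameterError
from kirdock.fixtures import make_peptide, make_toy_peptide
from conftest import TPN_SEQUENCE


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def test_free_lysine_charge_plus_one():
    lys = make_peptide("KA")     # K with free N-terminus; A carries C-terminus
    model = assign_charges(lys)
    assert model.total == pytest.approx(1.0)   # +1 NZ +1 Nterm -1 Cterm


def test_tpn_formal_charge_plus_five():
    # 4 Cys (all treated non-ionized), R+1, 4xK+4, N-term +1, C-term -1, His 0
    tpn = make_peptide(TPN_SEQUENCE)
    assert assign_charges(tpn).total == pytest.approx(5.0)


def test_polyglycine_neutral_caps_zero():
    gly = make_peptide("GGGGGG")
    model = assign_charges(gly, charged_termini=False)
    assert model.total == pytest.approx(0.0)


def test_his_charge_configurable():
    his = make_peptide("AHA")
    neutral = assign_charges(his, charged_termini=False)
    protonated = assign_charges(his, charged_termini=False, his_charge=1.0)
    assert neutral.total == pytest.approx(0.0)
    assert protonated.total == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# rotation set
# ---------------------------------------------------------------------------

def test_rotation_set_identity_first():
    for step in (15.0, 30.0, 45.0, 90.0):
        rotations = rotation_set(step)
        assert np.allclose(rotations[0], np.eye(3), atol=1e-12)


def test_rotation_set_orthonormal():
    for rot in rotation_set(30.0):
        assert np.allclose(rot.T @ rot, np.eye(3), atol=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)


def test_rotation_set_count_matches_reenumeration():
    step = 30.0
    betas = np.arange(0.0, 180.0 + 1e-9, step)
    expected = 0
    seen = set()
    for beta in betas:
        if 0.0 < beta < 180.0:
            n_alpha = max(1, round(360.0 / step * np.sin(np.radians(beta))))
            alphas = np.arange(n_alpha) * (360.0 / n_alpha)
            gammas = np.arange(0.0, 360.0, step)
        else:
            alphas = np.arange(0.0, 360.0, step)
            gammas = np.array([0.0])
        from kirdock.geometry import rotation_about_axis
        for a in alphas:
            for g in gammas:
                rot = (rotation_about_axis([0, 0, 1], a)
                       @ rotation_about_axis([0, 1, 0], beta)
                       @ rotation_about_axis([0, 0, 1], g))
                seen.add(np.round(rot, 9).tobytes())
    expected = len(seen)
    assert len(rotation_set(step)) == expected


def test_rotation_set_bad_step():
    for step in (0.0, -10.0, 120.0):
        with pytest.raises(ParameterError):
            rotation_set(step)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def test_single_atom_core_matches_triple_loop():
    coords = np.array([[0.3, -0.2, 0.1]])
    grids = build_grids(coords, None, spacing=0.8, surface_thickness=1.2,
                        margin=3.0, elements=["C"])
    radius = vdw_radius("C")
    reach = radius + 1.2
    core_expected = np.zeros_like(grids.core)
    near_expected = np.zeros_like(grids.core)
    nx, ny, nz = grids.core.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = grids.origin + 0.8 * np.array([i, j, k])
                d = np.linalg.norm(p - coords[0])
                if d <= radius:
                    core_expected[i, j, k] = 1.0
                if d <= reach:
                    near_expected[i, j, k] = 1.0
    assert np.array_equal(grids.core, core_expected)
    assert np.array_equal(grids.core + grids.surface, near_expected)


def test_empty_structure_rejected():
    with pytest.raises(GridError):
        build_grids(np.zeros((0, 3)), None)


def test_charge_splatting_conserves_total():
    rng = np.random.default_rng(5)
    coords = rng.uniform(-4, 4, size=(20, 3))
    charges = rng.normal(size=20)
    grids = build_grids(coords, charges, spacing=1.1, margin=3.0)
    assert grids.charge.sum() == pytest.approx(charges.sum(), abs=1e-9)


def test_oversize_grid_rejected():
    coords = np.array([[0.0, 0, 0], [400.0, 0, 0]])
    with pytest.raises(GridError):
        build_grids(coords, None, spacing=0.5)


# ---------------------------------------------------------------------------
# translational scan
# ---------------------------------------------------------------------------

def _direct_correlation(receptor, ligand):
    """Independent triple-loop direct correlation (full output)."""
    n_rec, n_lig = receptor.shape, ligand.shape
    out_shape = tuple(n_rec[k] + n_lig[k] - 1 for k in range(3))
    out = np.zeros(out_shape)
    for dx in range(out_shape[0]):
        ox = dx - (n_lig[0] - 1)
        for dy in range(out_shape[1]):
            oy = dy - (n_lig[1] - 1)
            for dz in range(out_shape[2]):
                oz = dz - (n_lig[2] - 1)
                total = 0.0
                r0 = (max(0, ox), max(0, oy), max(0, oz))
                r1 = (min(n_rec[0], n_lig[0] + ox),
                      min(n_rec[1], n_lig[1] + oy),
                      min(n_rec[2], n_lig[2] + oz))
                if r1[0] <= r0[0] or r1[1] <= r0[1] or r1[2] <= r0[2]:
                    continue
                rec_block = receptor[r0[0]:r1[0], r0[1]:r1[1], r0[2]:r1[2]]
                lig_block = ligand[r0[0] - ox:r1[0] - ox,
                                   r0[1] - oy:r1[1] - oy,
                                   r0[2] - oz:r1[2] - oz]
                total = float(np.sum(rec_block * lig_block))
                out[dx, dy, dz] = total
    return out


def _grids_from_arrays(surface, core, charge, spacing=1.0):
    from kirdock.dockengine import ScoreGrids
    return ScoreGrids(np.zeros(3), spacing, surface.astype(float),
                      core.astype(float), charge.astype(float))


def test_fft_equals_direct_small():
    rng = np.random.default_rng(11)
    config = DockConfig(spacing=1.0)
    for _ in range(3):
        rec = [rng.random((9, 8, 10)) for _ in range(3)]
        lig = [rng.random((4, 5, 3)) for _ in range(3)]
        maps = scan_translations(_grids_from_arrays(*rec),
                                 _grids_from_arrays(*lig), config)
        assert np.max(np.abs(maps.surface_overlap
                             - _direct_correlation(rec[0], lig[0]))) < 1e-6
        assert np.max(np.abs(maps.core_overlap
                             - _direct_correlation(rec[1], lig[1]))) < 1e-6
        assert np.max(np.abs(maps.electrostatic
                             + _direct_correlation(rec[2], lig[2]))) < 1e-6


def test_two_single_atom_grids_argmax_at_shell_contact():
    a = build_grids(np.array([[0.0, 0, 0]]), None, spacing=1.0,
                    surface_thickness=1.5, margin=4.0, elements=["C"])
    b = build_grids(np.array([[0.0, 0, 0]]), None, spacing=1.0,
                    surface_thickness=1.5, margin=4.0, elements=["C"])
    config = DockConfig(spacing=1.0, weight_electrostatic=0.0)
    maps = scan_translations(a, b, config)
    direct = (_direct_correlation(a.surface, b.surface)
              - config.core_penalty * _direct_correlation(a.core, b.core))
    assert np.max(np.abs(maps.total - direct)) < 1e-6
    best = np.unravel_index(np.argmax(maps.total), maps.total.shape)
    assert maps.total[best] == pytest.approx(direct.max())
    shift = maps.shift(best)
    # surface shells overlap without core overlap: separation between the
    # vdW radius and the shell reach
    separation = np.linalg.norm(shift)
    assert vdw_radius("C") < separation <= 2 * (vdw_radius("C") + 1.5)


def test_core_on_core_strongly_negative():
    grid = build_grids(np.array([[0.0, 0, 0]]), None, spacing=1.0,
                       surface_thickness=1.5, margin=4.0, elements=["C"])
    config = DockConfig(spacing=1.0, weight_electrostatic=0.0)
    maps = scan_translations(grid, grid, config)
    center = tuple(np.asarray(grid.core.shape) - 1)
    assert maps.total[center] < 0


def test_zero_charges_zero_electrostatics():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-2, 2, size=(5, 3))
    grids = build_grids(coords, None, spacing=1.0, margin=3.0)
    maps = scan_translations(grids, grids, DockConfig(spacing=1.0))
    assert np.all(maps.electrostatic == 0.0)


def test_spacing_mismatch_rejected():
    a = build_grids(np.zeros((1, 3)), None, spacing=1.0, margin=3.0)
    b = build_grids(np.zeros((1, 3)), None, spacing=1.2, margin=3.0)
    with pytest.raises(GridError):
        scan_translations(a, b)


# ---------------------------------------------------------------------------
# contact energy
# ---------------------------------------------------------------------------

def test_contact_zero_beyond_cutoff():
    a = np.array([[0.0, 0, 0]])
    b = np.array([[10.0, 0, 0]])
    assert contact_energy(a, ["C"], b, ["C"], cutoff=6.0) == 0.0


def test_contact_single_cc_pair_table_value():
    a = np.array([[0.0, 0, 0]])
    b = np.array([[4.0, 0, 0]])
    assert contact_energy(a, ["C"], b, ["C"], cutoff=6.0) == \
        pytest.approx(CONTACT_TABLE[("C", "C")])


def test_contact_matches_brute_force(rng):
    rec = rng.uniform(-5, 5, size=(30, 3))
    lig = rng.uniform(-5, 5, size=(12, 3))
    rec_el = rng.choice(["C", "N", "O", "S"], size=30)
    lig_el = rng.choice(["C", "N", "O", "S"], size=12)
    got = contact_energy(rec, rec_el, lig, lig_el, cutoff=6.0)
    from kirdock._chemdata import contact_value
    expected = sum(
        contact_value(ea, eb)
        for a, ea in zip(rec, rec_el)
        for b, eb in zip(lig, lig_el)
        if np.linalg.norm(a - b) <= 6.0
    )
    assert got == pytest.approx(expected, abs=1e-9)


def test_contact_symmetric_in_molecule_order(rng):
    rec = rng.uniform(-4, 4, size=(15, 3))
    lig = rng.uniform(-4, 4, size=(9, 3))
    rec_el = rng.choice(["C", "N", "O", "S"], size=15)
    lig_el = rng.choice(["C", "N", "O", "S"], size=9)
    ab = contact_energy(rec, rec_el, lig, lig_el)
    ba = contact_energy(lig, lig_el, rec, rec_el)
    assert ab == pytest.approx(ba, abs=1e-9)


# ---------------------------------------------------------------------------
# dock_rigid
# ---------------------------------------------------------------------------

def test_dock_deterministic(toy_channel, toy_peptide, coarse_config):
    first = dock_rigid(toy_channel.structure, toy_peptide, coarse_config)
    second = dock_rigid(toy_channel.structure, toy_peptide, coarse_config)
    assert len(first) == len(second)
    for a, b in zip(first.poses, second.poses):
        assert a.score_total == b.score_total
        assert a.rotation_index == b.rotation_index
        assert np.array_equal(a.translation, b.translation)


def test_dock_top_n_larger_than_scanned(toy_channel, toy_peptide):
    config = DockConfig(rotation_step=90.0, top_n=10 ** 6,
                        per_rotation_keep=2, contact_pool=10 ** 6)
    poselist = dock_rigid(toy_channel.structure, toy_peptide, config)
    assert len(poselist) == 2 * len(rotation_set(90.0))


def test_poselist_scores_non_increasing(coarse_poselist):
    scores = coarse_poselist.scores()
    assert np.all(np.diff(scores) <= 1e-12)


def test_pose_total_is_weighted_component_sum(coarse_poselist, coarse_config):
    for pose in coarse_poselist.poses[:20]:
        c = pose.score_components
        total = (coarse_config.weight_shape * c["shape"]
                 + coarse_config.weight_electrostatic * c["electrostatic"]
                 + coarse_config.weight_contact * c["contact"])
        assert pose.score_total == pytest.approx(total, abs=1e-9)
        assert c["shape"] == pytest.approx(
            c["surface_overlap"] - coarse_config.core_penalty * c["core_overlap"],
            abs=1e-9)


def test_core_penalty_monotonicity(coarse_poselist, coarse_config):
    """Raising the core penalty never lifts a more-clashing pose above a
    less-clashing one it already trailed."""
    poses = coarse_poselist.poses[:40]
    core = [p.score_components["core_overlap"] for p in poses]
    if not any(c > 0 for c in core):
        pytest.skip("no clashing pose retained")

    def totals(penalty):
        return [
            coarse_config.weight_shape
            * (p.score_components["surface_overlap"]
               - penalty * p.score_components["core_overlap"])
            + coarse_config.weight_electrostatic
            * p.score_components["electrostatic"]
            + coarse_config.weight_contact * p.score_components["contact"]
            for p in poses
        ]

    low = totals(coarse_config.core_penalty)
    high = totals(50.0)
    for i in range(len(poses)):
        for j in range(len(poses)):
            if core[i] > core[j] and low[i] <= low[j]:
                assert high[i] <= high[j]


def test_score_invariant_under_common_rigid_motion(toy_channel, toy_peptide):
    from kirdock.geometry import rotation_about_axis
    config = DockConfig(rotation_step=90.0, top_n=5, contact_pool=10)
    base = dock_rigid(toy_channel.structure, toy_peptide, config)
    rot = rotation_about_axis([0, 0, 1], 90.0)
    shift = np.array([2.4, -3.6, 1.2])    # whole voxels at spacing 1.2
    moved_receptor = toy_channel.structure.transformed(rot, shift)
    moved_ligand = toy_peptide.transformed(rot, shift)
    moved = dock_rigid(moved_receptor, moved_ligand, config)
    # identical discretization up to one voxel: best scores match closely
    assert moved.poses[0].score_total == pytest.approx(
        base.poses[0].score_total, rel=0.05)


def test_poselist_tsv_roundtrip(tmp_path, coarse_poselist):
    path = coarse_poselist.to_tsv(tmp_path / "poses.tsv")
    restored = read_poselist(path)
    assert len(restored) == len(coarse_poselist)
    assert np.allclose(restored.ligand_centroid, coarse_poselist.ligand_centroid)
    for a, b in zip(coarse_poselist.poses[:10], restored.poses[:10]):
        assert a.rotation_index == b.rotation_index
        assert b.score_total == pytest.approx(a.score_total, abs=1e-5)
        assert np.allclose(a.rotation, b.rotation)
        assert np.allclose(a.translation, b.translation, atol=1e-3)


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        DockConfig(spacing=0.0)
    with pytest.raises(ParameterError):
        DockConfig(rotation_step=0.0)
    with pytest.raises(ParameterError):
        DockConfig(top_n=0)
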