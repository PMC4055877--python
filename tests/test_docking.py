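"""Receptor preparation, grid channels and the pose search."""

import numpy as np
import pytest
from rdkit import Chem

from fraggrow import docking as dk
from fraggrow import fixtures as fx
from fraggrow import molecule_io as mio
from fraggrow.errors import ConfigError, InputError, NoPoseError, SelectionError
from fraggrow.fragment_growth import VirtualCompound, attach, minimize
from fraggrow.sidechain_library import SideChainTemplate

PROPYL = SideChainTemplate("*CCC", "propyl", "direct", 3, 1)


def probe_compound(position=(0.0, 0.0, 0.0)):
    """A single-heavy-atom (methane) probe placed at an exact position."""
    mol = mio.from_smiles("C", "probe")
    xyz = mio.coords(mol)
    shift = np.asarray(position) - xyz[0]
    conf = mol.GetConformer()
    for i, p in enumerate(xyz + shift):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
    return VirtualCompound(mol, "probe", None, "probe", 0)


# ---------------------------------------------------------------------------
# receptor preparation
# ---------------------------------------------------------------------------


def test_prepare_receptor_pocket_center_is_ligand_centroid(toy_receptor_path):
    import gemmi

    receptor, pocket = dk.prepare_receptor(toy_receptor_path, "LIG")
    structure = gemmi.read_pdb(str(toy_receptor_path))
    lig = np.array([[a.pos.x, a.pos.y, a.pos.z]
                    for ch in structure[0] for res in ch if res.name == "LIG"
                    for a in res])
    assert np.allclose(pocket.center, lig.mean(axis=0), atol=1e-6)
    half_extent = (lig.max(axis=0) - lig.min(axis=0)) / 2
    assert np.all(pocket.half_widths >= half_extent)
    # ligand and waters removed from the receptor
    assert receptor.n_atoms > 0


def test_prepare_receptor_missing_selector_raises(toy_receptor_path):
    with pytest.raises(SelectionError, match="XYZ"):
        dk.prepare_receptor(toy_receptor_path, "XYZ")


def test_prepare_receptor_ambiguous_selector_raises(tmp_path, toy_receptor_path):
    text = toy_receptor_path.read_text()
    # duplicate the ligand under a second residue number
    lig_lines = [ln for ln in text.splitlines() if " LIG " in ln and ln.startswith("HETATM")]
    extra = "\n".join(ln.replace(" LIG L   1", " LIG L   2") for ln in lig_lines)
    two = tmp_path / "two_ligands.pdb"
    two.write_text(text.replace("END", extra + "\nEND"))
    with pytest.raises(SelectionError, match="2 groups"):
        dk.prepare_receptor(two, "LIG")


# ---------------------------------------------------------------------------
# grid channels
# ---------------------------------------------------------------------------


def test_empty_receptor_gives_zero_channels():
    receptor = dk.Receptor(np.zeros((0, 3)), [], np.zeros(0))
    pocket = dk.PocketSpec([0, 0, 0], [5, 5, 5])
    grid = dk.build_grid(receptor, pocket, dims=20)
    assert not grid.surf.any() and not grid.elec.any() and not grid.rep.any()


def test_electrostatic_channel_is_odd_in_receptor_charges():
    coords = np.array([[1.0, 0.5, -0.5], [-2.0, 1.0, 0.0]])
    pocket = dk.PocketSpec([0, 0, 0], [5, 5, 5])
    plus = dk.build_grid(dk.Receptor(coords, ["C", "C"], [0.4, -0.2]), pocket, dims=20)
    minus = dk.build_grid(dk.Receptor(coords, ["C", "C"], [-0.4, 0.2]), pocket, dims=20)
    assert np.allclose(plus.elec, -minus.elec)
    assert np.allclose(plus.surf, minus.surf)  # geometry channels unaffected


def test_repulsion_decays_from_atom_center():
    receptor = dk.Receptor(np.zeros((1, 3)), ["C"], np.zeros(1))
    grid = dk.build_grid(receptor, dk.PocketSpec([0, 0, 0], [6, 6, 6]), dims=121)
    center = grid.world_to_index(np.zeros((1, 3)))[0].round().astype(int)
    far = grid.world_to_index(np.array([[5.0, 0.0, 0.0]]))[0].round().astype(int)
    assert grid.rep[tuple(center)] > grid.rep[tuple(far)]
    assert grid.rep[tuple(far)] == 0.0


def test_score_points_matches_channel_value_at_lattice_point(toy_grid):
    # trilinear interpolation is exact on lattice points
    idx = np.array(np.unravel_index(np.argmin(toy_grid.surf), toy_grid.surf.shape))
    point = toy_grid.origin + toy_grid.spacing * idx
    w = (1.0, 0.3, 20.0)
    got = dk.score_points(toy_grid, point[None, :], np.zeros(1), w)
    expected = (w[0] * toy_grid.surf[tuple(idx)] + w[2] * toy_grid.rep[tuple(idx)])
    assert abs(got - expected) < 1e-9


# ---------------------------------------------------------------------------
# conformers and rotations
# ---------------------------------------------------------------------------


def test_rigid_benzene_has_one_conformer():
    mol = mio.from_smiles("c1ccccc1")
    out = dk.generate_conformers(mol, dk.DockingConfig(max_conformers=50))
    assert out.GetNumConformers() == 1


def test_flexible_chain_conformer_count_bounded_and_deterministic():
    mol = mio.from_smiles("CCCCCC")
    cfg = dk.DockingConfig(max_conformers=100)
    a = dk.generate_conformers(mol, cfg)
    b = dk.generate_conformers(mol, cfg)
    assert 1 <= a.GetNumConformers() <= 100
    assert a.GetNumConformers() == b.GetNumConformers()
    for ca, cb in zip(a.GetConformers(), b.GetConformers()):
        assert np.allclose(ca.GetPositions(), cb.GetPositions())


def test_rotation_set_is_proper_and_deterministic():
    rots = dk.rotation_set(60)
    assert rots.shape == (60, 3, 3)
    assert np.allclose(np.linalg.det(rots), 1.0)
    assert np.allclose(rots, dk.rotation_set(60))
    assert np.allclose(dk.rotation_set(12), rots[:12])


# ---------------------------------------------------------------------------
# pose search
# ---------------------------------------------------------------------------


def tiny_receptor():
    """Four wall atoms around a small site; asymmetric on purpose."""
    coords = np.array([[3.5, 0.0, 0.0], [-3.5, 0.5, 0.0],
                       [0.0, 3.5, -0.5], [0.0, -3.0, 0.5]])
    return dk.Receptor(coords, ["C"] * 4, np.zeros(4))


def brute_force_best(mol, grid, cfg):
    """Independent enumeration of all sampled poses via score_points."""
    heavy_idx, charges = dk.united_atoms(mol)
    rots = dk.rotation_set(cfg.rotation_samples)
    trans = dk._translation_lattice(grid, cfg.translation_step)
    lo, hi = grid.origin, grid.origin + grid.extent
    best = np.inf
    for conf in mol.GetConformers():
        xyz = np.asarray(conf.GetPositions())[heavy_idx]
        xyz = xyz - xyz.mean(axis=0)
        for R in rots:
            rx = xyz @ R.T
            for t in trans:
                pts = rx + t
                if np.any(pts < lo) or np.any(pts > hi):
                    continue
                s = dk.score_points(grid, pts, charges, cfg.weights)
                if s < best:
                    best = s
    return best


def test_dock_score_matches_brute_force_enumeration():
    receptor = tiny_receptor()
    pocket = dk.PocketSpec([0, 0, 0], [5, 5, 5])
    grid = dk.build_grid(receptor, pocket, dims=20)
    vc = minimize(attach(mio.from_smiles("c1ccccc1", "benzene"),
                         mio.enumerate_replaceable_sites(mio.from_smiles("c1ccccc1"))[0],
                         PROPYL))
    vc.mol = mio.assign_gasteiger_charges(vc.mol)
    cfg = dk.DockingConfig(max_conformers=2, rotation_samples=12,
                           translation_step=2.5, refine_top=0)
    mol = dk.generate_conformers(vc.mol, cfg)
    result = dk.dock_score(vc, grid, cfg, conformers=mol)
    oracle = brute_force_best(mol, grid, cfg)
    assert abs(result.score - oracle) < 1e-9


def test_dock_score_deterministic_and_permutation_invariant(toy_grid, phenol_seed):
    site = mio.enumerate_replaceable_sites(phenol_seed)[0]
    vc = minimize(attach(phenol_seed, site, PROPYL))
    vc.mol = mio.assign_gasteiger_charges(vc.mol)
    cfg = dk.DockingConfig(max_conformers=2, rotation_samples=24, translation_step=1.5)
    r1 = dk.dock_score(vc, toy_grid, cfg)
    r2 = dk.dock_score(vc, toy_grid, cfg)
    assert r1.score == pytest.approx(r2.score, abs=1e-9)

    # permute-and-redock oracle: identical conformer geometry under a
    # shuffled atom order must give the identical best score
    mol = dk.generate_conformers(vc.mol, cfg)
    base = dk.dock_score(vc, toy_grid, cfg, conformers=mol)
    order = [int(i) for i in np.random.default_rng(3).permutation(mol.GetNumAtoms())]
    permuted = Chem.RenumberAtoms(mol, order)
    for atom in permuted.GetAtoms():
        atom.SetDoubleProp("partial_charge",
                           mol.GetAtomWithIdx(order[atom.GetIdx()])
                           .GetDoubleProp("partial_charge"))
    vp = VirtualCompound(permuted, vc.seed_name, vc.site, vc.template_name, 0)
    r3 = dk.dock_score(vp, toy_grid, cfg, conformers=permuted)
    assert r3.score == pytest.approx(base.score, abs=1e-6)


def test_translation_equivariance():
    receptor = tiny_receptor()
    pocket = dk.PocketSpec([0, 0, 0], [5, 5, 5])
    shift = np.array([11.0, -7.0, 3.0])
    grid_a = dk.build_grid(receptor, pocket, dims=24)
    grid_b = dk.build_grid(receptor.translated(shift), pocket.translated(shift), dims=24)
    assert np.allclose(grid_a.surf, grid_b.surf, atol=1e-9)

    vc = probe_compound()
    cfg = dk.DockingConfig(rotation_samples=6, translation_step=2.0, refine_top=2)
    ra = dk.dock_score(vc, grid_a, cfg)
    rb = dk.dock_score(vc, grid_b, cfg)
    assert abs(ra.score - rb.score) < 1e-6


def test_methane_probe_docks_into_the_subpocket(toy_grid, toy_spec):
    """The buried-surface well is deepest inside the tube, so a free probe
    must land there."""
    vc = probe_compound()
    cfg = dk.DockingConfig(rotation_samples=1, translation_step=0.5)
    result = dk.dock_score(vc, toy_grid, cfg)
    conf_id, rot_i, pose = result.pose
    final_pos = np.asarray(pose[0])
    target = np.asarray(toy_spec.subpocket_direction) * toy_spec.pocket_radius
    assert np.linalg.norm(final_pos - target) < 2.5


METHYL = SideChainTemplate("*C", "methyl", "direct", 1, 1)


def test_methyl_toward_subpocket_outscores_methyl_at_every_other_site(
        toy_grid, phenol_seed):
    """A methyl grown toward the hydrophobic subpocket (through the throat)
    scores better (lower) than a methyl grown at any other position of the
    seed."""
    sites = {s.label: s for s in mio.enumerate_replaceable_sites(phenol_seed)}
    target = fx.subpocket_site(phenol_seed).label
    cfg = dk.DockingConfig(max_conformers=3, translation_step=1.0)
    scores = {}
    for label, site in sites.items():
        vc = minimize(attach(phenol_seed, site, METHYL))
        vc.mol = mio.assign_gasteiger_charges(vc.mol)
        scores[label] = dk.dock_score(vc, toy_grid, cfg).score
    assert min(scores, key=scores.get) == target
    others = [v for k, v in scores.items() if k != target]
    assert scores[target] < min(others) - 10.0  # a clear margin, not a tie


def test_compound_larger_than_box_raises_no_pose():
    receptor = tiny_receptor()
    grid = dk.build_grid(receptor, dk.PocketSpec([0, 0, 0], [1.5, 1.5, 1.5]), dims=10)
    vc = minimize(attach(mio.from_smiles("c1ccccc1c2ccccc2", "biphenyl"),
                         mio.enumerate_replaceable_sites(
                             mio.from_smiles("c1ccccc1c2ccccc2"))[0], PROPYL))
    vc.mol = mio.assign_gasteiger_charges(vc.mol)
    with pytest.raises(NoPoseError):
        dk.dock_score(vc, grid, dk.DockingConfig(max_conformers=1, rotation_samples=4,
                                                 translation_step=1.0))


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        dk.DockingConfig(max_conformers=0)
    with pytest.raises(ConfigError):
        dk.DockingConfig(weights=(np.inf, 0.0, 1.0))


# ---------------------------------------------------------------------------
# external score ingestion
# ---------------------------------------------------------------------------


def small_library():
    seed = mio.from_smiles("c1ccccc1", "benzene")
    sites = mio.enumerate_replaceable_sites(seed)
    lib = []
    for i, site in enumerate(sites[:3]):
        vc = attach(seed, site, PROPYL)
        vc.generation_index = i
        lib.append(vc)
    return lib


def write_scores(path, rows):
    import pandas as pd

    pd.DataFrame(rows, columns=["compound_id", "receptor_id", "score"]).to_csv(
        path, index=False)


def test_import_external_scores_round_trip(tmp_path):
    lib = small_library()
    csv = tmp_path / "scores.csv"
    write_scores(csv, [(vc.uid, "1ABC", -5.0 - i) for i, vc in enumerate(lib)])
    results = dk.import_external_scores(csv, lib)
    assert len(results) == 3
    assert {r.compound_uid for r in results} == {vc.uid for vc in lib}
    assert all(r.receptor_ref == "1ABC" for r in results)


def test_import_external_scores_negate_flips_sign(tmp_path):
    lib = small_library()
    csv = tmp_path / "scores.csv"
    write_scores(csv, [(vc.uid, "1ABC", 7.5) for vc in lib])
    results = dk.import_external_scores(csv, lib, negate=True)
    assert all(r.score == -7.5 for r in results)


def test_import_external_scores_missing_row_raises(tmp_path):
    lib = small_library()
    csv = tmp_path / "scores.csv"
    write_scores(csv, [(vc.uid, "1ABC", -5.0) for vc in lib[:-1]])
    with pytest.raises(InputError, match="missing"):
        dk.import_external_scores(csv, lib)


def test_import_external_scores_unknown_id_raises(tmp_path):
    lib = small_library()
    csv = tmp_path / "scores.csv"
    write_scores(csv, [(vc.uid, "1ABC", -5.0) for vc in lib]
                 + [("not-a-compound", "1ABC", -1.0)])
    with pytest.raises(InputError, match="unknown"):
        dk.import_external_scores(csv, lib)


def test_import_external_scores_duplicate_rows_raise(tmp_path):
    lib = small_library()
    csv = tmp_path / "scores.csv"
    write_scores(csv, [(vc.uid, "1ABC", -5.0) for vc in lib]
                 + [(lib[0].uid, "1ABC", -6.0)])
    with pytest.raises(InputError, match="duplicate"):
        dk.import_external_scores(csv, lib)
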