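"""Virtual-compound generation: side-chain attachment, clash rejection and
energy minimization.

Growth replaces one H or F of a prepared seed with a side-chain template.
The template keeps its own embedded geometry and is bonded to the seed's
anchor atom along the former H/F bond vector, with the new bond length taken
from covalent radii.  The only placement freedom left, the torsion about
the new bond, is scanned in 30 degree steps and the rotamer with the fewest
close contacts is kept; if even that rotamer clashes with the seed the
compound is rejected (the subsequent docking stage re-generates conformers,
so no fuller conformational search is attempted here).  Survivors are
minimized with MMFF94 using the distance-dependent dielectric eps = 4R and
re-checked for clashes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from . import molecule_io as mio
from .errors import ChemistryError, ConfigError, LibraryIntegrityError, MinimizationError
from .molecule_io import ReplaceableSite
from .sidechain_library import SideChainSet, SideChainTemplate

_PT = Chem.GetPeriodicTable()
TORSION_STEP_DEG = 30


@dataclass
class ClashConfig:
    """Close-contact criterion: a non-exempt pair closer than
    ``scale * (vdw_i + vdw_j)`` is a clash.  Bonded and 1-3 pairs across the
    new bond are exempt."""

    heavy_scale: float = 0.7
    h_scale: float = 0.6

    def __post_init__(self):
        if not (0.0 < self.h_scale < 1.0 and 0.0 < self.heavy_scale < 1.0):
            raise ConfigError("clash scales must lie in (0, 1)")


@dataclass
class MinimizationConfig:
    force_field: str = "MMFF94"
    dielectric_constant: float = 4.0  # eps = 4R, distance-dependent
    max_iterations: int = 500
    gradient_tol: float = 1e-4  # kcal mol^-1 A^-1

    def __post_init__(self):
        if self.gradient_tol <= 0:
            raise ConfigError("gradient tolerance must be positive")


@dataclass
class VirtualCompound:
    """One seed molecule with a single site replaced by a template."""

    mol: Chem.Mol
    seed_name: str
    site: ReplaceableSite | None
    template_name: str
    generation_index: int = -1
    is_lead: bool = False

    @property
    def site_label(self) -> str:
        return self.site.label if self.site is not None else "-"

    @property
    def uid(self) -> str:
        return f"{self.seed_name}:{self.site_label}:{self.template_name}"


@dataclass
class Rejection:
    seed_name: str
    site: ReplaceableSite
    template_name: str
    reason: str
    pair: tuple[str, str] | None = None


def vdw_radius(atomic_num: int) -> float:
    return _PT.GetRvdw(atomic_num)


def _embedded_template(template: SideChainTemplate,
                       embed_seed: int = mio.DEFAULT_EMBED_SEED) -> tuple[Chem.Mol, int, int]:
    """3D template with explicit hydrogens.  The attachment dummy is kept as
    a placeholder atom so its position defines the outgoing bond direction.
    Returns (mol, dummy_index, attach_index)."""
    mol = template.mol()
    dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise LibraryIntegrityError(
            f"template {template.name!r}: {len(dummies)} attachment dummies")
    d = dummies[0]
    attach = mol.GetAtomWithIdx(d).GetNeighbors()[0].GetIdx()
    work = Chem.RWMol(mol)
    placeholder = work.GetAtomWithIdx(d)
    placeholder.SetAtomicNum(6)  # embeddable stand-in for '*'
    placeholder.SetNoImplicit(True)
    placeholder.SetNumExplicitHs(0)
    out = work.GetMol()
    Chem.SanitizeMol(out)
    out = Chem.AddHs(out)
    if AllChem.EmbedMolecule(out, randomSeed=embed_seed) != 0:
        raise ChemistryError(f"template {template.name!r}: 3D embedding failed")
    return out, d, attach


def _align_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector src onto unit vector dst."""
    v = np.cross(src, dst)
    c = float(np.dot(src, dst))
    if np.linalg.norm(v) < 1e-10:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(src, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(src, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_rotation(perp, math.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ax, ay, az = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array([
        [ax * ax * C + c, ax * ay * C - az * s, ax * az * C + ay * s],
        [ay * ax * C + az * s, ay * ay * C + c, ay * az * C - ax * s],
        [az * ax * C - ay * s, az * ay * C + ax * s, az * az * C + c],
    ])


def _clash_pairs(seed_xyz, seed_elems, tmpl_xyz, tmpl_elems, exempt_tmpl, clash):
    """Indices (seed_i, tmpl_j) of sub-threshold contacts between the seed
    and the placed side chain."""
    if len(tmpl_xyz) == 0:
        return []
    dists = np.linalg.norm(seed_xyz[:, None, :] - tmpl_xyz[None, :, :], axis=2)
    r_seed = np.array([vdw_radius(z) for z in seed_elems])
    r_tmpl = np.array([vdw_radius(z) for z in tmpl_elems])
    is_h = (np.array(seed_elems)[:, None] == 1) | (np.array(tmpl_elems)[None, :] == 1)
    scale = np.where(is_h, clash.h_scale, clash.heavy_scale)
    thresh = scale * (r_seed[:, None] + r_tmpl[None, :])
    bad = dists < thresh
    for si, tj in exempt_tmpl:
        bad[si, tj] = False
    return list(zip(*np.nonzero(bad)))


def attach(seed: Chem.Mol, site: ReplaceableSite, template: SideChainTemplate,
           clash: ClashConfig | None = None,
           embed_seed: int = mio.DEFAULT_EMBED_SEED) -> VirtualCompound | Rejection:
    """Replace the H/F at ``site`` with ``template``.

    Returns a :class:`VirtualCompound`, or a :class:`Rejection` when every
    scanned rotamer keeps at least one intramolecular clash between the side
    chain and the seed.
    """
    clash = clash or ClashConfig()
    seed_name = seed.GetProp("_Name") if seed.HasProp("_Name") else "seed"
    site_atom = seed.GetAtomWithIdx(site.atom_index)
    if site_atom.GetAtomicNum() not in (1, 9):
        raise ConfigError(f"site {site.label} is {site_atom.GetSymbol()}, not H/F")

    seed_xyz = mio.coords(seed)
    a_pos = seed_xyz[site.anchor_index]
    u = seed_xyz[site.atom_index] - a_pos
    u /= np.linalg.norm(u)

    tmpl, d_idx, attach_idx = _embedded_template(template, embed_seed)
    txyz = mio.coords(tmpl)
    bond_len = (_PT.GetRcovalent(seed.GetAtomWithIdx(site.anchor_index).GetAtomicNum())
                + _PT.GetRcovalent(tmpl.GetAtomWithIdx(attach_idx).GetAtomicNum()))
    # orient the template so its attach->dummy direction points back at the anchor
    src = txyz[d_idx] - txyz[attach_idx]
    src /= np.linalg.norm(src)
    rot0 = _align_rotation(src, -u)
    p_att = a_pos + bond_len * u
    placed0 = (txyz - txyz[attach_idx]) @ rot0.T + p_att

    tmpl_keep = [i for i in range(tmpl.GetNumAtoms()) if i != d_idx]
    tmpl_elems = [tmpl.GetAtomWithIdx(i).GetAtomicNum() for i in tmpl_keep]
    seed_keep = [i for i in range(seed.GetNumAtoms()) if i != site.atom_index]
    seed_elems = [seed.GetAtomWithIdx(i).GetAtomicNum() for i in seed_keep]
    seed_sub = seed_xyz[seed_keep]

    # bonded / 1-3 exemptions across the new anchor-attach bond
    anchor_nbrs = {n.GetIdx() for n in seed.GetAtomWithIdx(site.anchor_index).GetNeighbors()}
    attach_nbrs = {n.GetIdx() for n in tmpl.GetAtomWithIdx(attach_idx).GetNeighbors()} - {d_idx}
    s_of = {orig: i for i, orig in enumerate(seed_keep)}
    t_of = {orig: i for i, orig in enumerate(tmpl_keep)}
    exempt = {(s_of[site.anchor_index], t_of[attach_idx])}
    exempt |= {(s_of[n], t_of[attach_idx]) for n in anchor_nbrs if n in s_of}
    exempt |= {(s_of[site.anchor_index], t_of[n]) for n in attach_nbrs}

    best = None  # (n_clashes, step, placed_coords, first_pair)
    for step in range(360 // TORSION_STEP_DEG):
        rot = _axis_rotation(u, math.radians(step * TORSION_STEP_DEG))
        placed = (placed0 - p_att) @ rot.T + p_att
        pairs = _clash_pairs(seed_sub, seed_elems, placed[tmpl_keep], tmpl_elems,
                             exempt, clash)
        if best is None or len(pairs) < best[0]:
            best = (len(pairs), step, placed, pairs[0] if pairs else None)
        if not pairs:
            break
    n_clash, _, placed, first_pair = best
    if n_clash > 0:
        si, tj = first_pair
        pair = (mio.site_label(seed, seed_keep[si],
                               seed.GetAtomWithIdx(seed_keep[si]).GetIdx()).split("@")[0],
                f"{template.name}:{tmpl_keep[tj]}")
        return Rejection(seed_name, site, template.name,
                         f"{n_clash} intramolecular clash pair(s) in best rotamer", pair)

    # assemble the product graph with the placed coordinates
    for atom in seed.GetAtoms():
        atom.SetIntProp("seed_src_idx", atom.GetIdx())
    tmpl_nd = Chem.RWMol(tmpl)
    tmpl_nd.RemoveAtom(d_idx)
    combo = Chem.RWMol(Chem.CombineMols(seed, tmpl_nd.GetMol()))
    n_seed = seed.GetNumAtoms()
    attach_new = n_seed + (attach_idx if attach_idx < d_idx else attach_idx - 1)
    combo.AddBond(site.anchor_index, attach_new, Chem.BondType.SINGLE)
    combo.RemoveAtom(site.atom_index)
    product = combo.GetMol()
    Chem.SanitizeMol(product)

    conf = Chem.Conformer(product.GetNumAtoms())
    placed_keep = placed[tmpl_keep]
    out_xyz = np.vstack([seed_sub, placed_keep])
    for i, xyz in enumerate(out_xyz):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*xyz))
    product.RemoveAllConformers()
    product.AddConformer(conf, assignId=True)
    Chem.AssignStereochemistryFrom3D(product)
    product.SetProp("_Name", f"{seed_name}_{site.label}_{template.name}")
    return VirtualCompound(product, seed_name, site, template.name)


def _force_field(mol: Chem.Mol, cfg: MinimizationConfig, conf_id: int = -1):
    if cfg.force_field.upper().startswith("MMFF"):
        props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94")
        if props is not None:
            props.SetMMFFDielectricModel(2)  # distance-dependent
            props.SetMMFFDielectricConstant(cfg.dielectric_constant)
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id)
            if ff is not None:
                return ff
    # UFF fallback for molecules outside MMFF parameterization
    return AllChem.UFFGetMoleculeForceField(mol, confId=conf_id)


def minimize(vc: VirtualCompound, cfg: MinimizationConfig | None = None) -> VirtualCompound:
    """In-vacuum minimization; the electrostic term uses eps = 4R.

    The final energy never exceeds the initial one: if the minimizer fails
    to improve, the input coordinates are kept.
    """
    cfg = cfg or MinimizationConfig()
    mol = Chem.Mol(vc.mol)
    start = mio.coords(mol)
    ff = _force_field(mol, cfg)
    e0 = ff.CalcEnergy()
    converged = ff.Minimize(maxIts=cfg.max_iterations, forceTol=cfg.gradient_tol) == 0
    e1 = ff.CalcEnergy()
    if not (math.isfinite(e0) and math.isfinite(e1)):
        raise MinimizationError(
            f"{vc.uid}: minimization diverged (E0={e0}, E1={e1})")
    if e1 > e0:
        conf = mol.GetConformer()
        for i, xyz in enumerate(start):
            conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*xyz))
        e1, converged = e0, False
    mol.SetDoubleProp("energy_initial", e0)
    mol.SetDoubleProp("energy_final", e1)
    mol.SetBoolProp("minimization_converged", converged)
    return VirtualCompound(mol, vc.seed_name, vc.site, vc.template_name,
                           vc.generation_index, vc.is_lead)


def _post_min_clash(vc: VirtualCompound, seed_n_atoms_kept: int,
                    clash: ClashConfig) -> bool:
    """Re-check seed/side-chain contacts on the minimized geometry."""
    mol = vc.mol
    xyz = mio.coords(mol)
    elems = [a.GetAtomicNum() for a in mol.GetAtoms()]
    seed_idx = [a.GetIdx() for a in mol.GetAtoms() if a.HasProp("seed_src_idx")]
    tmpl_idx = [i for i in range(mol.GetNumAtoms()) if i not in set(seed_idx)]
    if not tmpl_idx:
        return False
    # exemptions: bonded + 1-3 across the junction
    exempt = set()
    for si in seed_idx:
        for tj in tmpl_idx:
            if mol.GetBondBetweenAtoms(si, tj) is not None:
                exempt.add((si, tj))
                for n in mol.GetAtomWithIdx(si).GetNeighbors():
                    if n.GetIdx() in seed_idx:
                        exempt.add((n.GetIdx(), tj))
                for n in mol.GetAtomWithIdx(tj).GetNeighbors():
                    if n.GetIdx() in tmpl_idx:
                        exempt.add((si, n.GetIdx()))
    s_map = {orig: k for k, orig in enumerate(seed_idx)}
    t_map = {orig: k for k, orig in enumerate(tmpl_idx)}
    pairs = _clash_pairs(xyz[seed_idx], [elems[i] for i in seed_idx],
                         xyz[tmpl_idx], [elems[i] for i in tmpl_idx],
                         {(s_map[s], t_map[t]) for s, t in exempt}, clash)
    return len(pairs) > 0


def enumerate_virtual_library(
    seed: Chem.Mol,
    scset: SideChainSet,
    clash: ClashConfig | None = None,
    min_cfg: MinimizationConfig | None = None,
    sites: list[ReplaceableSite] | None = None,
    assign_charges: bool = True,
) -> tuple[list[VirtualCompound], list[Rejection]]:
    """Grow every (site, template) combination: sites ascending by atom
    index, templates in library order.  Conservation holds by construction:
    ``len(accepted) + len(rejected) == len(sites) * len(templates)``.
    """
    clash = clash or ClashConfig()
    min_cfg = min_cfg or MinimizationConfig()
    if sites is None:
        sites = mio.enumerate_replaceable_sites(seed)
    accepted: list[VirtualCompound] = []
    rejected: list[Rejection] = []
    for site in sorted(sites, key=lambda s: s.atom_index):
        for template in scset:
            result = attach(seed, site, template, clash)
            if isinstance(result, Rejection):
                rejected.append(result)
                continue
            vc = minimize(result, min_cfg)
            if _post_min_clash(vc, seed.GetNumAtoms() - 1, clash):
                rejected.append(Rejection(vc.seed_name, site, template.name,
                                          "clash re-appeared after minimization"))
                continue
            if assign_charges:
                vc.mol = mio.assign_gasteiger_charges(vc.mol)
            vc.generation_index = len(accepted)
            accepted.append(vc)
    return accepted, rejected


def write_library_sdf(compounds: list[VirtualCompound], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    for vc in compounds:
        mol = Chem.Mol(vc.mol)
        mol.SetProp("seed", vc.seed_name)
        mol.SetProp("site_label", vc.site_label)
        mol.SetProp("template", vc.template_name)
        mol.SetIntProp("generation_index", vc.generation_index)
        writer.write(mol)
    writer.close()


def write_rejections_csv(rejections: list[Rejection], path: str | Path) -> None:
    pd.DataFrame(
        [{"seed": r.seed_name, "site_label": r.site.label,
          "template": r.template_name, "reason": r.reason} for r in rejections]
    ).to_csv(path, index=False)
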