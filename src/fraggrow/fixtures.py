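"""Synthetic receptors and seeds, plus the embedded evaluation tables.

The toy receptor is a molded cavity: a double shell of uncharged
pseudo-protein carbon atoms built on the offset surface of a positioned
reference seed (so the seed fits snugly in essentially one orientation),
with a single hydrophobic subpocket -- a narrow throat opening into a
wider capped chamber, sized for small alkyl/aryl groups -- adjacent to
exactly one replaceable site of the seed.  This isolates the geometric
claim the growth method rests on: a compound grown into a complementary
subpocket gains contact surface and therefore scores best.  Real binding sites differ in every chemical respect (charge
distribution, flexibility, waters, heteroatom pharmacophores); passing on
this fixture validates the machinery, not affinity prediction on proteins.

All generation is deterministic from ``rng_seed``; identical specs produce
byte-identical PDB files.

The embedded tables transcribe the published per-target evaluation data
(15 single-structure targets, 6 multi-structure ensembles, 15 lead-spiking
runs) and are integrity-checked against a SHA-256 manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem

from . import molecule_io as mio
from .errors import FixtureIntegrityError, GeometryError
from .molecule_io import ReplaceableSite
from .prediction_eval import EnsembleRecord, LeadSpikeRecord, TargetRecord

#: stand-off of the molded wall from seed heavy atoms: vdW contact
#: (1.7 + 1.7) A stays just outside the default clash threshold
WALL_STANDOFF = 3.4
TUBE_WALL_RADIUS = 3.8
THROAT_RADIUS = 3.0
#: the wall is molded around the seed's heavy atoms only, matching the
#: united-atom ligand treatment of the scorer: the free interior then hugs
#: the seed skeleton, so a bulkier core cannot fit without penetration
SEED_KINDS = ("benzene-like", "branched", "with-F")


@dataclass
class SyntheticPocketSpec:
    n_shell_atoms: int = 320
    pocket_radius: float = 5.0  # A, cavity center to subpocket mouth region
    subpocket_direction: tuple = (1.0, 0.0, 0.0)
    subpocket_depth: float = 4.5  # A
    charge_pattern: str = "neutral"  # "neutral" | "charged-cap"
    rng_seed: int = 0

    def __post_init__(self):
        if self.pocket_radius <= 0 or self.subpocket_depth <= 0:
            raise GeometryError("pocket radius and subpocket depth must be positive")
        if self.subpocket_depth > self.pocket_radius:
            raise GeometryError("subpocket depth exceeds pocket radius")
        d = np.asarray(self.subpocket_direction, dtype=float)
        self.subpocket_direction = tuple(d / np.linalg.norm(d))


# ---------------------------------------------------------------------------
# toy seeds
# ---------------------------------------------------------------------------

_SEED_SMILES = {
    "benzene-like": ("Oc1ccccc1", "phenol-seed"),
    "branched": ("CC(C)C", "isobutane-seed"),
    "with-F": ("Oc1ccc(F)cc1", "fluorophenol-seed"),
}


def _orient_along(mol: Chem.Mol, origin_idx: int, tip_idx: int) -> Chem.Mol:
    """Rigid transform: molecule centroid (heavy atoms) to the origin and
    the origin->tip atom direction onto +x, with a deterministic choice of
    the remaining rotational freedom."""
    xyz = mio.coords(mol)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    xyz = xyz - xyz[heavy].mean(axis=0)
    u = xyz[tip_idx] - xyz[origin_idx]
    u /= np.linalg.norm(u)
    # orthonormal frame: u -> x; deterministic perpendicular -> y
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(ref, u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    rot = np.stack([u, v, w])  # rows: new basis
    new = xyz @ rot.T
    conf = mol.GetConformer()
    for i, p in enumerate(new):
        conf.SetAtomPosition(i, Chem.rdGeometry.Point3D(*p))
    return mol


def make_toy_seed(kind: str = "benzene-like") -> Chem.Mol:
    """A small fragment positioned at the cavity center with exactly one
    replaceable site pointing along +x at the subpocket."""
    if kind not in _SEED_SMILES:
        raise GeometryError(f"unknown seed kind {kind!r}; choose from {SEED_KINDS}")
    smiles, name = _SEED_SMILES[kind]
    mol = mio.from_smiles(smiles, name)
    if kind == "branched":
        # orient the lone methine C-H toward the subpocket
        ch = next(a.GetIdx() for a in mol.GetAtoms()
                  if a.GetSymbol() == "C" and a.GetDegree() == 4
                  and sum(n.GetAtomicNum() > 1 for n in a.GetNeighbors()) == 3)
        h = next(n.GetIdx() for n in mol.GetAtomWithIdx(ch).GetNeighbors()
                 if n.GetAtomicNum() == 1)
        return _orient_along(mol, ch, h)
    # phenol-type: O-bearing carbon -> para substituent defines the axis
    c_oh = next(a.GetIdx() for a in mol.GetAtoms()
                if a.GetIsAromatic()
                and any(n.GetSymbol() == "O" for n in a.GetNeighbors()))
    para = Chem.MolFromSmarts("[cX3]1[cH][cH]c(~[OX2])[cH][cH]1")
    match = mol.GetSubstructMatch(para)
    c_para = match[0]
    tip = next(n.GetIdx() for n in mol.GetAtomWithIdx(c_para).GetNeighbors()
               if n.GetAtomicNum() in (1, 9))
    return _orient_along(mol, c_oh, tip)


def subpocket_site(seed: Chem.Mol,
                   direction=(1.0, 0.0, 0.0)) -> ReplaceableSite:
    """The replaceable site whose bond vector best aligns with the
    subpocket direction."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    xyz = mio.coords(seed)
    best, best_cos = None, -2.0
    for site in mio.enumerate_replaceable_sites(seed):
        v = xyz[site.atom_index] - xyz[site.anchor_index]
        c = float(np.dot(v / np.linalg.norm(v), d))
        if c > best_cos:
            best, best_cos = site, c
    if best is None:
        raise GeometryError("seed has no replaceable sites")
    return best


# ---------------------------------------------------------------------------
# toy receptor
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    th = phi * i
    return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)


def _molded_shell(seed_xyz: np.ndarray, spec: SyntheticPocketSpec) -> np.ndarray:
    """Wall atoms on the offset surface of the seed skeleton: points at the
    stand-off distance from one seed heavy atom and no closer to any other,
    greedily thinned to an even spacing.  Two concentric layers make the
    wall effectively impenetrable and remove the attractive far side a
    single sheet of atoms would have."""
    layers = []
    for standoff in (WALL_STANDOFF, WALL_STANDOFF + 1.35):
        candidates = []
        per_atom = max(60, 6 * spec.n_shell_atoms // max(len(seed_xyz), 1))
        unit = _fibonacci_sphere(per_atom)
        for center in seed_xyz:
            pts = center + standoff * unit
            dmin = np.min(np.linalg.norm(pts[:, None, :] - seed_xyz[None, :, :], axis=2), axis=1)
            candidates.append(pts[dmin >= standoff - 0.05])
        cand = np.concatenate(candidates, axis=0)
        # deterministic greedy thinning
        spacing = 1.4
        kept: list[np.ndarray] = []
        for p in cand:
            if all(np.dot(p - q, p - q) >= spacing * spacing for q in kept):
                kept.append(p)
            if len(kept) >= spec.n_shell_atoms:
                break
        layers.append(np.asarray(kept))
    return np.concatenate(layers, axis=0)


def _subpocket_tube(spec: SyntheticPocketSpec) -> tuple[np.ndarray, int]:
    """Capped cylindrical channel along the subpocket direction.

    Returns the atoms (end-cap last) and the end-cap atom count."""
    d = np.asarray(spec.subpocket_direction)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    # narrow throat at the cavity exit, then a wider rewarding chamber: only
    # a substituent collinear with the subpocket axis can pass the throat,
    # which is what makes the adjoining seed site uniquely rewarded -- a
    # side chain grown elsewhere would have to drag the seed core into the
    # throat walls to reach the chamber
    throat = (spec.pocket_radius - 1.8, spec.pocket_radius - 0.6)
    chamber = (spec.pocket_radius + 0.6,
               spec.pocket_radius - 0.6 + spec.subpocket_depth)
    atoms = []
    for (x_lo, x_hi), radius_in in ((throat, THROAT_RADIUS),
                                    (chamber, TUBE_WALL_RADIUS)):
        for radius, stagger in ((radius_in, 0.0), (radius_in + 1.35, 0.5)):
            for x in np.arange(x_lo, x_hi + 1e-6, 1.2):
                for k in range(10):
                    th = 2 * np.pi * (k + stagger) / 10
                    atoms.append(x * d + radius * (np.cos(th) * e1 + np.sin(th) * e2))
    # end cap: two discs closing the chamber
    n_cap = 0
    for x_cap, stagger in ((chamber[1] + 1.4, 0.0), (chamber[1] + 2.7, 0.5)):
        for rr in (0.0, 1.4, 2.6):
            nk = 1 if rr == 0 else max(6, int(2 * np.pi * rr / 1.4))
            n_cap += nk
            for k in range(nk):
                th = 2 * np.pi * (k + stagger) / nk
                atoms.append(x_cap * d + rr * (np.cos(th) * e1 + np.sin(th) * e2))
    return np.asarray(atoms), n_cap


def _anchor_dimple(seed: Chem.Mol) -> np.ndarray:
    """A small recognition cup around the seed's exocyclic substituent
    (the phenol O-H), opposite the subpocket.  Together with the tube it
    makes the pocket doubly anchored: only a compound grown at the
    subpocket-facing site can engage both features at once, which removes
    the in-plane rotational degeneracy of a disc-shaped seed in a molded
    cavity."""
    xyz = mio.coords(seed)
    try:
        o_idx = next(a.GetIdx() for a in seed.GetAtoms() if a.GetSymbol() == "O")
    except StopIteration:
        return np.zeros((0, 3))
    h_idx = next((n.GetIdx() for n in seed.GetAtomWithIdx(o_idx).GetNeighbors()
                  if n.GetAtomicNum() == 1), None)
    tip = xyz[h_idx] if h_idx is not None else xyz[o_idx]
    axis = tip - xyz[o_idx] if h_idx is not None else tip / np.linalg.norm(tip)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    # deliberately sparse: a single ring plus apex gives the intact O-H a
    # modest orientation reward without creating a second subpocket that a
    # grown side chain could occupy instead of the tube
    cup_center = tip + 2.2 * axis
    atoms = [cup_center + 1.2 * axis]  # apex
    for k in range(6):
        th = 2 * np.pi * k / 6
        atoms.append(cup_center + 3.0 * (np.cos(th) * e1 + np.sin(th) * e2))
    return np.asarray(atoms)


def make_toy_receptor(spec: SyntheticPocketSpec | None = None,
                      out_path: str | Path = "toy_receptor.pdb",
                      seed_kind: str = "benzene-like") -> Path:
    """Write a synthetic pocket PDB: pseudo-protein shell (chain A, residue
    POC, carbons) plus the reference ligand (chain L, residue LIG) whose
    coordinates define the scoring box.  Per-atom charges are stored in the
    B-factor column (zero for the hydrophobic default)."""
    spec = spec or SyntheticPocketSpec()
    d = np.asarray(spec.subpocket_direction)
    seed = make_toy_seed(seed_kind)
    seed_xyz = mio.coords(seed)
    heavy_xyz = seed_xyz[[a.GetIdx() for a in seed.GetAtoms() if a.GetAtomicNum() > 1]]

    shell = _molded_shell(heavy_xyz, spec)
    tube, n_cap = _subpocket_tube(spec)
    dimple = _anchor_dimple(seed)
    # open the shell only where the tube pierces the wall
    axis_dist = np.linalg.norm(shell - np.outer(shell @ d, d), axis=1)
    along = shell @ d
    keep = ~((axis_dist < THROAT_RADIUS - 0.1) & (along > 2.0))
    shell = shell[keep]
    if len(dimple):
        # drop molded-shell atoms that would fill the dimple cup
        dmin = np.min(np.linalg.norm(shell[:, None, :] - dimple[None, :, :], axis=2), axis=1)
        shell = shell[dmin >= 1.2]

    rng = np.random.default_rng(spec.rng_seed)
    wall = np.concatenate([shell, tube, dimple], axis=0)
    wall = wall + rng.uniform(-0.05, 0.05, size=wall.shape)

    charges = np.zeros(len(wall))
    if spec.charge_pattern == "charged-cap":
        # the tube end-cap atoms carry a small negative charge
        cap = slice(len(shell) + len(tube) - n_cap, len(shell) + len(tube))
        charges[cap] = -0.2
    elif spec.charge_pattern != "neutral":
        raise GeometryError(f"unknown charge pattern {spec.charge_pattern!r}")

    # reference ligand: seed heavy atoms plus one marker inside the subpocket,
    # so the box (bbox + margin) covers both the cavity and the channel
    lig = np.vstack([heavy_xyz, spec.pocket_radius * d])

    structure = gemmi.Structure()
    structure.name = "TOYPOCKET"
    model = gemmi.Model("1")
    chain_a = gemmi.Chain("A")
    for i, (pos, q) in enumerate(zip(wall, charges)):
        res = gemmi.Residue()
        res.name = "POC"
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "C"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = float(q)
        res.add_atom(atom)
        chain_a.add_residue(res)
    chain_l = gemmi.Chain("L")
    res = gemmi.Residue()
    res.name = "LIG"
    res.seqid = gemmi.SeqId(1, " ")
    res.het_flag = "H"
    for j, pos in enumerate(lig):
        atom = gemmi.Atom()
        atom.name = f"C{j + 1}"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
    chain_l.add_residue(res)
    model.add_chain(chain_a)
    model.add_chain(chain_l)
    structure.add_model(model)
    structure.setup_entities()

    out_path = Path(out_path)
    structure.write_pdb(str(out_path))
    return out_path


# ---------------------------------------------------------------------------
# embedded evaluation tables
# ---------------------------------------------------------------------------


def paper_tables_dir() -> Path:
    return Path(resources.files("fraggrow").joinpath("data/paper_tables"))


def _verify_manifest(directory: Path) -> None:
    manifest = directory / "MANIFEST.sha256"
    for line in manifest.read_text().splitlines():
        if not line.strip():
            continue
        digest, name = line.split()
        actual = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        if actual != digest:
            raise FixtureIntegrityError(
                f"{name}: checksum mismatch (expected {digest}, got {actual})")


def load_paper_tables(directory: str | Path | None = None):
    """The transcribed evaluation tables.

    Returns ``(target_records, ensemble_records, lead_spike_records)`` --
    15 single-structure targets, 6 multi-structure ensembles and 15
    lead-spiking runs.
    """
    import pandas as pd

    directory = Path(directory) if directory else paper_tables_dir()
    _verify_manifest(directory)

    targets = [
        TargetRecord(
            row["target"], row["pdb_id"], int(row["n_sites"]), int(row["n_active"]),
            {s: int(row[f"rank_{s}"]) for s in ("A", "B", "C")},
            {s: int(row[f"n_compounds_{s}"]) for s in ("A", "B", "C")},
        )
        for _, row in pd.read_csv(directory / "targets.csv").iterrows()
    ]
    ensemble = [
        EnsembleRecord(row["target"], tuple(row["pdb_ids"].split(";")), int(row["rank"]))
        for _, row in pd.read_csv(directory / "ensemble.csv").iterrows()
    ]
    leads = [
        LeadSpikeRecord(row["target"], row["pdb_id"], int(row["n_compounds"]),
                        int(row["n_true_leads"]), int(row["best_lead_rank"]))
        for _, row in pd.read_csv(directory / "lead_spiking.csv").iterrows()
    ]
    return targets, ensemble, leads
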