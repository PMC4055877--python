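"""Reading, writing and preparing small molecules.

Molecules are represented as :class:`rdkit.Chem.Mol` objects with explicit
hydrogens.  Preparation follows the usual docking convention: assign the
dominant ionization state at pH 7 with a small rule table, then compute
Gasteiger partial charges.  Replaceable sites -- the hydrogen and fluorine
atoms that fragment growth may substitute -- are enumerated from the
prepared molecule.

Site labels are 1-based ("H7@C3" = hydrogen at atom 7 bonded to carbon at
atom 3) while all programmatic indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

from .errors import ChemistryError, ConfigError, FormatError

# seed used when a SMILES input needs a generated 3D conformer
DEFAULT_EMBED_SEED = 24601


@dataclass(frozen=True)
class ReplaceableSite:
    """A hydrogen or fluorine atom eligible for side-chain replacement."""

    atom_index: int
    anchor_index: int
    label: str


@dataclass(frozen=True)
class ProtonationRule:
    """One SMARTS-driven ionization edit.

    ``atom_pos`` selects which atom of the match is edited; ``charge_delta``
    adjusts its formal charge and ``h_delta`` adds (+1) or removes (-1) one
    explicit hydrogen on it.
    """

    name: str
    smarts: str
    atom_pos: int
    charge_delta: int
    h_delta: int

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ConfigError(f"protonation rule {self.name!r}: invalid SMARTS {self.smarts!r}")
        return patt


#: dominant ionization states at pH 7.  The charge filters (+0) make every
#: rule idempotent: a transformed group no longer matches its own pattern.
DEFAULT_PROTONATION_RULES: tuple[ProtonationRule, ...] = (
    ProtonationRule("carboxylic-acid", "[CX3](=O)[OX2H1;+0]", 2, -1, -1),
    ProtonationRule(
        "aliphatic-amine",
        "[NX3;H2,H1,H0;+0;!$([N]-[!#6;!#1]);!$([N]-c);!$([N]-C=[O,N,S,P])]",
        0, +1, +1,
    ),
    ProtonationRule("amidine-guanidine", "[NX2;H1,H0;+0]=[CX3;$([C](=N)[NX3])]", 0, +1, +1),
)


@dataclass
class ProtonationConfig:
    target_pH: float = 7.0
    rules: tuple[ProtonationRule, ...] = field(default=DEFAULT_PROTONATION_RULES)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtonationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = tuple(
            ProtonationRule(
                r["name"], r["smarts"], int(r.get("atom_pos", 0)),
                int(r.get("charge_delta", 0)), int(r.get("h_delta", 0)),
            )
            for r in raw.get("rules", [])
        )
        return cls(target_pH=float(raw.get("target_pH", 7.0)), rules=rules)


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

_FORMAT_BY_SUFFIX = {
    ".sdf": "SDF", ".sd": "SDF", ".mol": "SDF",
    ".mol2": "MOL2", ".pdb": "PDB", ".smi": "SMILES", ".smiles": "SMILES",
}


def _finalize(mol: Chem.Mol, path: str, fmt: str, name: str | None = None) -> Chem.Mol:
    """Add explicit hydrogens (with coordinates when a conformer exists) and
    stamp provenance properties."""
    if mol.GetNumConformers() > 0:
        mol = Chem.AddHs(mol, addCoords=True)
    else:
        mol = Chem.AddHs(mol)
    if name:
        mol.SetProp("_Name", name)
    mol.SetProp("provenance_path", str(path))
    mol.SetProp("provenance_format", fmt)
    return mol


def from_smiles(smiles: str, name: str = "", embed_seed: int = DEFAULT_EMBED_SEED) -> Chem.Mol:
    """Build a 3D molecule from SMILES; the conformer is generated with a
    fixed ETKDG seed recorded in the provenance properties."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"cannot parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=embed_seed) != 0:
        raise ChemistryError(f"3D embedding failed for SMILES {smiles!r}")
    mol.SetProp("_Name", name or smiles)
    mol.SetProp("provenance_path", f"smiles:{smiles}")
    mol.SetProp("provenance_format", "SMILES")
    mol.SetProp("embed_seed", str(embed_seed))
    return mol


def load_molecules(path: str | Path, fmt: str | None = None,
                   embed_seed: int = DEFAULT_EMBED_SEED) -> list[Chem.Mol]:
    """Load every record of a molecule file.  Formats: SDF, MOL2, PDB, SMILES."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (fmt or _FORMAT_BY_SUFFIX.get(path.suffix.lower(), "")).upper()
    if fmt not in {"SDF", "MOL2", "PDB", "SMILES"}:
        raise FormatError(f"unknown molecule format {fmt!r} for {path}")

    mols: list[Chem.Mol] = []
    if fmt == "SDF":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise FormatError(f"{path}: SDF record {i + 1} failed to parse")
            mols.append(_finalize(mol, str(path), fmt))
    elif fmt == "MOL2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        if mol is None:
            raise FormatError(f"{path}: MOL2 parse failure")
        mols.append(_finalize(mol, str(path), fmt))
    elif fmt == "PDB":
        # first model only; altloc A wins (RDKit keeps the first altloc)
        mol = Chem.MolFromPDBFile(str(path), removeHs=False)
        if mol is None:
            raise FormatError(f"{path}: PDB parse failure")
        mols.append(_finalize(mol, str(path), fmt))
    else:  # SMILES file: one record per line, optional name column
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            try:
                mol = from_smiles(parts[0], name=parts[1] if len(parts) > 1 else parts[0],
                                  embed_seed=embed_seed)
            except FormatError as exc:
                raise FormatError(f"{path}: line {ln}: {exc}") from exc
            mols.append(mol)
    return mols


def load_molecule(path: str | Path, fmt: str | None = None,
                  embed_seed: int = DEFAULT_EMBED_SEED) -> Chem.Mol:
    """Load the first (usually only) record of a molecule file."""
    return load_molecules(path, fmt=fmt, embed_seed=embed_seed)[0]


def write_sdf(mols, path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    for mol in mols:
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------


def prepare_protonation(mol: Chem.Mol, cfg: ProtonationConfig | None = None) -> Chem.Mol:
    """Apply the pH-7 ionization rule table, in listed order.

    Carboxylic acids are deprotonated; aliphatic amines, amidines and
    guanidines are protonated.  The input must carry explicit hydrogens;
    the returned copy does too, with formal charges updated.
    """
    cfg = cfg or ProtonationConfig()
    rw = Chem.RWMol(mol)
    for rule in cfg.rules:
        patt = rule.pattern()
        # matches are located on the current (possibly already edited) state
        for match in rw.GetMol().GetSubstructMatches(patt):
            idx = match[rule.atom_pos]
            atom = rw.GetAtomWithIdx(idx)
            atom.SetFormalCharge(atom.GetFormalCharge() + rule.charge_delta)
            if rule.h_delta < 0:
                h_idx = next((n.GetIdx() for n in atom.GetNeighbors()
                              if n.GetAtomicNum() == 1), None)
                if h_idx is None:
                    raise ChemistryError(
                        f"rule {rule.name!r}: no explicit H to remove on atom {idx}")
                rw.RemoveAtom(h_idx)
            elif rule.h_delta > 0:
                h_idx = rw.AddAtom(Chem.Atom(1))
                rw.AddBond(idx, h_idx, Chem.BondType.SINGLE)
                if rw.GetNumConformers() > 0:
                    _place_new_hydrogen(rw, idx, h_idx)
            atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    for key in ("_Name", "provenance_path", "provenance_format"):
        if mol.HasProp(key):
            out.SetProp(key, mol.GetProp(key))
    return out


def _place_new_hydrogen(rw: Chem.RWMol, heavy_idx: int, h_idx: int) -> None:
    """Geometric placement of an added proton: 1.0 A from the heavy atom,
    opposite the centroid of its existing neighbors."""
    conf = rw.GetConformer()
    heavy = np.array(conf.GetAtomPosition(heavy_idx))
    nbrs = [n.GetIdx() for n in rw.GetAtomWithIdx(heavy_idx).GetNeighbors()
            if n.GetIdx() != h_idx]
    if nbrs:
        centroid = np.mean([np.array(conf.GetAtomPosition(i)) for i in nbrs], axis=0)
        direction = heavy - centroid
    else:
        direction = np.array([1.0, 0.0, 0.0])
    norm = float(np.linalg.norm(direction))
    direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    pos = heavy + direction
    conf.SetAtomPosition(h_idx, Chem.rdGeometry.Point3D(*pos))


def assign_gasteiger_charges(mol: Chem.Mol) -> Chem.Mol:
    """Compute Gasteiger partial charges onto atom property ``partial_charge``.

    The total partial charge matches the total formal charge to 1e-3 e by
    construction of the method; a violation (or a NaN) indicates an element
    outside the parameterization and raises :class:`ChemistryError`.
    """
    mol = Chem.Mol(mol)
    try:
        ComputeGasteigerCharges(mol, throwOnParamFailure=True)
    except Exception as exc:  # RDKit raises a generic ValueError subclass
        raise ChemistryError(f"Gasteiger parameterization failure: {exc}") from exc
    total = 0.0
    for atom in mol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        if not math.isfinite(q):
            raise ChemistryError(
                f"non-finite Gasteiger charge on atom {atom.GetIdx()} "
                f"({atom.GetSymbol()})")
        atom.SetDoubleProp("partial_charge", q)
        total += q
    formal = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    if abs(total - formal) > 1e-3:
        raise ChemistryError(
            f"Gasteiger charges sum to {total:.4f}, expected {formal}")
    return mol


def partial_charges(mol: Chem.Mol) -> np.ndarray:
    """Per-atom partial charges (zeros where none were assigned)."""
    out = np.zeros(mol.GetNumAtoms())
    for atom in mol.GetAtoms():
        if atom.HasProp("partial_charge"):
            out[atom.GetIdx()] = atom.GetDoubleProp("partial_charge")
    return out


# ---------------------------------------------------------------------------
# replaceable sites
# ---------------------------------------------------------------------------


def site_label(mol: Chem.Mol, atom_index: int, anchor_index: int) -> str:
    a = mol.GetAtomWithIdx(atom_index)
    b = mol.GetAtomWithIdx(anchor_index)
    return f"{a.GetSymbol()}{atom_index + 1}@{b.GetSymbol()}{anchor_index + 1}"


def enumerate_replaceable_sites(mol: Chem.Mol) -> list[ReplaceableSite]:
    """Every hydrogen and fluorine atom, one by one, in ascending atom order.

    Both elements are monovalent substituent positions of the seed and are
    treated uniformly by the growth engine.
    """
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in (1, 9):
            continue
        nbrs = atom.GetNeighbors()
        if len(nbrs) != 1:
            continue  # e.g. bridging H in exotic inputs: not replaceable
        anchor = nbrs[0].GetIdx()
        sites.append(ReplaceableSite(atom.GetIdx(), anchor,
                                     site_label(mol, atom.GetIdx(), anchor)))
    return sites


def coords(mol: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    """Atom coordinates as an (N, 3) array in Angstrom."""
    return np.asarray(mol.GetConformer(conf_id).GetPositions(), dtype=float)
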