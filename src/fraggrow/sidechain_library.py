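"""Construction and serialization of the side-chain sets A, B and C.

The three nested hydrocarbon libraries used for virtual growth contain 78,
38 and 25 templates.  Each template is a small hydrocarbon group (up to two
aromatic rings, no heteroatoms) written as SMILES with a single attachment
dummy ``*``.  Templates are generated from a scaffold file of base
compounds 1-9 and their derivatives: every marked R position yields a
direct-attachment template, and positions on the two aromatic scaffold
families (ids 8 and 9) additionally yield linker variants --
``-CH2-`` / ``-CH2-CH2-`` / trans ``-CH=CH-`` for set A,
``-CH2-`` / ``-CH2-CH2-`` for set B and ``-CH2-`` for set C.  The vinyl
linker (set A only) mimics the geometry of amide/ester links.  Duplicates
are removed by canonical SMILES, dummy included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .errors import ConfigError, FormatError, LibraryIntegrityError

LINKERS = ("direct", "CH2", "CH2CH2", "CHeqCH")
_LINKER_SMILES = {"direct": "", "CH2": "C", "CH2CH2": "CC", "CHeqCH": "/C=C/"}
SET_LINKERS = {"C": ("CH2",), "B": ("CH2", "CH2CH2"), "A": ("CH2", "CH2CH2", "CHeqCH")}
EXPECTED_SIZES = {"A": 78, "B": 38, "C": 25}
_TIER_ORDER = {"C": 0, "B": 1, "A": 2}
#: scaffold families that receive linker variants
LINKER_SCAFFOLDS = (8, 9)


def default_scaffold_path() -> Path:
    return Path(resources.files("fraggrow").joinpath("data/scaffolds.tsv"))


@dataclass(frozen=True)
class SideChainTemplate:
    """One attachable hydrocarbon group with a single dummy-atom attachment
    point."""

    smiles: str
    name: str
    linker: str
    scaffold_id: int
    variant_id: int

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise LibraryIntegrityError(f"template {self.name!r}: bad SMILES {self.smiles!r}")
        return mol

    @property
    def canonical(self) -> str:
        return Chem.MolToSmiles(self.mol())

    def validate(self) -> None:
        mol = self.mol()
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise LibraryIntegrityError(
                f"template {self.name!r}: {len(dummies)} attachment points, expected 1")
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() not in (0, 1, 6):
                raise LibraryIntegrityError(
                    f"template {self.name!r}: heteroatom {atom.GetSymbol()} not allowed")
        if Chem.GetSSSR(mol) and _aromatic_ring_count(mol) > 2:
            raise LibraryIntegrityError(
                f"template {self.name!r}: more than two aromatic rings")
        if self.linker not in LINKERS:
            raise LibraryIntegrityError(f"template {self.name!r}: unknown linker {self.linker!r}")


def _aromatic_ring_count(mol: Chem.Mol) -> int:
    ri = mol.GetRingInfo()
    return sum(1 for ring in ri.AtomRings()
               if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring))


@dataclass
class SideChainSet:
    set_id: str
    templates: list[SideChainTemplate]

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def canonical_forms(self) -> set[str]:
        return {t.canonical for t in self.templates}

    def validate(self, expected_size: int | None = None) -> None:
        seen: dict[str, str] = {}
        for t in self.templates:
            t.validate()
            canon = t.canonical
            if canon in seen:
                raise LibraryIntegrityError(
                    f"set {self.set_id}: duplicate canonical form {canon!r} "
                    f"({seen[canon]!r} / {t.name!r})")
            seen[canon] = t.name
        if expected_size is not None and len(self.templates) != expected_size:
            raise LibraryIntegrityError(
                f"set {self.set_id}: {len(self.templates)} templates, "
                f"expected {expected_size}")


def _linker_variant(smiles: str, linker: str) -> str:
    if not smiles.startswith("*"):
        raise ConfigError(f"scaffold SMILES must start with '*': {smiles!r}")
    return "*" + _LINKER_SMILES[linker] + smiles[1:]


def _read_scaffolds(path: str | Path):
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 5:
            raise FormatError(f"{path}: line {ln}: expected 5 columns, got {len(parts)}")
        smiles, name, scaffold_id, variant_id, tier = parts
        if tier not in _TIER_ORDER:
            raise FormatError(f"{path}: line {ln}: unknown set tier {tier!r}")
        if "*" not in smiles:
            raise ConfigError(f"{path}: line {ln}: scaffold {name!r} has no marked R position")
        rows.append((smiles, name, int(scaffold_id), int(variant_id), tier))
    if not rows:
        raise ConfigError(f"{path}: no scaffold rows")
    return rows


def build_set(set_id: str, scaffold_file: str | Path | None = None) -> SideChainSet:
    """Build one side-chain set from a scaffold file.

    Every marked position contributes its direct-attachment template; the
    aromatic scaffold families additionally contribute the set's linker
    variants.  When built from the shipped scaffold file the result is
    checked against the expected cardinalities (78/38/25).
    """
    set_id = set_id.upper()
    if set_id not in SET_LINKERS:
        raise ConfigError(f"unknown side-chain set {set_id!r} (expected A, B or C)")
    shipped = scaffold_file is None
    path = default_scaffold_path() if shipped else Path(scaffold_file)

    templates: list[SideChainTemplate] = []
    seen: set[str] = set()
    for smiles, name, scaffold_id, variant_id, tier in _read_scaffolds(path):
        if _TIER_ORDER[tier] > _TIER_ORDER[set_id]:
            continue
        variants = ["direct"]
        if scaffold_id in LINKER_SCAFFOLDS:
            variants.extend(SET_LINKERS[set_id])
        for linker in variants:
            tname = name if linker == "direct" else f"{name}-{linker}"
            t = SideChainTemplate(_linker_variant(smiles, linker), tname,
                                  linker, scaffold_id, variant_id)
            t.validate()
            canon = t.canonical
            if canon in seen:
                continue
            seen.add(canon)
            templates.append(t)

    scset = SideChainSet(set_id, templates)
    if shipped:
        expected = EXPECTED_SIZES[set_id]
        if len(scset) != expected:
            raise LibraryIntegrityError(
                f"shipped set {set_id} built {len(scset)} templates, expected "
                f"{expected}; scaffold file out of sync")
    return scset


def build_all_sets(scaffold_file: str | Path | None = None) -> dict[str, SideChainSet]:
    return {sid: build_set(sid, scaffold_file) for sid in ("A", "B", "C")}


# ---------------------------------------------------------------------------
# serialization: SMILES-with-attachment dialect, one template per line
# ---------------------------------------------------------------------------

_HEADER = "# smiles\tname\tlinker\tscaffold_id\tvariant_id"


def save_library(scset: SideChainSet, path: str | Path) -> None:
    lines = [f"# fraggrow side-chain set {scset.set_id}", _HEADER]
    for t in scset.templates:
        lines.append(f"{t.smiles}\t{t.name}\t{t.linker}\t{t.scaffold_id}\t{t.variant_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_library(path: str | Path, set_id: str | None = None) -> SideChainSet:
    path = Path(path)
    if set_id is None:
        first = path.read_text().splitlines()[0] if path.exists() else ""
        set_id = first.rsplit(" ", 1)[-1] if first.startswith("# fraggrow side-chain set") else "?"
    templates = []
    seen: set[str] = set()
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 5:
            raise FormatError(f"{path}: line {ln}: expected 5 columns, got {len(parts)}")
        t = SideChainTemplate(parts[0], parts[1], parts[2], int(parts[3]), int(parts[4]))
        t.validate()
        canon = t.canonical
        if canon in seen:
            warnings.warn(f"{path}: line {ln}: duplicate canonical form {canon!r}")
        seen.add(canon)
        templates.append(t)
    return SideChainSet(set_id, templates)
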