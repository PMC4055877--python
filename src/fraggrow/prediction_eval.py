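"""Ranking, active-position prediction and evaluation statistics.

The unit of evaluation is the rank table: all virtual compounds for one
target sorted by ascending docking score (lower = better affinity).  The
site modified in the top-ranked compound is the predicted active position;
the top-2 extension collects the first two *distinct* site labels.  For a
target with known active positions, the headline statistic is whether the
best-ranked compound grown at a true active position sits at rank 1 (top-1
success) or within the first two distinct positions (top-2 success).

The random baseline pools counts across targets: p = (sum of active
positions) / (sum of replaceable H/F positions).  The two-guess baseline
treats the second guess as an independent draw, 1 - (1 - p)^2.  For the
lead-spiking experiment the baseline is the mean per-target fraction of
true leads in the spiked library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .docking import DockResult
from .errors import InputError
from .fragment_growth import VirtualCompound

RANK_COLUMNS = ["rank", "compound_id", "site_label", "template_name",
                "score", "receptor_ref", "is_lead"]


@dataclass
class RankTable:
    """Per-target ordered scores with site labels (ranks ordinal 1..N,
    scores non-decreasing, ties broken by generation order)."""

    rows: pd.DataFrame
    target_name: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def to_csv(self, path: str | Path) -> None:
        df = self.rows.copy()
        df.insert(0, "target", self.target_name)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RankTable":
        df = pd.read_csv(path)
        target = str(df["target"].iloc[0]) if "target" in df.columns and len(df) else ""
        return cls(df[RANK_COLUMNS].copy(), target)


@dataclass(frozen=True)
class TargetRecord:
    """One evaluation target: seed site counts and the per-set rank of the
    best compound grown at a true active position."""

    target_name: str
    pdb_id: str
    n_sites: int
    n_active: int
    set_ranks: dict  # set_id -> rank (1-based)
    n_compounds: dict = field(default_factory=dict)  # set_id -> library size
    active_site_labels: frozenset = frozenset()

    def __post_init__(self):
        if not (1 <= self.n_active <= self.n_sites):
            raise InputError(
                f"{self.target_name}: n_active={self.n_active} outside [1, {self.n_sites}]")
        if any(r < 1 for r in self.set_ranks.values()):
            raise InputError(f"{self.target_name}: ranks must be >= 1")


@dataclass(frozen=True)
class EnsembleRecord:
    """Merged multi-structure result for one target."""

    target_name: str
    pdb_ids: tuple
    rank: int


@dataclass(frozen=True)
class LeadSpikeRecord:
    """True-lead spiking result for one target."""

    target_name: str
    pdb_id: str
    n_compounds: int
    n_true_leads: int
    best_lead_rank: int

    def __post_init__(self):
        if not (1 <= self.n_true_leads < self.n_compounds):
            raise InputError(f"{self.target_name}: invalid lead count")
        if not (1 <= self.best_lead_rank <= self.n_compounds):
            raise InputError(f"{self.target_name}: invalid lead rank")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def rank_compounds(results: list[DockResult], target_name: str = "") -> RankTable:
    """Sort by ascending score; ties break by generation index (stable)."""
    if not results:
        raise InputError("cannot rank an empty result list")
    if any(not math.isfinite(r.score) for r in results):
        bad = [r.compound_uid for r in results if not math.isfinite(r.score)]
        raise InputError(f"non-finite scores for: {bad}")
    ordered = sorted(results, key=lambda r: (r.score, r.generation_index))
    df = pd.DataFrame({
        "rank": np.arange(1, len(ordered) + 1),
        "compound_id": [r.compound_uid for r in ordered],
        "site_label": [r.site_label for r in ordered],
        "template_name": [r.template_name for r in ordered],
        "score": [r.score for r in ordered],
        "receptor_ref": [r.receptor_ref for r in ordered],
        "is_lead": [r.is_lead for r in ordered],
    })
    return RankTable(df, target_name)


def predict_active_position(table: RankTable, k: int = 1) -> list[str]:
    """The first ``k`` distinct modified positions from the top of the
    table.  ``k=1`` is the headline prediction; ``k=2`` also admits the
    second-best distinct position."""
    if k < 1:
        raise InputError("k must be >= 1")
    seen: list[str] = []
    for label in table.rows["site_label"]:
        if label not in seen:
            seen.append(label)
        if len(seen) == k:
            return seen
    return seen  # fewer than k distinct sites available


def merge_ensemble(tables: list[RankTable]) -> RankTable:
    """Pool scores over several receptor structures of one target and
    re-rank globally by score."""
    if not tables:
        raise InputError("no tables to merge")
    reference = set(tables[0].rows["compound_id"])
    for t in tables[1:]:
        ids = set(t.rows["compound_id"])
        if ids != reference:
            raise InputError(
                "inconsistent compound libraries across tables: "
                f"only-first={sorted(reference - ids)[:5]} "
                f"only-other={sorted(ids - reference)[:5]}")
    merged = pd.concat([t.rows for t in tables], ignore_index=True)
    merged = merged.sort_values(
        ["score", "compound_id", "receptor_ref"], kind="mergesort").reset_index(drop=True)
    merged["rank"] = np.arange(1, len(merged) + 1)
    return RankTable(merged[RANK_COLUMNS].copy(), tables[0].target_name)


def active_position_rank(table: RankTable, active_sites) -> int:
    """Smallest rank whose modified site is a true active position.

    Returns ``len(table) + 1`` as a sentinel when no compound in the table
    was grown at an active position (flagged via the value itself).
    """
    active = set(active_sites)
    if not active:
        raise InputError("active_sites must be nonempty")
    hits = table.rows[table.rows["site_label"].isin(active)]
    if len(hits) == 0:
        return len(table) + 1
    return int(hits["rank"].iloc[0])


def lead_rank(table: RankTable) -> int:
    """Smallest rank held by a spiked true lead."""
    hits = table.rows[table.rows["is_lead"]]
    if len(hits) == 0:
        raise InputError("table contains no lead compounds")
    return int(hits["rank"].iloc[0])


def spike_true_leads(library: list[VirtualCompound],
                     leads: list) -> list[VirtualCompound]:
    """Append prepared true-lead molecules to the virtual library.

    Leads are tagged ``is_lead`` and receive generation indices continuing
    the library's; ranking mechanics downstream are unchanged.
    """
    import warnings

    from rdkit import Chem

    if not leads:
        raise InputError("at least one true lead is required")
    lib_canon = {Chem.MolToSmiles(Chem.RemoveHs(vc.mol)) for vc in library}
    next_index = max((vc.generation_index for vc in library), default=-1) + 1
    combined = list(library)
    for i, lead in enumerate(leads):
        mol = lead.mol if isinstance(lead, VirtualCompound) else lead
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"lead{i + 1}"
        canon = Chem.MolToSmiles(Chem.RemoveHs(mol))
        if canon in lib_canon:
            warnings.warn(f"lead {name!r} duplicates a library compound; kept")
        combined.append(VirtualCompound(mol, name, None, "__lead__",
                                        next_index + i, is_lead=True))
    return combined


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def success_rate(records: list[TargetRecord], set_id: str, k: int = 1) -> float:
    """Fraction of targets whose active-position rank is 1 (k=1) or <= 2
    (k=2, the two-distinct-positions extension)."""
    if not records:
        raise InputError("no target records")
    if k not in (1, 2):
        raise InputError("k must be 1 or 2")
    ranks = []
    for rec in records:
        if set_id not in rec.set_ranks:
            raise InputError(f"{rec.target_name}: no rank for set {set_id!r}")
        ranks.append(rec.set_ranks[set_id])
    hits = sum(1 for r in ranks if r <= k)
    return hits / len(ranks)


def random_baseline(records: list[TargetRecord], k: int = 1) -> float:
    """Probability of hitting an active position by random choice of a
    replaceable position, pooled over targets; for two guesses,
    1 - (1 - p)^2."""
    if k not in (1, 2):
        raise InputError("k must be 1 or 2")
    total_sites = sum(r.n_sites for r in records)
    total_active = sum(r.n_active for r in records)
    if total_sites == 0:
        raise InputError("zero total sites")
    p = total_active / total_sites
    return p if k == 1 else 1.0 - (1.0 - p) ** 2


def ensemble_top1_rate(records: list[EnsembleRecord]) -> float:
    if not records:
        raise InputError("no ensemble records")
    return sum(1 for r in records if r.rank == 1) / len(records)


def lead_top1_rate(records: list[LeadSpikeRecord]) -> float:
    if not records:
        raise InputError("no lead-spiking records")
    return sum(1 for r in records if r.best_lead_rank == 1) / len(records)


def lead_baseline(records: list[LeadSpikeRecord]) -> float:
    """Random-selection probability of drawing a true lead: mean per-target
    ratio of leads to library size."""
    if not records:
        raise InputError("no lead-spiking records")
    return float(np.mean([r.n_true_leads / r.n_compounds for r in records]))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def summary_statistics(targets: list[TargetRecord],
                       ensemble: list[EnsembleRecord],
                       leads: list[LeadSpikeRecord]) -> dict:
    """All headline percentages, on the 0-100 scale."""
    return {
        "random_baseline_top1_pct": 100 * random_baseline(targets, 1),
        "random_baseline_top2_pct": 100 * random_baseline(targets, 2),
        "setA_top1_pct": 100 * success_rate(targets, "A", 1),
        "setA_top2_pct": 100 * success_rate(targets, "A", 2),
        "setB_top1_pct": 100 * success_rate(targets, "B", 1),
        "setB_top2_pct": 100 * success_rate(targets, "B", 2),
        "setC_top1_pct": 100 * success_rate(targets, "C", 1),
        "setC_top2_pct": 100 * success_rate(targets, "C", 2),
        "ensemble_top1_pct": 100 * ensemble_top1_rate(ensemble),
        "lead_top1_pct": 100 * lead_top1_rate(leads),
        "lead_random_baseline_pct": 100 * lead_baseline(leads),
    }


def report(targets: list[TargetRecord], ensemble: list[EnsembleRecord],
           leads: list[LeadSpikeRecord], out_dir: str | Path) -> dict:
    """Write per-target CSVs plus a Markdown/CSV summary block; returns the
    summary dict."""
    if not (targets and ensemble and leads):
        raise InputError("all three record lists must be nonempty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([
        {"target": r.target_name, "pdb_id": r.pdb_id, "n_sites": r.n_sites,
         "n_active": r.n_active,
         **{f"rank_{s}": r.set_ranks.get(s) for s in ("A", "B", "C")},
         **{f"n_compounds_{s}": r.n_compounds.get(s) for s in ("A", "B", "C")}}
        for r in targets
    ]).to_csv(out / "targets.csv", index=False)
    pd.DataFrame([
        {"target": r.target_name, "pdb_ids": ";".join(r.pdb_ids), "rank": r.rank}
        for r in ensemble
    ]).to_csv(out / "ensemble.csv", index=False)
    pd.DataFrame([
        {"target": r.target_name, "pdb_id": r.pdb_id, "n_compounds": r.n_compounds,
         "n_true_leads": r.n_true_leads, "best_lead_rank": r.best_lead_rank}
        for r in leads
    ]).to_csv(out / "lead_spiking.csv", index=False)

    stats = summary_statistics(targets, ensemble, leads)
    pd.DataFrame([stats]).to_csv(out / "summary.csv", index=False)
    lines = ["# Active-position prediction summary", ""]
    lines += [f"- {key}: {value:.2f}%" for key, value in stats.items()]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return stats
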