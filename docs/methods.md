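# Methods

`fraggrow` implements an active-position prediction workflow for fragment
evolution, together with the evaluation machinery for measuring its success
rate over a panel of targets. This note records the model, the numerical
choices, and what the synthetic fixtures do and do not demonstrate.

## The prediction procedure

Given an active seed fragment with known 3D coordinates and a rigid
receptor structure, the method asks: *which hydrogen or fluorine position
of the seed should be modified chemically to gain affinity?* The answer is
produced by brute force:

1. **Preparation.** Molecules are set to their dominant ionization state at
   pH 7 by a small SMARTS rule table (carboxylic acids deprotonated;
   aliphatic amines, amidines and guanidines protonated) and given
   Gasteiger partial charges. Every H and F atom with a single bond is a
   replaceable site; H and F are treated uniformly as monovalent
   substituent positions.
2. **Growth.** Each site is replaced, one at a time, by each template of a
   side-chain set. The template keeps its own embedded geometry and is
   bonded to the anchor along the former bond vector, with the new bond
   length taken from covalent radii. The torsion about the new bond is
   scanned in 30° steps; the rotamer with the fewest close contacts is
   kept, and the compound is rejected when even that rotamer leaves a
   contact below `scale · (r_vdw,i + r_vdw,j)` (0.7 for heavy pairs, 0.6
   for pairs involving H; bonded and 1–3 pairs across the junction are
   exempt). Survivors are minimized with MMFF94 in vacuum using the
   distance-dependent dielectric ε = 4R, and the clash check is repeated on
   the relaxed geometry. No numeric clash criterion is inherited from
   elsewhere — the thresholds are conventional close-contact cutoffs and
   are exposed in `ClashConfig`; consequently, absolute virtual-library
   sizes are a function of this package's configuration and are not
   comparable with counts produced under other (unpublished) criteria.
3. **Docking.** Each virtual compound is scored against the receptor with
   the grid scorer described below, flexible only through a pre-generated
   conformer ensemble (ETKDG, fixed seed, RMSD-deduplicated at 0.5 Å, at
   most `max_conformers`, default 100).
4. **Ranking.** Compounds are sorted by ascending score (lower = better);
   ties break by generation order so that ranking is total and
   deterministic. The modified position of the top-ranked compound is the
   predicted active position; the top-2 prediction collects the first two
   *distinct* positions from the top of the table.

## Side-chain sets A, B and C

The three nested hydrocarbon libraries (78/38/25 templates; no
heteroatoms, at most two aromatic rings) are generated from a shipped
scaffold file of base compounds and their methyl-/ring-substituted
derivatives, each row marking one R position. Every marked position
contributes a direct-attachment template; positions on the two aromatic
families additionally contribute linker variants — `-CH2-R`,
`-CH2-CH2-R` and trans `-CH=CH-R` for set A, the first two for set B, and
`-CH2-R` only for set C. The vinyl linker is fixed *trans* because that
geometry mimics amide/ester links. Duplicates are removed by canonical
SMILES with the attachment dummy included.

Two points are deliberate design choices rather than consequences of the
rules alone. First, the published figure that defines the base compounds
is not machine-readable, so the scaffold file is a curated reconstruction;
it is data, not code, and users can substitute their own. Second, the
per-set cardinalities (78/38/25) cannot be produced by applying different
linker lists to one common position list: each linker maps attachment
positions injectively, so the number of vinyl-only templates in A (40)
could never exceed the size of set C (25). The sets must therefore draw on
nested *position* lists as well — each scaffold row carries the smallest
set that uses it (tier C ⊂ B ⊂ A), which also makes the subset invariant
C ⊆ B ⊆ A hold by construction. The shipped file is constructed so the
stated rules then yield exactly 78/38/25 after deduplication, and the
library builder raises an integrity error if the file and the expected
counts ever disagree.

## The grid scorer

The built-in scorer is a documented three-channel lattice potential; it is
not a reimplementation of any published docking program. Guided by the
observation that surface-contact terms dominate empirical docking scores
while electrostatics matter less, the composite score of a pose is

    S = w_surf · Σ_a surf(x_a) + w_elec · Σ_a q_a · elec(x_a) + w_rep · Σ_a rep(x_a)

summed over *heavy* atoms a (united-atom treatment; hydrogen charges are
condensed onto their heavy neighbors), with each channel precomputed on a
120³ lattice over the pocket box and interpolated trilinearly:

* `surf` — a Gaussian contact well per receptor atom, centred 0.5 Å
  outside the contact distance d₀ = r_vdw + 1.2 Å (probe radius), width
  σ = 0.8 Å, negated so that snug, enclosed placements (many simultaneous
  wall contacts) are rewarded.
* `elec` — Coulomb potential Σ q/(4r²), i.e. the distance-dependent
  dielectric ε = 4R, clamped below 0.5 Å and cut off at 10 Å.
* `rep` — a soft-core linear wedge `1 − r/d₀` inside the van der Waals
  envelope.

Default weights are (w_surf, w_elec, w_rep) = (1.0, 0.3, 150.0). The large
repulsion weight, combined with the linear (rather than quadratic) wedge,
makes even ~0.3 Å of penetration cost more than the contact reward it
could buy; the quadratic alternative is too gentle near the surface and
lets poses trade shallow overlap for buried contact, which destroys shape
selectivity. Legitimate poses sit at or outside d₀ and never pay this
penalty.

The pocket box is defined by the reference ligand: centre at its centroid,
half-widths from its bounding box plus a 4 Å margin. Grid dimensions
default to 120³ (spacing = box size / 119) and are configurable; the
coarse grids used by the brute-force equivalence tests are the same code
at 20³.

**Pose search.** The search is exhaustive over pre-generated conformers ×
a fixed orientation set (the 60-element icosahedral rotation group, in a
canonical order) × a translation lattice spanning the box
(`translation_step`, default 1 Å), followed by deterministic local
rigid-body refinement (Nelder–Mead over translation + rotation vector,
bounded iterations, quadratic out-of-box penalty) seeded from the
`refine_top` best discrete poses (default 5). The refinement step exists
because conformer embedding fixes an arbitrary molecular frame: 60
orientations leave up to ~25° of error, which displaces atoms by more than
an Ångström in a snug pocket and would otherwise drown shape
discrimination in sampling noise.

Two details make the seeding reliable. Seeds are *diversity-filtered*: a
candidate must use a different orientation than, or sit at least
`max(2·translation_step, 2.5 Å)` away from, every seed already chosen —
on a dense lattice the best discrete poses are otherwise near-duplicates
of a single basin. And seeds are *ranked with a softened clash term*
(`soft_seed_factor`, default 0.15× the repulsion weight, soft-docking
style): under the full penalty a discrete pose a fraction of an Ångström
off its basin floor looks terrible and the basin never gets refined,
which makes results depend on the accident of lattice alignment. Refined
poses are always re-scored with the full repulsion weight, so softening
never leaks into reported scores. With `refine_top = 0` the search is the
pure discrete enumeration at full weights, which is what the brute-force
oracle tests compare against. Everything is deterministic: identical
inputs and seeds give identical scores, and ties break toward the
earliest (conformer, rotation, translation) triple.

**Receptor treatment.** Receptors are rigid. PDB input keeps the first
model (altloc A wins), strips waters and the reference ligand, and is
treated united-atom with element vdW radii; no hydrogens are added.
Per-atom charges come from the B-factor column (the convention used by the
synthetic fixtures, whose walls are uncharged by default) or are zero.
Force-field-grade protein charge assignment is out of scope; users with a
prepared receptor and their own docking engine can bypass the built-in
scorer entirely through `import_external_scores`, which adapts any
(compound, receptor, score) CSV to the ranking machinery.

## Evaluation statistics

For a panel of targets, each with `n_sites` replaceable positions,
`n_active` true active positions, and the rank of the best compound grown
at a true active position, the package computes:

* **Top-k success rate** — fraction of targets with that rank ≤ k
  (k ∈ {1, 2}).
* **Random baseline** — pooled over targets: p = Σ n_active / Σ n_sites.
  Pooling is used rather than averaging per-target ratios because only the
  pooled form reproduces the published baseline for this panel (26.32% =
  45/171; per-target averaging gives 26.78%). For two guesses the baseline
  is 1 − (1 − p)², i.e. two independent draws with replacement; this form
  was chosen because it reproduces the published 45.71% exactly and is
  flagged here as reverse-engineered rather than quoted.
* **Ensemble merging** — scores of one compound library against several
  structures of a target are concatenated and re-ranked globally by score.
* **Lead spiking** — known true lead compounds are appended to the virtual
  library (tagged, mechanics unchanged); the statistic is the smallest
  rank any lead reaches, and the random baseline is the mean per-target
  fraction of leads in the spiked library (2.80% on the embedded panel).

The embedded panel tables (15 single-structure targets, 6 ensembles, 15
lead-spiking runs) ship as CSV with a SHA-256 manifest; `load_paper_tables`
refuses tampered files. One displayed value in the source material is a
truncation ("66%" for 4/6); the package always computes exact fractions
and formats separately.

## Synthetic fixtures: what they show

Real protein targets cannot be bundled, so the end-to-end claim is tested
on a constructed geometry that isolates what the method relies on: *a
compound grown into a complementary subpocket gains contact surface and
therefore outscores growth at any other position.*

The toy receptor is a molded cavity: two concentric shells of uncharged
carbon pseudo-atoms on the offset surface of a positioned reference seed
(stand-off 3.4 Å, matching the contact-well optimum), a single hydrophobic
subpocket along +x — a narrow throat opening into a wider, capped,
double-walled chamber — and a small, deliberately sparse recognition cup
around the seed's exocyclic substituent (the phenol O–H) on the opposite
side. Four details matter and were arrived at by construction, each
closing an exploit that exhaustive docking otherwise finds:

* **Heavy-atom molding.** The wall is molded around the seed's heavy atoms
  only, matching the scorer's united-atom ligand view. Molding around all
  atoms inflates the cavity enough that a flat two-ring aromatic fits a
  one-ring pocket.
* **Double walls.** A single sheet of atoms is attractive from both sides
  and full of gaps; two staggered layers make the wall opaque and
  one-sided.
* **The throat.** With a wide subpocket mouth, a side chain grown at *any*
  position can reach the subpocket by rotating or shifting the seed core
  within the cavity — an ether chain grown on the hydroxyl oxygen threads
  a wide tube exactly as well as a para chain. The narrow throat (radius
  3.0 Å against a 2.9 Å contact distance) admits only a substituent
  collinear with the subpocket axis; growth anywhere else would have to
  drag the ring into the throat walls.
* **The anchor cup.** A disc-shaped seed in a molded cavity can spin
  freely in its plane, which would make ring positions equivalent under
  exhaustive docking. A sparse ring of cup atoms gives the intact O–H a
  modest orientation reward; an earlier, denser cup design backfired by
  acting as a second subpocket that oxygen-grown side chains occupied
  instead of the tube.

Three seed kinds are provided: `benzene-like` (phenol, 6 sites),
`with-F` (4-fluorophenol, whose fluorine is the subpocket-facing site) and
`branched` (isobutane, 10 sites). Fixture generation is bit-reproducible
from its RNG seed (the only randomness is a ±0.05 Å jitter on wall atoms).

Passing the end-to-end test shows that growth, scoring, ranking and
prediction compose correctly and that the scorer's shape term is sharp
enough to discriminate attachment positions a bond apart. It does not
show that the scorer predicts affinity on real proteins: real sites have
heteroatom pharmacophores, waters, flexibility and charge patterns the
fixture deliberately lacks.

## Problem sizes and runtime

The default test and demonstration conditions are sized for a single CPU:
toy end-to-end runs grow the full set A (6 sites × 78 templates = 468
attachments) and dock each compound with up to 3 conformers, 60
orientations and a 1.25 Å translation lattice over a 120³ grid, about
0.5 s per compound; the nested sets B and C are evaluated as restrictions
of the set-A table rather than re-docked. The panel statistics are pure
arithmetic on the embedded tables and run in milliseconds. Grid
construction for the toy pocket takes a few seconds.

## Known limitations

* The scorer is shape-dominated by design; its electrostatic channel is
  exercised by tests but plays no role in the hydrophobic fixtures.
* Attachment-time conformational search is a single torsion scan; poses of
  the side chain are otherwise delegated to the docking conformers, so a
  clash verdict at growth time can differ from what a fuller search would
  conclude for highly congested sites.
* Protonation is a fixed rule table, not pKa prediction; tautomers are not
  enumerated.
* Virtual-library sizes depend on the clash thresholds and are not
  comparable across different threshold conventions.
* Stereocenters created by attachment inherit whatever configuration the
  3D placement produces; stereoisomers are not enumerated.
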