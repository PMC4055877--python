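# fraggrow

Active-position prediction for fragment evolution in fragment-based drug
design (FBDD).

When a weakly binding seed fragment has been found, the central question of
lead generation is *where to modify it*: which hydrogen (or fluorine)
position, when replaced by a larger group, will gain affinity? `fraggrow`
answers this in silico. Every replaceable position of the seed is
substituted, one at a time, by each member of a small hydrocarbon
side-chain library; the resulting virtual compounds are energy-minimized,
docked against the target pocket, and ranked by docking score. The
position modified in the top-ranked compound is the predicted **active
position**:

    site* = argmin over (site, template) of  S(dock(seed[site → template]))

with S the docking score (lower = better affinity). Three nested
side-chain sets are shipped — A (78 templates), B (38) and C (25) — small
hydrocarbons with up to two aromatic rings and no heteroatoms, differing
in which linker variants (`-CH2-`, `-CH2CH2-`, trans `-CH=CH-`) they
include.

The package also contains the full evaluation machinery for this kind of
method: top-1/top-2 success rates over a target panel, pooled random
baselines p = Σ n_active / Σ n_sites and 1 − (1 − p)² for two guesses,
multi-structure ensemble re-ranking, and true-lead spiking, together with
an embedded 15-target evaluation panel.

Scoring uses a documented three-channel grid potential (surface-contact
well, ε = 4R Coulomb term, soft-core repulsion) with an exhaustive,
deterministic pose search; scores from any external docking engine can be
substituted via a CSV adapter.

## Worked example

Build a side-chain library, generate a synthetic pocket whose hydrophobic
subpocket sits next to exactly one seed position, and predict that
position:

```
$ fraggrow library build --set C --out setC.tsv
set C: 25 templates -> setC.tsv

$ fraggrow make-fixture --out pocket.pdb --seed-out seed.sdf
receptor written to pocket.pdb
seed written to seed.sdf

$ fraggrow predict --seed seed.sdf --receptor pocket.pdb --set C \
      --max-conformers 3 --top-k 1 --out ranks.csv
predicted active position 1: H11@C5
```

The seed is a phenol positioned at the cavity centre; `H11@C5` is its
para C–H, the one site pointing into the subpocket, so the prediction
recovers the constructed ground truth. The rank table written to
`ranks.csv` lists every virtual compound with its site label, template and
score.

Recompute the panel statistics from the embedded evaluation tables:

```
$ fraggrow evaluate --out report/
random_baseline_top1_pct: 26.32%
random_baseline_top2_pct: 45.71%
setA_top1_pct: 60.00%
setA_top2_pct: 66.67%
setB_top1_pct: 33.33%
setB_top2_pct: 46.67%
setC_top1_pct: 33.33%
setC_top2_pct: 46.67%
ensemble_top1_pct: 66.67%
lead_top1_pct: 60.00%
lead_random_baseline_pct: 2.80%
```

Reading: across the 15-target panel, a random choice among replaceable
positions would hit a true active position 26.32% of the time; ranking
with side-chain set A predicts it correctly for 60% of targets (top-1) and
66.67% within the first two distinct positions. Spiked true lead compounds
rank first for 60% of targets against a 2.80% random-selection baseline —
an upper bound on what the scoring can deliver.

## Layout

| Module | Contents |
| --- | --- |
| `fraggrow.molecule_io` | reading/writing molecules, pH-7 protonation rules, Gasteiger charges, replaceable-site enumeration |
| `fraggrow.sidechain_library` | side-chain sets A/B/C: construction from the scaffold file, validation, serialization |
| `fraggrow.fragment_growth` | attachment, clash rejection, MMFF94 minimization (ε = 4R), library enumeration |
| `fraggrow.docking` | receptor/pocket preparation, 120³ scoring grids, conformers, deterministic pose search, external-score import |
| `fraggrow.prediction_eval` | rank tables, active-position prediction, ensemble merging, lead spiking, panel statistics, reports |
| `fraggrow.fixtures` | synthetic pockets and seeds; the embedded evaluation tables |

See `docs/methods.md` for the model, the numerical choices and the
limitations of the synthetic validation.
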