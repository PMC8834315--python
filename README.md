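# npcquant

Quantification toolkit for a pharmacological-chaperone screen against the
NPC1 cholesterol transporter. It covers the full desk-side analysis chain
of such a screen:

- **`npcquant.triage`** — ingest docking score tables or AutoDock Vina
  output (PDBQT result remarks or the log affinity table), compute
  per-heavy-atom binding efficiency (energy / non-hydrogen atom count,
  counted from SMILES with RDKit), and call hits against a natural-ligand
  reference energy with an inclusive threshold (ties are hits). A packaged
  worked example — ten candidate drugs plus the cholesterol and
  25-hydroxycholesterol references — ships with the package.
- **`npcquant.imaging`** — the filipin "LSO compartment ratio" (total
  intensity strictly above a high threshold divided by the count of pixels
  strictly above a low threshold) and plain Pearson colocalization of two
  channels, with optional masks and per-experiment aggregation.
- **`npcquant.blot`** — Western-blot densitometry: beta-actin-normalized
  levels, treatment fold changes versus a control condition, and
  Endo H-resistant/sensitive glycoform fractions computed per lane.
- **`npcquant.groupstats`** — normality-gated comparisons against a
  control: Shapiro–Wilk per group, then one-way ANOVA with Dunnett's
  many-to-one post hoc when all groups pass, otherwise Kruskal–Wallis with
  Dunn's rank comparisons (Bonferroni over the k−1 contrasts); two groups
  use the unpaired Student's t-test. Adjusted p-values map to stars with
  strict `0.05 / 0.01 / 0.001` thresholds.
- **`npcquant.synthetic`** — seeded generators for every stage: filipin
  fields with tunable perinuclear punctum accumulation and closed-form
  ground truth, channel pairs with exactly planted correlation, blot lanes
  with planted folds/fractions under lognormal noise, and score tables
  with a planted hit count. Regeneration is bit-identical per seed.
- **`npcquant.pipeline`** — config-driven orchestration (YAML/JSON, one
  schema version) with per-stage failure isolation, atomic output writes,
  and a consolidated CSV+JSON report carrying a provenance block.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the quantitative acceptance criteria
(exact table reproduction, hit calling, oracle equivalence of the imaging
statistic, colocalization and blot-recovery calibration, monotonicity of
the synthetic fields, and familywise error calibration of the gated
statistics over 2000 simulations).

## CLI

```sh
npcquant triage                         # packaged worked example, JSON summary
npcquant triage --input screen.csv --reference -11.3 --out ranking.csv
npcquant lso --manifest fields.csv --t-low 10 --t-high 120 --out ratios.csv
npcquant coloc --ch1 npc1.tif --ch2 lamp2.tif [--mask cells.tif]
npcquant blot --lanes lanes.csv --glyco glyco.csv --control DMSO --out blot
npcquant stats --input tidy.csv --control ctrl
npcquant simulate --kind filipin --seed 7 --out sim/ --param accumulation=0.8
npcquant run --config run.yaml --seed 7
```

Logs go to stderr; results go to files or JSON on stdout. Exit code is
nonzero on failure.

## Notes on conventions

- "Above threshold" is strict (`>`) for both LSO thresholds; the numerator
  uses the full intensity of supra-threshold pixels.
- Colocalization is plain Pearson over all in-scope pixels (no intensity
  thresholding); masked and unmasked values are both reported when a mask
  is supplied.
- Threshold values are explicit per run and recorded in every output; a
  percentile-based helper (`recommend_thresholds`) exists for synthetic
  work and is an artifact default, not a protocol value.
- Band signals are assumed background-corrected upstream; glycoform
  fractions are computed per lane before any averaging.
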