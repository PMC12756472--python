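# phylogrid

Community phylogenetics for grid-cell floras: given a dated phylogeny, a
grid-cell × species presence/absence matrix, and a species→genus map,
`phylogrid` computes per-cell divergence-time statistics, Faith's
phylogenetic diversity, and phylogenetic community structure, each
standardized against richness-preserving null models. It is aimed at
biogeographers asking where a regional flora is evolutionarily old or
young, and whether local assemblages are phylogenetically clustered
(consistent with environmental filtering) or overdispersed (consistent
with competitive exclusion).

## Statistics

For a grid cell holding species of genera *i* = 1…*n* with per-genus
species counts *S*ᵢ and genus ages *AGE*ᵢ (crown age; stem age for
monotypic genera):

- **MDT** (mean divergence time): `MDT = Σ(AGEᵢ·Sᵢ) / ΣSᵢ`, in Ma. The mean
  ages of the youngest and oldest genus quartiles (⌈n/4⌉ genera each) are
  reported alongside.
- **PD** (Faith's phylogenetic diversity): the sum of branch lengths on the
  union of root-to-tip paths of the cell's species (root-inclusive).
- **MPD / MNTD**: mean patristic distance over all unordered species pairs /
  mean distance from each species to its nearest co-occurring relative.
- **SES** (standardized effect size): for each statistic X,
  `SES-X = (X_obs − mean(X_null)) / sd(X_null)` over 999 (configurable)
  richness-matched uniform draws from the regional pool;
  `NRI = −SES(MPD)` and `NTI = −SES(MNTD)`, so positive values mean
  clustering. |SES| > 1.96 (strict) flags significance at P < 0.05.

Cells are classified by the (NRI, NTI) sign pair; both positive with a
significant index reads as habitat filtering, both negative as competitive
exclusion.

A seeded synthetic-data module generates dated pure-birth trees with genus
structure and landscapes assembled under four regimes (random, filtering,
overdispersion, age gradient), so the whole pipeline is testable without
any external data.

## Worked example

Generate a 200-tip dated tree (root age 100 Ma, 71 genera) with four
40-cell landscapes, run the full analysis, and check that each assembly
regime is recovered:

```bash
python analysis/01_simulate_landscapes.py
python analysis/02_full_pipeline.py
python analysis/03_scenario_recovery.py
python analysis/04_null_calibration.py
```

`02_full_pipeline.py` prints, for the random landscape:

```
genus ages: mean 28.54 +- 22.26 Ma, median 26.16 Ma over 71 genera
SR-PD: Pearson r = 0.979 (p = 1.2e-27)
```

i.e. the simulated flora is dominated by Neogene–Paleogene genus ages and
richer cells carry proportionally more evolutionary history. The scenario
sweep (`03_scenario_recovery.py`) separates the regimes cleanly:

```
         random: mean NRI -0.08, mean NTI -0.19, mean SES-PD +0.17, modal both_negative, MDT-gradient rho +0.12
      filtering: mean NRI +12.31, mean NTI +2.47, mean SES-PD -4.66, modal both_positive, MDT-gradient rho +0.15
 overdispersion: mean NRI -2.05, mean NTI -4.54, mean SES-PD +4.49, modal both_negative, MDT-gradient rho +0.11
   age_gradient: mean NRI +0.04, mean NTI +0.29, mean SES-PD -0.19, modal both_positive, MDT-gradient rho +0.97
```

Clade-filtered cells are strongly clustered (positive NRI/NTI, depressed
PD), spaced assemblages are overdispersed, and only the age-gradient
landscape shows a strong rank correlation between cell position and MDT.
Per-cell tables land in `results/`.

The same pipeline runs from the shell on your own files:

```bash
phylogrid analyze --tree tree.nwk --matrix matrix.csv --genus-map genus_map.csv \
    --reps 999 --seed 1 --out results/run1
phylogrid simulate --scenario filtering --tips 200 --cells 40 --seed 1 --out data/
phylogrid validate --tree tree.nwk --matrix matrix.csv
```

Input formats: a single Newick tree with branch lengths in Ma; a UTF-8
comma-separated matrix (first column cell id, header row species, entries
0/1/empty); a two-column `species,genus` CSV.

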