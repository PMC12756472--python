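# Methods

## Model and procedure

`phylogrid` treats a regional flora as a dated, rooted, (near-)ultrametric
phylogeny whose tips are species, plus a binary grid-cell × species
occupancy matrix. All per-cell statistics condition on observed richness:
the null hypothesis throughout is that a cell's members are a uniform
random subset of the regional pool, so departures reflect non-random
assembly, not richness differences.

Three families of statistics are computed per cell:

1. **Divergence time.** Genus ages are extracted from the tree: for genera
   with ≥ 2 tips, the age of the most recent common ancestor of their tips
   (the crown node) — this also covers non-monophyletic genera, whose MRCA
   simply sits deeper; monotypic genera fall back to the age of the tip's
   parent node (stem age) and are flagged, because a crown age is undefined
   for a single tip. MDT is the species-count-weighted mean genus age,
   `Σ(AGEᵢSᵢ)/ΣSᵢ`. The unweighted mean ages of the ⌈n/4⌉ youngest and
   oldest genera are auxiliary outputs; with fewer than four genera both
   collapse to the overall mean and are flagged.
2. **Phylogenetic diversity.** Faith's PD under the root-inclusive
   convention: the sum of branch lengths on the union of root-to-tip paths.
   This makes single-species PD well-defined (its root-path length) and the
   SES comparison self-consistent; a root edge, if present in the Newick,
   is never counted.
3. **Community structure.** MPD and MNTD on the patristic distance matrix
   (unweighted — the occupancy data are presence/absence). NRI and NTI
   negate the corresponding SES so positive = clustered.

## Null models and standardized effect sizes

One null scheme serves every statistic: richness-preserving uniform draws
without replacement from the regional pool ("pool draw") — species for
PD/MPD/MNTD, genera for MDT. MDT replicates draw as many genera as the cell
holds and reassign the cell's observed multiset of S values to the drawn
genera in draw order, preserving the weighting structure. SES uses the
sample (n−1) standard deviation over `n_reps` replicates (default 999).
Significance is |SES| > 1.96, strictly — a value of exactly ±1.96 is not
significant; a rank p-value `(r+1)/(n_reps+1)` is reported alongside but
never drives the classification. For the (NRI, NTI) sign-pair
classification, a value ≥ 0 counts as positive; an exact zero has
probability zero under a continuous null, so the convention is
inconsequential but deterministic.

Numerical choices:

- A null whose replicates are all the same assemblage (richness = pool
  size) has spread that is pure floating-point noise; any null sd below
  `1e-12 · max(1, |mean|)` is treated as zero and the SES is flagged
  undefined (NaN) rather than ±∞. Undefined SES is never significant.
- Node ages are computed as maximum tip-to-node path length (tips anchored
  at age 0), which is robust to the small rounding deviations of
  mega-tree-derived phylogenies; ultrametricity violations beyond a
  relative 1e-6 warn but do not fail.
- Quartile membership ties (equal ages) break by genus name,
  lexicographically.

Reproducibility: a single user seed spawns one PCG64 substream per
(cell, metric-group), keyed by a CRC32 of the cell id, so results are
independent of cell processing order and deleting a cell leaves all other
cells' numbers bit-identical. NRI and NTI for a cell consume the same draw
stream, which makes the two-taxon identity NRI = NTI hold exactly, not just
in distribution.

## Synthetic data

The generator emulates a provincial flora at reduced scale: a pure-birth
(Yule) tree rescaled so all tips sit at age 0 and the root at a chosen
depth, with tips partitioned into genera as contiguous runs of 1–5 tips in
leaf order (mean ≈ 3 species/genus, mixing monotypic and small genera,
comparable to the ~4.6 species/genus of large temperate floras). Landscape
cells draw a uniform richness from a configured range and sample taxa by
scenario:

- *random*: uniform (the null itself);
- *filtering*: a seed tip plus co-occupants weighted
  `exp(−d(i, seed)·strength·κ)` with κ = 5/tree-depth, giving
  clade-restricted cells;
- *overdispersion*: greedy max–min-distance selection, each step greedy
  with probability `strength`, else uniform;
- *age_gradient*: per-genus weight `exp(γ·AGE·5/max-age)` with γ sweeping
  linearly from −strength to +strength across the cell index. The 5/max-age
  factor makes the exponent dimensionless (mirroring the filtering kernel's
  κ); raw ages in Ma would overflow the exponential and collapse every cell
  onto the single oldest genus.

At `strength = 0` every scenario reduces to the uniform draw. What the
generator does **not** emulate: spatial autocorrelation between cells,
environmental covariates, abundance structure, detection error, or the
taxonomic noise of real floristic compilations. Passing scenario-recovery
tests therefore shows the statistics respond correctly to known assembly
signals, not that real-world compilations are free of confounding.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_reps` | 999 | null replicates behind every SES |
| `significance_z` | 1.96 | two-sided 5% threshold on SES (strict) |
| `seed` | 1 | master seed for all substreams |
| age-bin edges | 23.03, 66.00, 145.00 Ma | epoch boundaries for the genus-age tally (Neogene/Paleogene/Cretaceous); user-configurable because boundary conventions vary across sources |
| tree depth (synthetic) | 100 Ma (270 Ma in the acceptance script) | root age; 100 Ma yields genus-age distributions resembling a temperate flora, 270 Ma exercises the full epoch range |
| richness range (synthetic) | per script; e.g. 10–50 of 200 tips | occupancy fractions comparable to county floras |
| `strength` | 1.0 | scenario intensity in [0, 1]; 0 = random |

Age bins are half-open and lower-inclusive, `[0, e₁), [e₁, e₂), …,
[e_k, ∞)`, so a genus exactly on an edge falls in the older bin.

## Design choices

- Species present in the matrix but missing from the tree are dropped with
  a warning (recorded in the validation report), not rejected: mega-tree
  workflows routinely lose a few taxa. SR and PD are then computed over the
  same tree-matched assemblage for internal consistency.
- MPD is the *mean* over unordered pairs (the metric's standard
  definition), not a cumulative sum; at fixed richness the distinction
  cancels in the SES anyway.
- SES-MDT is computed on MDT itself; the young/old quartile means get their
  own SES values from the same null draws as auxiliary outputs, since both
  summaries are informative about whether a cell's age composition deviates
  toward antiquity or youth.
- The CSV dialect is deliberately rigid (UTF-8, comma, no quoting; names
  must not contain commas) so that read → write → read round trips are
  byte-stable and results are diffable.
- The genus-age tally and quartile machinery assume genus ages > 0; a
  zero-length terminal structure would indicate an undated tree, which is
  rejected early.

## Problem sizes

The test suite and the acceptance script run on simulated problems sized to
be statistically informative while staying quick: trees of 50–400 tips,
landscapes of 40–100 cells, 199 null replicates for calibration sweeps
(999 for sign/direction checks, 99 999 when converging on exhaustive
enumeration, which is feasible only on 6-tip pools with C(6,2)=15 or
C(6,3)=20 subsets). The library itself is vectorized (batched index draws;
a boolean path-incidence matrix for PD; tensor-indexed submatrices for
MPD/MNTD) and handles thousands of tips and hundreds of cells at 999
replicates.

## Known limitations

- Only the pool-draw null is implemented — no independent/trial-swap or
  frequency-weighted randomizations, and no abundance weighting.
- Genus ages come from the input tree; no divergence-time estimation is
  performed.
- Classification thresholds treat cells independently; no correction for
  testing many cells is applied (matching standard practice for NRI/NTI
  maps, where the 5% flag is descriptive).
- Newick only; no Nexus/PhyloXML, no polytomy resolution, no grafting of
  taxa missing from the tree.
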