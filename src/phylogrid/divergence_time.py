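"""Genus divergence times and the mean-divergence-time (MDT) statistics.

MDT of a grid cell is the species-count-weighted mean of genus ages,

    MDT = sum_i(AGE_i * S_i) / sum_i(S_i),

where AGE_i is the crown age of genus i (stem age for monotypic genera,
where a crown age is undefined) and S_i the number of species of that genus
present in the cell.  SES-MDT standardizes MDT against random reassignments
of genera from the regional pool: each replicate draws as many genera as the
cell holds, uniformly without replacement, and reassigns the cell's observed
multiset of S values to the drawn genera in draw order.  The mean ages of
the youngest and oldest genus quartiles are standardized against the same
replicate draws as auxiliary outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputValidationError, UndefinedResultError
from .io_formats import DatedTree, GenusMap
from .nullmodels import NullConfig, SESResult, null_index_batches, summarize_ses

__all__ = [
    "GenusAgeTable",
    "CellGenusCounts",
    "genus_crown_ages",
    "mdt",
    "quartile_mean_ages",
    "QuartileAges",
    "MdtSesSuite",
    "mdt_ses_suite",
    "ses_mdt",
    "mdt_bias_label",
]


@dataclass(frozen=True)
class GenusAgeTable:
    """Genus name -> age in Ma, with a flag for stem-age (monotypic) fallbacks."""

    ages: Mapping[str, float]
    monotypic: frozenset[str] = frozenset()

    def __post_init__(self):
        bad = [g for g, a in self.ages.items() if not a > 0]
        if bad:
            raise InputValidationError(f"non-positive genus age(s): {sorted(bad)}")

    def age(self, genus: str) -> float:
        return self.ages[genus]

    def genera(self) -> list[str]:
        return sorted(self.ages)

    def to_frame(self) -> pd.DataFrame:
        genera = self.genera()
        return pd.DataFrame(
            {
                "genus": genera,
                "age_Ma": [self.ages[g] for g in genera],
                "monotypic": [g in self.monotypic for g in genera],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CellGenusCounts:
    """Per-cell species counts by genus; Sum(S_i) = the cell's richness."""

    cell_id: str
    counts: Mapping[str, int]

    def __post_init__(self):
        bad = [g for g, s in self.counts.items() if s < 1]
        if bad:
            raise InputValidationError(f"non-positive species count for {sorted(bad)}")

    @property
    def n_genera(self) -> int:
        return len(self.counts)

    @property
    def richness(self) -> int:
        return sum(self.counts.values())


def cell_genus_counts(cell_id: str, species: list[str], genus_map: GenusMap) -> CellGenusCounts:
    counts: dict[str, int] = {}
    for sp in species:
        g = genus_map.genus(sp)
        counts[g] = counts.get(g, 0) + 1
    return CellGenusCounts(cell_id, counts)


def genus_crown_ages(tree: DatedTree, genus_map: GenusMap) -> GenusAgeTable:
    """Extract per-genus ages from a dated tree.

    Genera with >= 2 tips get the age of their tips' MRCA (the crown node);
    monotypic genera fall back to the age of the tip's parent node (the stem
    age) and are flagged.  Genera in the map with no tip in the tree are
    skipped with a warning.
    """
    tips_by_genus: dict[str, list[str]] = {}
    tree_tips = set(tree.tip_labels)
    for sp, gen in genus_map.mapping.items():
        if sp in tree_tips:
            tips_by_genus.setdefault(gen, []).append(sp)
    absent = sorted(set(genus_map.genera()) - set(tips_by_genus))
    if absent:
        warnings.warn(
            f"{len(absent)} genus/genera with no tips in the tree were skipped",
            stacklevel=2,
        )
    ages: dict[str, float] = {}
    monotypic: set[str] = set()
    for gen, tips in tips_by_genus.items():
        if len(tips) == 1:
            ages[gen] = tree.stem_age(tips[0])
            monotypic.add(gen)
        else:
            ages[gen] = tree.mrca_age(tips)
    return GenusAgeTable(ages=ages, monotypic=frozenset(monotypic))


def mdt(cell: CellGenusCounts, ages: GenusAgeTable) -> float:
    """Species-count-weighted mean genus age of a cell, in Ma."""
    if cell.n_genera == 0:
        raise UndefinedResultError(f"cell {cell.cell_id!r} has no genera")
    num = 0.0
    den = 0
    for gen, s in cell.counts.items():
        num += ages.age(gen) * s
        den += s
    return num / den


@dataclass(frozen=True)
class QuartileAges:
    young_mean: float
    old_mean: float
    flagged: bool  # True when the cell has < 4 genera (both means = overall mean)


def _sorted_cell_ages(cell: CellGenusCounts, ages: GenusAgeTable) -> np.ndarray:
    # Age ties broken by genus name, lexicographically, for determinism.
    ordered = sorted(cell.counts, key=lambda g: (ages.age(g), g))
    return np.array([ages.age(g) for g in ordered], dtype=float)


def quartile_mean_ages(cell: CellGenusCounts, ages: GenusAgeTable) -> QuartileAges:
    """Unweighted mean age of the ceil(n/4) youngest and oldest genera."""
    if cell.n_genera == 0:
        raise UndefinedResultError(f"cell {cell.cell_id!r} has no genera")
    vals = _sorted_cell_ages(cell, ages)
    n = vals.size
    if n < 4:
        m = float(vals.mean())
        return QuartileAges(m, m, flagged=True)
    q = math.ceil(n / 4)
    return QuartileAges(float(vals[:q].mean()), float(vals[-q:].mean()), flagged=False)


@dataclass(frozen=True)
class MdtSesSuite:
    """SES of MDT plus the young/old quartile-mean auxiliaries, one null stream."""

    mdt: SESResult
    young_quartile: SESResult
    old_quartile: SESResult
    quartiles_flagged: bool


def mdt_ses_suite(
    cell: CellGenusCounts,
    ages: GenusAgeTable,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> MdtSesSuite:
    """SES-MDT and quartile SES values from a single sequence of null draws."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = ages.genera()
    k = cell.n_genera
    if k == 0:
        raise UndefinedResultError(f"cell {cell.cell_id!r} has no genera")
    missing = sorted(set(cell.counts) - set(pool))
    if missing:
        raise InputValidationError(f"cell genera not in age table: {missing}")
    pool_ages = np.array([ages.age(g) for g in pool], dtype=float)
    # The cell's S multiset, in genus-name order; reassigned to drawn genera
    # in draw order under the null.
    s = np.array([cell.counts[g] for g in sorted(cell.counts)], dtype=float)
    q = math.ceil(k / 4)
    obs_mdt = mdt(cell, ages)
    obs_q = quartile_mean_ages(cell, ages)

    null_mdt = np.empty(config.n_reps)
    null_young = np.empty(config.n_reps)
    null_old = np.empty(config.n_reps)
    pos = 0
    for idx in null_index_batches(len(pool), k, config.n_reps, rng):
        drawn = pool_ages[idx]  # (chunk, k) ages in draw order
        null_mdt[pos : pos + len(idx)] = drawn @ s / s.sum()
        srt = np.sort(drawn, axis=1)
        if k < 4:
            m = srt.mean(axis=1)
            null_young[pos : pos + len(idx)] = m
            null_old[pos : pos + len(idx)] = m
        else:
            null_young[pos : pos + len(idx)] = srt[:, :q].mean(axis=1)
            null_old[pos : pos + len(idx)] = srt[:, -q:].mean(axis=1)
        pos += len(idx)

    z = config.significance_z
    return MdtSesSuite(
        mdt=summarize_ses(obs_mdt, null_mdt, z),
        young_quartile=summarize_ses(obs_q.young_mean, null_young, z),
        old_quartile=summarize_ses(obs_q.old_mean, null_old, z),
        quartiles_flagged=obs_q.flagged,
    )


def ses_mdt(
    cell: CellGenusCounts,
    ages: GenusAgeTable,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """Standardized effect size of MDT under random genus reassignment."""
    return mdt_ses_suite(cell, ages, config, rng).mdt


def mdt_bias_label(result: SESResult) -> str:
    """'ancient-biased' / 'young-biased' / 'none' per the |1.96| rule."""
    if result.significant and result.ses > 0:
        return "ancient-biased"
    if result.significant and result.ses < 0:
        return "young-biased"
    return "none"
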