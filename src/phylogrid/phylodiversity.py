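"""Faith's phylogenetic diversity (PD) and its standardized effect size.

PD of an assemblage is the sum of branch lengths of the union of paths from
each of its tips to the tree root (root-inclusive convention, so a
single-species assemblage has PD equal to its root-path length).  SES-PD
standardizes the observed PD against richness-matched uniform draws from
the regional species pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import InputValidationError, UndefinedResultError
from .io_formats import DatedTree
from .nullmodels import NullConfig, SESResult, null_index_batches, summarize_ses

__all__ = ["PDValue", "faith_pd", "ses_pd", "sr_pd_correlation"]


@dataclass(frozen=True)
class PDValue:
    cell: str
    sr: int
    pd: float


def _tip_rows(tree: DatedTree, taxa: Iterable[str]) -> np.ndarray:
    rows = np.array([tree.tip_index(t) for t in set(taxa)], dtype=np.intp)
    if rows.size == 0:
        raise InputValidationError("empty taxon set")
    return rows


def faith_pd(tree: DatedTree, taxa: Iterable[str]) -> float:
    """Sum of branch lengths spanned by ``taxa`` (paths to the root included)."""
    rows = _tip_rows(tree, taxa)
    covered = tree.path_matrix()[rows].any(axis=0)
    return float(tree.branch_lengths @ covered)


def ses_pd(
    taxa: Iterable[str],
    pool: Sequence[str],
    tree: DatedTree,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """SES of Faith PD against richness-matched uniform pool draws."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taxa = set(taxa)
    pool_sorted = sorted(set(pool))
    if not taxa <= set(pool_sorted):
        raise InputValidationError("cell taxa must be a subset of the pool")
    observed = faith_pd(tree, taxa)
    pool_rows = np.array([tree.tip_index(t) for t in pool_sorted], dtype=np.intp)
    paths = tree.path_matrix()[pool_rows]  # (pool, edges)
    lengths = tree.branch_lengths
    nulls = np.empty(config.n_reps)
    pos = 0
    for idx in null_index_batches(len(pool_sorted), len(taxa), config.n_reps, rng):
        covered = paths[idx].any(axis=1)  # (chunk, edges)
        nulls[pos : pos + len(idx)] = covered @ lengths
        pos += len(idx)
    return summarize_ses(observed, nulls, config.significance_z)


def sr_pd_correlation(pd_values: Sequence[PDValue]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between SR and PD across cells."""
    if len(pd_values) < 3:
        raise UndefinedResultError("need >= 3 cells for the SR-PD correlation")
    sr = np.array([v.sr for v in pd_values], dtype=float)
    pd_ = np.array([v.pd for v in pd_values], dtype=float)
    if sr.std() == 0 or pd_.std() == 0:
        raise UndefinedResultError("SR (or PD) is constant across cells")
    r, p = stats.pearsonr(sr, pd_)
    return float(r), float(p)
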