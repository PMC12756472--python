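"""Phylogenetic community structure: MPD, MNTD, NRI, NTI and classification.

MPD is the mean patristic distance over all unordered pairs in an
assemblage; MNTD the mean distance from each taxon to its nearest
co-occurring relative.  NRI and NTI negate the standardized effect sizes of
MPD and MNTD so that positive values mean phylogenetic clustering
(co-occurring taxa more related than richness-matched random draws from the
pool) and negative values overdispersion.  |value| > 1.96 (strict) flags
significance at P < 0.05; clustering under that rule is conventionally read
as habitat filtering, overdispersion as competitive exclusion.

For one cell, NRI and NTI are computed from the same sequence of null
assemblages, so the two-taxon identity NRI == NTI holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputValidationError, UndefinedResultError
from .io_formats import DatedTree
from .nullmodels import NullConfig, SESResult, null_index_batches, summarize_ses

__all__ = [
    "DistanceMatrix",
    "StructureClassification",
    "patristic_distances",
    "mpd",
    "mntd",
    "nri",
    "nti",
    "structure_ses",
    "classify",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise patristic distances (Ma) with a zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputValidationError("distance matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise InputValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise InputValidationError("distance matrix diagonal not zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def index_of(self, taxa: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[t] for t in taxa], dtype=np.intp)
        except KeyError as exc:
            raise InputValidationError(f"unknown taxon {exc.args[0]!r}") from None

    def distance(self, a: str, b: str) -> float:
        i, j = self.index_of([a, b])
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="taxon")


def patristic_distances(tree: DatedTree) -> DistanceMatrix:
    """All pairwise tip-to-tip path-length distances, by one postorder pass.

    At each internal node, tips descending through different children are at
    distance d_i + d_j, where d is the accumulated distance from the tip up
    to that node; every unordered tip pair is realized exactly once, at its
    MRCA.
    """
    n = tree.n_tips
    D = np.zeros((n, n), dtype=float)
    acc: dict = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            acc[node] = (
                np.array([tree.tip_index(label)], dtype=np.intp),
                np.zeros(1),
            )
            continue
        child_data = []
        for child in node.child_nodes():
            tips, dist = acc.pop(child)
            child_data.append((tips, dist + (child.edge.length or 0.0)))
        for a in range(len(child_data)):
            ta, da = child_data[a]
            for b in range(a + 1, len(child_data)):
                tb, db = child_data[b]
                block = da[:, None] + db[None, :]
                D[np.ix_(ta, tb)] = block
                D[np.ix_(tb, ta)] = block.T
        acc[node] = (
            np.concatenate([t for t, _ in child_data]),
            np.concatenate([d for _, d in child_data]),
        )
    return DistanceMatrix(labels=tuple(tree.tip_labels), matrix=D)


def _sub(dist: DistanceMatrix, taxa: Iterable[str]) -> np.ndarray:
    idx = dist.index_of(sorted(set(taxa)))
    if idx.size < 2:
        raise UndefinedResultError("MPD/MNTD need at least 2 taxa")
    return dist.matrix[np.ix_(idx, idx)]


def mpd(taxa: Iterable[str], dist: DistanceMatrix) -> float:
    """Mean pairwise distance over all unordered pairs within ``taxa``."""
    sub = _sub(dist, taxa)
    iu = np.triu_indices(sub.shape[0], k=1)
    return float(sub[iu].mean())


def mntd(taxa: Iterable[str], dist: DistanceMatrix) -> float:
    """Mean distance from each taxon to its nearest neighbour in ``taxa``."""
    sub = _sub(dist, taxa).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_mpd_mntd(
    pool_matrix: np.ndarray,
    richness: int,
    config: NullConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    null_mpd = np.empty(config.n_reps)
    null_mntd = np.empty(config.n_reps)
    iu = np.triu_indices(richness, k=1)
    pos = 0
    for idx in null_index_batches(pool_matrix.shape[0], richness, config.n_reps, rng):
        sub = pool_matrix[idx[:, :, None], idx[:, None, :]]  # (chunk, k, k)
        null_mpd[pos : pos + len(idx)] = sub[:, iu[0], iu[1]].mean(axis=1)
        diag = np.arange(richness)
        sub[:, diag, diag] = np.inf
        null_mntd[pos : pos + len(idx)] = sub.min(axis=2).mean(axis=1)
        pos += len(idx)
    return null_mpd, null_mntd


def structure_ses(
    taxa: Iterable[str],
    pool: Sequence[str],
    dist: DistanceMatrix,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SESResult, SESResult]:
    """(NRI, NTI) for one cell, sharing a single stream of null assemblages."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taxa = set(taxa)
    pool_sorted = sorted(set(pool))
    if not taxa <= set(pool_sorted):
        raise InputValidationError("cell taxa must be a subset of the pool")
    if len(taxa) < 2:
        raise UndefinedResultError("NRI/NTI need at least 2 taxa")
    pool_idx = dist.index_of(pool_sorted)
    pool_matrix = dist.matrix[np.ix_(pool_idx, pool_idx)]
    obs_mpd = mpd(taxa, dist)
    obs_mntd = mntd(taxa, dist)
    null_mpd, null_mntd = _null_mpd_mntd(pool_matrix, len(taxa), config, rng)
    z = config.significance_z
    return (
        summarize_ses(obs_mpd, null_mpd, z, sign=-1),
        summarize_ses(obs_mntd, null_mntd, z, sign=-1),
    )


def nri(
    taxa: Iterable[str],
    pool: Sequence[str],
    dist: DistanceMatrix,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """Net relatedness index: -1 x SES of MPD under the pool-draw null."""
    return structure_ses(taxa, pool, dist, config, rng)[0]


def nti(
    taxa: Iterable[str],
    pool: Sequence[str],
    dist: DistanceMatrix,
    config: NullConfig,
    rng: np.random.Generator | None = None,
) -> SESResult:
    """Nearest taxon index: -1 x SES of MNTD under the pool-draw null."""
    return structure_ses(taxa, pool, dist, config, rng)[1]


@dataclass(frozen=True)
class StructureClassification:
    cell_id: str
    nri: float
    nti: float
    category: str  # both_positive | both_negative | nri_pos_nti_neg | nri_neg_nti_pos
    nri_significant: bool
    nti_significant: bool
    interpretation: str  # habitat_filtering | competitive_exclusion | mixed | random


def classify(
    nri_result: SESResult, nti_result: SESResult, cell_id: str = ""
) -> StructureClassification:
    """Sign-pair category and significance flags for one cell.

    A value >= 0 counts as positive (an exact 0 has probability zero under a
    continuous null).  Both-positive with at least one |value| > 1.96 is
    labelled habitat filtering; both-negative likewise competitive exclusion.
    """
    if not (nri_result.defined and nti_result.defined):
        return StructureClassification(
            cell_id, nri_result.ses, nti_result.ses, "undefined", False, False, "undefined"
        )
    nri_v, nti_v = nri_result.ses, nti_result.ses
    pos = (nri_v >= 0, nti_v >= 0)
    category = {
        (True, True): "both_positive",
        (False, False): "both_negative",
        (True, False): "nri_pos_nti_neg",
        (False, True): "nri_neg_nti_pos",
    }[pos]
    any_sig = nri_result.significant or nti_result.significant
    if category == "both_positive" and any_sig:
        interpretation = "habitat_filtering"
    elif category == "both_negative" and any_sig:
        interpretation = "competitive_exclusion"
    elif any_sig:
        interpretation = "mixed"
    else:
        interpretation = "random"
    return StructureClassification(
        cell_id,
        nri_v,
        nti_v,
        category,
        nri_result.significant,
        nti_result.significant,
        interpretation,
    )
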