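"""Seeded generators for dated trees and grid-cell landscapes.

The generators provide study-shaped inputs with known assembly regimes so
every pipeline stage can be exercised end to end: a pure-birth (Yule) tree
rescaled to a fixed root age with tips partitioned into small genera
(runs of 1-5 tips in leaf order, labelled ``g<i>_s<j>``), and a
presence/absence landscape whose cells are assembled under one of four
scenarios:

random
    uniform richness-matched draws from the pool (the null itself);
filtering
    a seed tip is chosen and co-occupants sampled with weight
    exp(-d(i, seed) * strength * kappa), kappa = 5 / tree depth, giving
    clade-restricted (phylogenetically clustered) cells;
overdispersion
    greedy max-min-distance selection, each step taken greedily with
    probability ``strength`` (else uniformly), spacing taxa out;
age_gradient
    per-genus weight exp(gamma_c * AGE * 5 / max age) with gamma_c sweeping
    linearly from -strength to +strength across the cell index, so mean
    divergence time climbs from young to old along the landscape.

At ``strength = 0`` every scenario reduces exactly to ``random``.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .community_structure import patristic_distances
from .divergence_time import genus_crown_ages
from .errors import InputValidationError
from .io_formats import CommunityMatrix, DatedTree, GenusMap
from .nullmodels import substream

__all__ = [
    "ScenarioConfig",
    "simulate_yule_tree",
    "genus_map_from_labels",
    "simulate_landscape",
]

SCENARIOS = ("random", "filtering", "overdispersion", "age_gradient")


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str
    n_cells: int
    richness_min: int
    richness_max: int
    strength: float = 1.0
    seed: int = 1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise InputValidationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if not (1 <= self.richness_min <= self.richness_max):
            raise InputValidationError("need 1 <= richness_min <= richness_max")
        if self.n_cells < 1:
            raise InputValidationError("n_cells must be >= 1")
        if not (0.0 <= self.strength <= 1.0):
            raise InputValidationError("strength must be in [0, 1]")


def simulate_yule_tree(n_tips: int, seed: int, depth: float = 100.0) -> DatedTree:
    """Pure-birth tree with ``n_tips`` extant tips, rescaled to root age ``depth``.

    Tip labels encode a genus partition: consecutive runs of 1-5 tips (in
    leaf order) form genus ``g<i>`` with members ``g<i>_s<j>``, mirroring
    real floras' mix of small and monotypic genera.
    """
    if n_tips < 2:
        raise InputValidationError("need n_tips >= 2")
    if depth <= 0:
        raise InputValidationError("depth must be positive")
    rng = substream(seed, f"yule_{n_tips}", "tree")
    if n_tips == 2:
        # the pure-birth start state: a single cherry at the root
        tree = dendropy.Tree.get(
            data=f"(t1:{depth},t2:{depth});", schema="newick"
        )
    else:
        py_rng = _random.Random(int(rng.integers(0, 2**31 - 1)))
        tree = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_tips,
            rng=py_rng,
        )
    # Rescale edges so the maximum root-to-tip depth equals `depth`, then
    # snap each tip exactly onto age 0 by absorbing the simulator's float
    # error into the terminal edge.
    root = tree.seed_node
    root.edge.length = None
    dists = {root: 0.0}
    maxdepth = 0.0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        dists[node] = dists[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            maxdepth = max(maxdepth, dists[node])
    if maxdepth <= 0:
        raise InputValidationError("degenerate simulated tree")
    scale = depth / maxdepth
    for node in tree.preorder_node_iter():
        if node is not root and node.edge.length is not None:
            node.edge.length *= scale
    dists = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        dists[node] = dists[node.parent_node] + node.edge.length
        if node.is_leaf():
            node.edge.length += depth - dists[node]
            dists[node] = depth

    # Genus partition over leaves in traversal order.
    leaves = list(tree.leaf_node_iter())
    sizes: list[int] = []
    remaining = len(leaves)
    while remaining > 0:
        s = int(rng.integers(1, 6))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    tree.taxon_namespace = dendropy.TaxonNamespace()
    pos = 0
    for gi, size in enumerate(sizes, start=1):
        for sj in range(1, size + 1):
            label = f"g{gi}_s{sj}"
            taxon = tree.taxon_namespace.new_taxon(label=label)
            leaves[pos].taxon = taxon
            pos += 1
    return DatedTree(tree)


def genus_map_from_labels(tree: DatedTree) -> GenusMap:
    """Recover the genus partition encoded in ``g<i>_s<j>`` tip labels."""
    mapping = {}
    for label in tree.tip_labels:
        genus = label.split("_")[0]
        if not genus:
            raise InputValidationError(f"tip label {label!r} encodes no genus")
        mapping[label] = genus
    return GenusMap(mapping)


def _weighted_subset(
    rng: np.random.Generator, n: int, k: int, weights: np.ndarray
) -> np.ndarray:
    p = weights / weights.sum()
    return rng.choice(n, size=k, replace=False, p=p, shuffle=False)


def simulate_landscape(
    tree: DatedTree, config: ScenarioConfig
) -> tuple[CommunityMatrix, GenusMap]:
    """Assemble ``n_cells`` presence/absence cells from the tree's tips."""
    pool = sorted(tree.tip_labels)
    n = len(pool)
    if config.richness_max > n:
        raise InputValidationError("richness_max exceeds the number of tips")
    genus_map = genus_map_from_labels(tree)
    rng = substream(config.seed, f"landscape_{config.scenario}", "landscape")

    dist = None
    tip_age_weight_base = None
    if config.scenario in ("filtering", "overdispersion"):
        full = patristic_distances(tree)
        idx = full.index_of(pool)
        dist = full.matrix[np.ix_(idx, idx)]
    if config.scenario == "age_gradient":
        ages = genus_crown_ages(tree, genus_map)
        tip_ages = np.array([ages.age(genus_map.genus(t)) for t in pool])
        max_age = tip_ages.max()
        tip_age_weight_base = tip_ages * (5.0 / max_age) if max_age > 0 else tip_ages

    strength = config.strength
    kappa = 5.0 / tree.depth
    occupancy = np.zeros((config.n_cells, n), dtype=np.int8)
    for ci in range(config.n_cells):
        k = int(rng.integers(config.richness_min, config.richness_max + 1))
        if config.scenario == "random" or strength == 0.0:
            chosen = rng.choice(n, size=k, replace=False, shuffle=False)
        elif config.scenario == "filtering":
            seed_tip = int(rng.integers(0, n))
            w = np.exp(-dist[seed_tip] * strength * kappa)
            chosen = _weighted_subset(rng, n, k, w)
        elif config.scenario == "overdispersion":
            chosen_list = [int(rng.integers(0, n))]
            remaining = set(range(n)) - set(chosen_list)
            while len(chosen_list) < k:
                cand = np.array(sorted(remaining), dtype=np.intp)
                if rng.random() < strength:
                    mins = dist[np.ix_(cand, np.array(chosen_list, dtype=np.intp))].min(axis=1)
                    pick = int(cand[int(np.argmax(mins))])
                else:
                    pick = int(cand[int(rng.integers(0, len(cand)))])
                chosen_list.append(pick)
                remaining.discard(pick)
            chosen = np.array(chosen_list, dtype=np.intp)
        else:  # age_gradient
            if config.n_cells > 1:
                gamma = -strength + 2.0 * strength * ci / (config.n_cells - 1)
            else:
                gamma = 0.0
            w = np.exp(gamma * tip_age_weight_base)
            chosen = _weighted_subset(rng, n, k, w)
        occupancy[ci, chosen] = 1

    width = len(str(config.n_cells - 1))
    cells = tuple(f"cell_{i:0{width}d}" for i in range(config.n_cells))
    matrix = CommunityMatrix(cells=cells, species=tuple(pool), occupancy=occupancy)
    return matrix, genus_map
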