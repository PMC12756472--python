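"""Readers, writers and validation for the three external inputs.

The package consumes (a) a dated, near-ultrametric phylogeny in Newick
format with branch lengths in Ma, (b) a grid-cell x species presence/absence
matrix in CSV, and (c) a two-column species->genus map.  All three readers
enforce a fixed, deterministic dialect (UTF-8, comma delimiter, no quoting)
so that read -> write -> read round trips are bit-stable.
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    InputValidationError,
    MatrixFormatError,
    NewickFormatError,
    UndefinedResultError,
)

ULTRAMETRIC_RTOL = 1e-6

__all__ = [
    "DatedTree",
    "CommunityMatrix",
    "GenusMap",
    "ValidationReport",
    "read_newick",
    "read_community_matrix",
    "read_genus_map",
    "validate",
    "write_cell_reports",
    "read_cell_reports",
    "CELL_REPORT_COLUMNS",
]


class DatedTree:
    """A rooted tree with branch lengths in Ma and node ages derived from them.

    Tips sit at age 0; the age of an internal node is the maximum path
    length from the node down to any descendant tip, so ages are robust to
    the small rounding deviations typical of mega-tree-derived phylogenies.
    A deviation from ultrametricity beyond a relative tolerance of 1e-6
    raises a warning, never an error.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True
        self._validate_structure()
        self._index()

    # -- construction helpers -------------------------------------------------

    def _validate_structure(self) -> None:
        root = self._tree.seed_node
        labels = []
        for leaf in self._tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if not label:
                raise InputValidationError("tree has a tip with an empty label")
            labels.append(label)
        dup = {l for l in labels if labels.count(l) > 1}
        if dup:
            raise InputValidationError(f"duplicate tip label(s): {sorted(dup)}")
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise NewickFormatError(
                    "missing branch length on a non-root edge "
                    f"(node {node.taxon.label if node.taxon else '<internal>'})"
                )
            if node.edge.length < 0:
                raise InputValidationError("negative branch length")

    def _index(self) -> None:
        # Node heights: leaf height 0, internal = max(child height + edge).
        self._height: dict[dendropy.Node, float] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                self._height[node] = 0.0
            else:
                self._height[node] = max(
                    self._height[c] + (c.edge.length or 0.0)
                    for c in node.child_nodes()
                )
        root = self._tree.seed_node
        self._depth_from_root: dict[dendropy.Node, float] = {root: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            self._depth_from_root[node] = (
                self._depth_from_root[node.parent_node] + node.edge.length
            )

        self._leaves = list(self._tree.leaf_node_iter())
        self.tip_labels: list[str] = [
            (l.taxon.label if l.taxon is not None else l.label) for l in self._leaves
        ]
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        self._leaf_by_label = dict(zip(self.tip_labels, self._leaves))

        self.depth: float = self._height[root]
        tip_depths = np.array(
            [self._depth_from_root[l] for l in self._leaves], dtype=float
        )
        self.ultrametric_deviation: float = (
            float(np.max(np.abs(tip_depths - self.depth)) / self.depth)
            if self.depth > 0
            else 0.0
        )
        if self.ultrametric_deviation > ULTRAMETRIC_RTOL:
            warnings.warn(
                "tree is not ultrametric (max relative tip-depth deviation "
                f"{self.ultrametric_deviation:.3g}); node ages use max tip depth",
                stacklevel=3,
            )

        # Edge table over non-root nodes; the root's own edge (if any) is
        # ignored everywhere, matching the usual Faith-PD convention.
        self._edge_nodes = [
            n for n in self._tree.preorder_node_iter() if n is not root
        ]
        self._edge_index = {n: i for i, n in enumerate(self._edge_nodes)}
        self.branch_lengths: np.ndarray = np.array(
            [n.edge.length for n in self._edge_nodes], dtype=float
        )
        self._path_matrix: np.ndarray | None = None

    # -- public surface -------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise InputValidationError(f"unknown tip label: {label!r}") from None

    def node_age(self, node: dendropy.Node) -> float:
        return self._height[node]

    def mrca_age(self, labels: Iterable[str]) -> float:
        """Age (Ma) of the most recent common ancestor of the given tips."""
        labels = list(labels)
        if not labels:
            raise UndefinedResultError("MRCA of an empty tip set is undefined")
        for lab in labels:
            self.tip_index(lab)
        if len(labels) == 1:
            return 0.0
        mrca = self._tree.mrca(taxa=[self._leaf_by_label[l].taxon for l in labels])
        return self._height[mrca]

    def stem_age(self, label: str) -> float:
        """Age of the node where the tip's edge attaches (its parent)."""
        leaf = self._leaf_by_label.get(label)
        if leaf is None:
            raise InputValidationError(f"unknown tip label: {label!r}")
        parent = leaf.parent_node
        if parent is None:  # single-tip tree
            return self._height[leaf]
        return self._height[parent]

    def path_matrix(self) -> np.ndarray:
        """Boolean (n_tips x n_edges) incidence of tip-to-root paths.

        Row i marks every edge on the path from tip i up to (and excluding)
        the root; PD of a tip set is ``branch_lengths @ (rows OR-ed)``.
        """
        if self._path_matrix is None:
            mat = np.zeros((self.n_tips, len(self._edge_nodes)), dtype=bool)
            for i, leaf in enumerate(self._leaves):
                node = leaf
                while node.parent_node is not None:
                    mat[i, self._edge_index[node]] = True
                    node = node.parent_node
            self._path_matrix = mat
        return self._path_matrix

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.as_newick() + "\n")


@dataclass(frozen=True)
class CommunityMatrix:
    """Grid-cell x species presence/absence table (binary occupancy)."""

    cells: tuple[str, ...]
    species: tuple[str, ...]
    occupancy: np.ndarray  # (n_cells, n_species) int8 in {0,1}

    def __post_init__(self):
        if len(set(self.cells)) != len(self.cells):
            raise InputValidationError("duplicate cell ids")
        if len(set(self.species)) != len(self.species):
            raise InputValidationError("duplicate species names")
        occ = np.asarray(self.occupancy, dtype=np.int8)
        if occ.shape != (len(self.cells), len(self.species)):
            raise InputValidationError("occupancy shape mismatch")
        if not np.isin(occ, (0, 1)).all():
            raise InputValidationError("occupancy entries must be 0/1")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def richness(self) -> pd.Series:
        return pd.Series(self.occupancy.sum(axis=1), index=list(self.cells), name="SR")

    def cell_species(self, cell: str) -> list[str]:
        i = self.cells.index(cell)
        return [s for s, v in zip(self.species, self.occupancy[i]) if v]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy, index=list(self.cells), columns=list(self.species)
        )

    def restrict_species(self, keep: Sequence[str]) -> "CommunityMatrix":
        """Drop all species not in ``keep``; cells may become empty."""
        keep_set = set(keep)
        cols = [j for j, s in enumerate(self.species) if s in keep_set]
        return CommunityMatrix(
            cells=self.cells,
            species=tuple(self.species[j] for j in cols),
            occupancy=self.occupancy[:, cols],
        )

    def drop_empty_cells(self) -> "CommunityMatrix":
        rows = np.flatnonzero(self.occupancy.sum(axis=1) > 0)
        return CommunityMatrix(
            cells=tuple(self.cells[i] for i in rows),
            species=self.species,
            occupancy=self.occupancy[rows],
        )

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("cell," + ",".join(self.species) + "\n")
            for cell, row in zip(self.cells, self.occupancy):
                fh.write(cell + "," + ",".join(str(int(v)) for v in row) + "\n")


@dataclass(frozen=True)
class GenusMap:
    """Total mapping species name -> genus name."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        for sp, gen in self.mapping.items():
            if not gen:
                raise InputValidationError(f"empty genus for species {sp!r}")

    def genus(self, species: str) -> str:
        return self.mapping[species]

    def genera(self) -> set[str]:
        return set(self.mapping.values())

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("species,genus\n")
            for sp in self.mapping:
                fh.write(f"{sp},{self.mapping[sp]}\n")


@dataclass(frozen=True)
class ValidationReport:
    """Cross-input concordance report; purely descriptive, no side effects."""

    missing_from_tree: tuple[str, ...]
    tree_only_tips: tuple[str, ...]
    cells_emptied: tuple[str, ...]
    species_without_genus: tuple[str, ...] = ()
    ultrametric_deviation: float = 0.0

    @property
    def concordant(self) -> bool:
        return not (
            self.missing_from_tree or self.cells_emptied or self.species_without_genus
        )


# ---------------------------------------------------------------------------
# readers


def read_newick(path) -> DatedTree:
    """Parse a single dated Newick tree with mandatory branch lengths."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return parse_newick(text)


def parse_newick(text: str) -> DatedTree:
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickFormatError(
            f"missing terminating ';' (byte offset {len(text.rstrip())})"
        )
    depth = 0
    for offset, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickFormatError(
                    f"unbalanced ')' at byte offset {offset}"
                )
    if depth != 0:
        raise NewickFormatError(
            f"unbalanced parentheses ({depth} unclosed '(') at byte offset "
            f"{len(stripped)}"
        )
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon" in str(exc):
            raise InputValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickFormatError(f"Newick parse failure: {exc}") from exc
    return DatedTree(tree)


def _read_strict_csv(path) -> list[list[str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        raw = fh.read()
    if '"' in raw:
        raise MatrixFormatError(
            "quoted fields are not supported; names must not contain commas"
        )
    reader = csv.reader(io.StringIO(raw), delimiter=",", quoting=csv.QUOTE_NONE)
    return [row for row in reader if row]


def read_community_matrix(path) -> CommunityMatrix:
    """Read a presence/absence CSV: first column cell id, header = species.

    Body entries must be 0, 1 or empty (empty = absence); anything else is
    rejected with the offending (row, column) coordinates.
    """
    rows = _read_strict_csv(path)
    if len(rows) < 2:
        raise MatrixFormatError("matrix must have a header and at least one cell row")
    header = rows[0]
    species = [h.strip() for h in header[1:]]
    if any(not s for s in species):
        raise MatrixFormatError("empty species name in header")
    if len(set(species)) != len(species):
        raise InputValidationError("duplicate species names in header")
    cells: list[str] = []
    occ = np.zeros((len(rows) - 1, len(species)), dtype=np.int8)
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise MatrixFormatError(
                f"row {r + 1} has {len(row)} fields, expected {len(header)}"
            )
        cells.append(row[0].strip())
        for c, entry in enumerate(row[1:]):
            entry = entry.strip()
            if entry in ("", "0"):
                continue
            if entry == "1":
                occ[r - 1, c] = 1
            else:
                raise InputValidationError(
                    f"non-binary entry {entry!r} at row {r + 1}, "
                    f"column {c + 2} (cell {row[0]!r}, species {species[c]!r})"
                )
    if len(set(cells)) != len(cells):
        raise InputValidationError("duplicate cell ids")
    return CommunityMatrix(tuple(cells), tuple(species), occ)


def read_genus_map(path) -> GenusMap:
    """Read the two-column ``species,genus`` CSV (exact header required)."""
    rows = _read_strict_csv(path)
    if not rows or [h.strip() for h in rows[0]] != ["species", "genus"]:
        raise MatrixFormatError("genus map must start with header 'species,genus'")
    mapping: dict[str, str] = {}
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise MatrixFormatError(f"genus map row {r} must have 2 fields")
        sp, gen = row[0].strip(), row[1].strip()
        if sp in mapping:
            raise InputValidationError(f"duplicate species {sp!r} in genus map")
        mapping[sp] = gen
    return GenusMap(mapping)


def validate(
    matrix: CommunityMatrix, tree: DatedTree, genus_map: GenusMap | None = None
) -> ValidationReport:
    """Cross-check matrix species against tree tips (and the genus map)."""
    matrix_sp = set(matrix.species)
    tree_sp = set(tree.tip_labels)
    missing = sorted(matrix_sp - tree_sp)
    tree_only = sorted(tree_sp - matrix_sp)
    matched = matrix_sp & tree_sp
    emptied = []
    for i, cell in enumerate(matrix.cells):
        present = {s for s, v in zip(matrix.species, matrix.occupancy[i]) if v}
        if present and not (present & matched):
            emptied.append(cell)
    no_genus = ()
    if genus_map is not None:
        no_genus = tuple(sorted(matched - set(genus_map.mapping)))
    return ValidationReport(
        missing_from_tree=tuple(missing),
        tree_only_tips=tuple(tree_only),
        cells_emptied=tuple(emptied),
        species_without_genus=no_genus,
        ultrametric_deviation=tree.ultrametric_deviation,
    )


# ---------------------------------------------------------------------------
# result tables

CELL_REPORT_COLUMNS = (
    "cell",
    "SR",
    "PD",
    "SES_PD",
    "MDT",
    "SES_MDT",
    "SES_young_quartile",
    "SES_old_quartile",
    "MPD",
    "MNTD",
    "NRI",
    "NTI",
    "classification",
)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, str):
        return value
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    v = float(value)
    if math.isnan(v):
        return "NA"
    return f"{v:.6g}"


def write_cell_reports(reports, path) -> None:
    """Write one CSV row per cell, fixed column order, floats at 6 sig. digits."""
    reports = list(reports)
    if not reports:
        raise InputValidationError("no cell reports to write")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(CELL_REPORT_COLUMNS) + "\n")
        for rep in reports:
            row = rep.as_row() if hasattr(rep, "as_row") else rep
            fh.write(",".join(_fmt(row[c]) for c in CELL_REPORT_COLUMNS) + "\n")


def read_cell_reports(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    missing = set(CELL_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise MatrixFormatError(f"cell-report CSV missing columns {sorted(missing)}")
    return df
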