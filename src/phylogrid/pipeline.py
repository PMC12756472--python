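"""End-to-end per-cell analysis: tree + matrix + genus map -> cell reports.

For every grid cell with at least one tree-matched species the pipeline
computes SR, Faith PD, SES-PD, MDT, SES-MDT (plus the young/old quartile
SES auxiliaries), MPD, MNTD, NRI, NTI and the sign-pair classification, all
under one user seed with per-(cell, metric) substreams so results are
independent of processing order.  A summary aggregates genus-age
distribution statistics, age-bin tallies, the SR-PD correlation, and the
per-category cell counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .community_structure import classify, mntd, mpd, patristic_distances, structure_ses
from .divergence_time import (
    GenusAgeTable,
    cell_genus_counts,
    genus_crown_ages,
    mdt,
    mdt_bias_label,
    mdt_ses_suite,
)
from .errors import InputValidationError, UndefinedResultError
from .io_formats import (
    CommunityMatrix,
    DatedTree,
    GenusMap,
    read_community_matrix,
    read_genus_map,
    read_newick,
    validate,
    write_cell_reports,
)
from .nullmodels import NullConfig, substream
from .phylodiversity import PDValue, faith_pd, ses_pd, sr_pd_correlation

__all__ = ["RunConfig", "CellReport", "run_analysis", "run_analysis_files", "age_bin_summary"]

logger = logging.getLogger("phylogrid")

DEFAULT_AGE_BIN_EDGES = (23.03, 66.00, 145.00)

_NAN = float("nan")


@dataclass(frozen=True)
class RunConfig:
    tree_path: str
    matrix_path: str
    genus_map_path: str
    null: NullConfig = field(default_factory=NullConfig)
    age_bin_edges: tuple[float, ...] = DEFAULT_AGE_BIN_EDGES
    out_dir: str | None = None

    def __post_init__(self):
        edges = tuple(float(e) for e in self.age_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])) or (edges and edges[0] <= 0):
            raise InputValidationError("age bin edges must be positive and increasing")
        object.__setattr__(self, "age_bin_edges", edges)


@dataclass(frozen=True)
class CellReport:
    cell: str
    sr: int
    pd: float
    ses_pd: float
    mdt: float
    ses_mdt: float
    ses_young_quartile: float
    ses_old_quartile: float
    mpd: float
    mntd: float
    nri: float
    nti: float
    classification: str
    mdt_bias: str = "none"
    interpretation: str = "random"
    ses_pd_significant: bool = False
    nri_significant: bool = False
    nti_significant: bool = False

    def as_row(self) -> dict:
        return {
            "cell": self.cell,
            "SR": self.sr,
            "PD": self.pd,
            "SES_PD": self.ses_pd,
            "MDT": self.mdt,
            "SES_MDT": self.ses_mdt,
            "SES_young_quartile": self.ses_young_quartile,
            "SES_old_quartile": self.ses_old_quartile,
            "MPD": self.mpd,
            "MNTD": self.mntd,
            "NRI": self.nri,
            "NTI": self.nti,
            "classification": self.classification,
        }


def age_bin_summary(ages: GenusAgeTable, edges: Sequence[float]) -> pd.DataFrame:
    """Genus counts and percentages per half-open age bin [e_k, e_{k+1}).

    Bins are lower-inclusive: [0, e1), [e1, e2), ..., [e_last, inf).
    """
    values = np.array([ages.ages[g] for g in ages.genera()], dtype=float)
    if values.size == 0:
        raise UndefinedResultError("empty genus age table")
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise InputValidationError("age bin edges must be strictly increasing")
    bounds = [0.0] + edges + [math.inf]
    rows = []
    for lo, hi in zip(bounds, bounds[1:]):
        count = int(((values >= lo) & (values < hi)).sum())
        label = f"[{lo:g}, {hi:g})" if math.isfinite(hi) else f">= {lo:g}"
        rows.append({"bin": label, "count": count})
    df = pd.DataFrame(rows)
    df["percentage"] = 100.0 * df["count"] / values.size
    return df


def _ses_value(result) -> float:
    return result.ses if result is not None else _NAN


def run_analysis(
    tree: DatedTree,
    matrix: CommunityMatrix,
    genus_map: GenusMap,
    null: NullConfig | None = None,
    age_bin_edges: Sequence[float] = DEFAULT_AGE_BIN_EDGES,
) -> tuple[list[CellReport], dict]:
    """Full per-cell analysis; returns (cell reports, summary dict)."""
    null = null or NullConfig()
    report = validate(matrix, tree, genus_map)
    if report.missing_from_tree:
        logger.warning(
            "%d species in the matrix are absent from the tree and were dropped",
            len(report.missing_from_tree),
        )
    if report.species_without_genus:
        raise InputValidationError(
            "species without genus mapping: "
            f"{list(report.species_without_genus)[:5]} ..."
        )
    matched = sorted(set(matrix.species) & set(tree.tip_labels))
    pruned = matrix.restrict_species(matched)
    emptied = [c for c, s in zip(pruned.cells, pruned.occupancy.sum(axis=1)) if s == 0]
    if emptied:
        logger.warning("%d cells emptied by pruning: %s", len(emptied), emptied)
    pruned = pruned.drop_empty_cells()
    if pruned.n_cells == 0:
        raise InputValidationError("no cells with tree-matched species remain")

    # Regional pools: species present anywhere in the matrix; their genera.
    present_anywhere = pruned.occupancy.any(axis=0)
    species_pool = sorted(
        s for s, p in zip(pruned.species, present_anywhere) if p
    )
    ages_all = genus_crown_ages(tree, genus_map)
    genus_pool = sorted({genus_map.genus(s) for s in species_pool})
    ages = GenusAgeTable(
        ages={g: ages_all.ages[g] for g in genus_pool},
        monotypic=frozenset(g for g in genus_pool if g in ages_all.monotypic),
    )
    dist = patristic_distances(tree)

    reports: list[CellReport] = []
    pd_values: list[PDValue] = []
    for cell in pruned.cells:
        taxa = pruned.cell_species(cell)
        sr = len(taxa)
        pd_obs = faith_pd(tree, taxa)
        pd_values.append(PDValue(cell, sr, pd_obs))

        ses_pd_res = ses_pd(
            taxa, species_pool, tree, null, rng=substream(null.seed, cell, "pd")
        )
        counts = cell_genus_counts(cell, taxa, genus_map)
        suite = mdt_ses_suite(
            counts, ages, null, rng=substream(null.seed, cell, "mdt")
        )
        if sr >= 2:
            nri_res, nti_res = structure_ses(
                taxa, species_pool, dist, null,
                rng=substream(null.seed, cell, "structure"),
            )
            cls = classify(nri_res, nti_res, cell)
            mpd_v, mntd_v = mpd(taxa, dist), mntd(taxa, dist)
            nri_v, nti_v = nri_res.ses, nti_res.ses
            category, interp = cls.category, cls.interpretation
            nri_sig, nti_sig = cls.nri_significant, cls.nti_significant
        else:
            mpd_v = mntd_v = nri_v = nti_v = _NAN
            category, interp = "undefined", "undefined"
            nri_sig = nti_sig = False

        reports.append(
            CellReport(
                cell=cell,
                sr=sr,
                pd=pd_obs,
                ses_pd=ses_pd_res.ses,
                mdt=suite.mdt.observed,
                ses_mdt=suite.mdt.ses,
                ses_young_quartile=suite.young_quartile.ses,
                ses_old_quartile=suite.old_quartile.ses,
                mpd=mpd_v,
                mntd=mntd_v,
                nri=nri_v,
                nti=nti_v,
                classification=category,
                mdt_bias=mdt_bias_label(suite.mdt),
                interpretation=interp,
                ses_pd_significant=ses_pd_res.significant,
                nri_significant=nri_sig,
                nti_significant=nti_sig,
            )
        )
        logger.info("cell=%s SR=%d PD=%.4g MDT=%.4g", cell, sr, pd_obs, suite.mdt.observed)

    summary = _summarize(reports, ages, pd_values, age_bin_edges)
    return reports, summary


def _count(reports, pred) -> int:
    return sum(1 for r in reports if pred(r))


def _summarize(reports, ages: GenusAgeTable, pd_values, age_bin_edges) -> dict:
    age_vals = np.array([ages.ages[g] for g in ages.genera()])
    bins = age_bin_summary(ages, age_bin_edges)
    try:
        r, p = sr_pd_correlation(pd_values)
        sr_pd = {"pearson_r": r, "p_value": p}
    except UndefinedResultError:
        sr_pd = {"pearson_r": None, "p_value": None}
    nn = lambda v: not math.isnan(v)  # noqa: E731
    summary = {
        "n_cells": len(reports),
        "genus_ages": {
            "n_genera": int(age_vals.size),
            "mean_Ma": float(age_vals.mean()),
            "sd_Ma": float(age_vals.std(ddof=1)) if age_vals.size > 1 else 0.0,
            "median_Ma": float(np.median(age_vals)),
        },
        "age_bins": bins.to_dict(orient="records"),
        "sr_pd": sr_pd,
        "ses_pd_counts": {
            "positive": _count(reports, lambda r: nn(r.ses_pd) and r.ses_pd >= 0),
            "negative": _count(reports, lambda r: nn(r.ses_pd) and r.ses_pd < 0),
            "significant_positive": _count(
                reports, lambda r: r.ses_pd_significant and r.ses_pd > 0
            ),
            "significant_negative": _count(
                reports, lambda r: r.ses_pd_significant and r.ses_pd < 0
            ),
        },
        "ses_mdt_counts": {
            "ancient_biased": _count(reports, lambda r: r.mdt_bias == "ancient-biased"),
            "young_biased": _count(reports, lambda r: r.mdt_bias == "young-biased"),
        },
        "structure_categories": {
            cat: _count(reports, lambda r, c=cat: r.classification == c)
            for cat in (
                "both_positive",
                "both_negative",
                "nri_pos_nti_neg",
                "nri_neg_nti_pos",
                "undefined",
            )
        },
        "interpretations": {
            lab: _count(reports, lambda r, l=lab: r.interpretation == l)
            for lab in (
                "habitat_filtering",
                "competitive_exclusion",
                "mixed",
                "random",
                "undefined",
            )
        },
    }
    return summary


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_analysis_files(config: RunConfig) -> tuple[list[CellReport], dict]:
    """Read the three inputs, run the analysis, and (optionally) write outputs.

    With ``config.out_dir`` set, writes ``cell_reports.csv``,
    ``summary.json`` and ``provenance.json`` (input checksums, config,
    package version) into that directory.
    """
    tree = read_newick(config.tree_path)
    matrix = read_community_matrix(config.matrix_path)
    genus_map = read_genus_map(config.genus_map_path)
    reports, summary = run_analysis(
        tree, matrix, genus_map, null=config.null, age_bin_edges=config.age_bin_edges
    )
    if config.out_dir is not None:
        import os

        os.makedirs(config.out_dir, exist_ok=True)
        write_cell_reports(reports, os.path.join(config.out_dir, "cell_reports.csv"))
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        provenance = {
            "version": __version__,
            "inputs": {
                "tree": {"path": config.tree_path, "sha256": _sha256(config.tree_path)},
                "matrix": {
                    "path": config.matrix_path,
                    "sha256": _sha256(config.matrix_path),
                },
                "genus_map": {
                    "path": config.genus_map_path,
                    "sha256": _sha256(config.genus_map_path),
                },
            },
            "null": {
                "n_reps": config.null.n_reps,
                "seed": config.null.seed,
                "significance_z": config.null.significance_z,
                "scheme": config.null.scheme,
            },
            "age_bin_edges": list(config.age_bin_edges),
        }
        with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2)
    return reports, summary
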