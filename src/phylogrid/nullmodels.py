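"""Shared null-model engine.

One null scheme is used throughout: richness-preserving uniform draws
without replacement from the regional pool ("pool_draw").  Every
standardized effect size (SES-MDT, SES-PD, and the MPD/MNTD standardization
behind NRI/NTI) is (observed - null mean) / null s.d. over ``n_reps``
replicate draws, with the sample (n-1) standard deviation.  |SES| > 1.96
(strict) flags significance at P < 0.05; a rank p-value is reported
alongside but never drives the 1.96 classification.

Reproducibility: a single user seed spawns one deterministic substream per
(cell, metric-group) keyed by a CRC32 of the cell id, so per-cell results do
not depend on the order cells are processed in, and removing a cell leaves
every other cell's numbers untouched.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import yaml

from .errors import InputValidationError

__all__ = [
    "NullConfig",
    "SESResult",
    "draw_null_assemblage",
    "null_index_batches",
    "summarize_ses",
    "standardized_effect",
    "substream",
]

DEFAULT_N_REPS = 999
DEFAULT_SIGNIFICANCE_Z = 1.96

# Fixed metric-group ids so substreams are stable across versions.
_STREAM_IDS = {"mdt": 0, "pd": 1, "structure": 2, "landscape": 3, "tree": 4}

_BATCH = 2048  # replicate draws are generated in chunks of this size


@dataclass(frozen=True)
class NullConfig:
    """Null-model settings: replicate count, seed, significance threshold."""

    n_reps: int = DEFAULT_N_REPS
    seed: int = 1
    significance_z: float = DEFAULT_SIGNIFICANCE_Z
    scheme: str = "pool_draw"

    def __post_init__(self):
        if self.n_reps < 1:
            raise InputValidationError("n_reps must be >= 1")
        if self.scheme != "pool_draw":
            raise InputValidationError(f"unknown null scheme {self.scheme!r}")

    @classmethod
    def from_yaml(cls, path) -> "NullConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"n_reps", "seed", "significance_z", "scheme"}
        unknown = set(raw) - known
        if unknown:
            raise InputValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class SESResult:
    """Observed value standardized against a null distribution.

    ``ses = sign * (observed - null_mean) / null_sd`` with ``sign = +1`` for
    SES-PD / SES-MDT and ``sign = -1`` for NRI / NTI (which negate the raw
    standardization so that positive means phylogenetic clustering).
    A zero-variance null (e.g. cell richness equals pool size) yields
    ``ses = nan`` with ``significant = False`` rather than +/-infinity.
    """

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_rank: float
    n_reps: int
    significant: bool
    direction: str  # "high" | "low" | "none"
    sign: int = 1

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ses)


def substream(seed: int, cell_id: str, group: str) -> np.random.Generator:
    """Deterministic per-(cell, metric-group) random generator."""
    key = zlib.crc32(cell_id.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM_IDS[group], key))
    return np.random.default_rng(ss)


def draw_null_assemblage(
    pool: Sequence[str], richness: int, rng: np.random.Generator
) -> set[str]:
    """Uniform subset of ``richness`` taxa drawn without replacement.

    The pool is sorted internally, so results are invariant to its ordering.
    """
    pool_sorted = sorted(pool)
    n = len(pool_sorted)
    if richness <= 0:
        raise InputValidationError("richness must be positive")
    if richness > n:
        raise InputValidationError(f"richness {richness} exceeds pool size {n}")
    idx = rng.choice(n, size=richness, replace=False)
    return {pool_sorted[i] for i in idx}


def null_index_batches(
    pool_size: int, richness: int, n_reps: int, rng: np.random.Generator
) -> Iterator[np.ndarray]:
    """Yield (chunk, richness) index matrices of uniform subsets of the pool.

    Uses the random-key argsort trick so each row is an independent uniform
    subset without replacement; chunked to bound memory at large n_reps.
    """
    if richness <= 0 or richness > pool_size:
        raise InputValidationError(
            f"richness {richness} invalid for pool of size {pool_size}"
        )
    done = 0
    while done < n_reps:
        m = min(_BATCH, n_reps - done)
        keys = rng.random((m, pool_size))
        yield np.argpartition(keys, richness - 1, axis=1)[:, :richness]
        done += m


def summarize_ses(
    observed: float,
    null_values: np.ndarray,
    significance_z: float = DEFAULT_SIGNIFICANCE_Z,
    sign: int = 1,
) -> SESResult:
    """Build an SESResult from a vector of replicate null values."""
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1)) if n > 1 else 0.0
    # A null whose spread is pure floating-point noise (all replicates are
    # the same assemblage, e.g. richness == pool size) counts as degenerate.
    if sd <= 1e-12 * max(1.0, abs(mean)):
        sd = float(sd)
        degenerate = True
    else:
        degenerate = False
    if not degenerate:
        ses = sign * (observed - mean) / sd
    else:
        ses = float("nan")
    # Rank p on the reported scale: upper tail when the reported value is
    # non-negative, lower tail otherwise.
    o_rep = sign * observed
    n_rep = sign * null_values
    if math.isnan(ses) or ses >= 0:
        r = int((n_rep >= o_rep).sum())
    else:
        r = int((n_rep <= o_rep).sum())
    p_rank = (r + 1) / (n + 1)
    if math.isnan(ses):
        significant, direction = False, "none"
    elif ses > significance_z:
        significant, direction = True, "high"
    elif ses < -significance_z:
        significant, direction = True, "low"
    else:
        significant, direction = False, "none"
    return SESResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=float(ses),
        p_rank=float(p_rank),
        n_reps=int(n),
        significant=significant,
        direction=direction,
        sign=int(sign),
    )


def standardized_effect(
    observed: float,
    statistic: Callable[[frozenset[str]], float],
    pool: Sequence[str],
    richness: int,
    config: NullConfig,
    rng: np.random.Generator | None = None,
    sign: int = 1,
) -> SESResult:
    """Generic SES of ``observed`` against pool-draw replicates of ``statistic``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool_sorted = sorted(pool)
    pool_arr = np.array(pool_sorted, dtype=object)
    nulls = np.empty(config.n_reps, dtype=float)
    pos = 0
    for idx in null_index_batches(len(pool_sorted), richness, config.n_reps, rng):
        for row in idx:
            nulls[pos] = statistic(frozenset(pool_arr[row]))
            pos += 1
    return summarize_ses(observed, nulls, config.significance_z, sign=sign)
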