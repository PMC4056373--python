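"""Plate normalization and interaction residuals.

Raw colony sizes are normalized per plate by the plate mode — the location
of the maximum of a Gaussian kernel density estimate over the plate's sizes,
which is robust to dead colonies and strong interactions in a way the plate
mean is not. Array single-mutant fitnesses are then estimated as the median
normalized size of each array position across all plates, and subtracted to
yield interaction residuals epsilon. Because each plate carries a single
query, plate-mode division absorbs the plate growth constant and the query
fitness jointly; no separate query-fitness estimate is made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from dgi.io import ColonyTable

logger = logging.getLogger("dgi")

__all__ = [
    "NormalizationModel",
    "RESIDUAL_COLUMNS",
    "filter_colonies",
    "estimate_plate_mode",
    "normalize_plates",
    "compute_residuals",
    "residuals_pipeline",
]

#: Columns of the long-format residual table.
RESIDUAL_COLUMNS = ("query_id", "array_id", "replicate", "condition", "residual")

KDE_GRID_POINTS = 512
MIN_PLATE_OBS = 10


@dataclass
class NormalizationModel:
    """Fitted normalization quantities: plate modes, target scale, array fitnesses."""

    plate_mode: dict = field(default_factory=dict)  # plate_id -> mode (raw units)
    target_scale: float = float("nan")  # common post-normalization scale
    array_fitness: dict = field(default_factory=dict)  # array_id -> median size


def filter_colonies(table: ColonyTable, min_size: float, max_size: float) -> ColonyTable:
    """Drop missing measurements and sizes outside ``[min_size, max_size]``."""
    if not min_size < max_size:
        raise ValueError("min_size must be < max_size")
    sizes = table.data["raw_size"]
    keep = sizes.notna() & (sizes >= min_size) & (sizes <= max_size)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_colonies: dropped %d of %d measurements", dropped, len(table))
    return ColonyTable(table.data.loc[keep].reset_index(drop=True))


def estimate_plate_mode(values) -> float:
    """Mode of a Gaussian-KDE fit to *values*.

    Silverman's rule-of-thumb bandwidth; the mode is the argmax of the
    density on a 512-point grid spanning the data range. A degenerate
    (zero-spread) sample returns its common value directly.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < MIN_PLATE_OBS:
        raise ValueError(
            f"plate-mode estimation needs >= {MIN_PLATE_OBS} values, got {vals.size}"
        )
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return float(lo)
    kde = gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(lo, hi, KDE_GRID_POINTS)
    return float(grid[np.argmax(kde(grid))])


def normalize_plates(table: ColonyTable, target_scale: float | None = None):
    """Normalize each plate to a common scale by its KDE mode.

    ``size' = raw_size * target_scale / plate_mode``; by default
    ``target_scale`` is the median of the plate modes, so typical colonies
    keep their raw magnitude. Plates with a non-positive mode are dropped
    with a warning. Returns ``(normalized ColonyTable, NormalizationModel)``.
    """
    df = table.data
    modes = {
        plate: estimate_plate_mode(grp["raw_size"].to_numpy())
        for plate, grp in df.groupby("plate_id", sort=True)
    }
    bad = [p for p, m in modes.items() if not m > 0]
    for p in bad:
        logger.warning("normalize_plates: dropping plate %r (non-positive mode)", p)
        del modes[p]
    if not modes:
        raise ValueError("no plate with a positive mode")
    if target_scale is None:
        target_scale = float(np.median(list(modes.values())))
    keep = df["plate_id"].isin(modes)
    out = df.loc[keep].copy()
    out["raw_size"] = out["raw_size"] * target_scale / out["plate_id"].map(modes)
    model = NormalizationModel(plate_mode=modes, target_scale=target_scale)
    return ColonyTable(out.reset_index(drop=True)), model


def compute_residuals(
    normalized: ColonyTable,
    min_obs: int = 6,
    per_condition: bool = False,
    model: NormalizationModel | None = None,
):
    """Subtract array-median fitness from normalized sizes.

    The array fitness is the median normalized size of each array gene over
    all plates (queries, replicates and conditions pooled; set
    ``per_condition`` to estimate it within each condition instead). Arrays
    observed fewer than ``min_obs`` times are dropped. Returns a long-format
    residual DataFrame and the model with fitted array fitnesses.
    """
    if min_obs < 2:
        raise ValueError("min_obs must be >= 2")
    df = normalized.data.dropna(subset=["raw_size"]).copy()
    if model is None:
        model = NormalizationModel()
    group_cols = ["array_id", "condition"] if per_condition else ["array_id"]
    counts = df.groupby(group_cols)["raw_size"].transform("size")
    dropped = int((counts < min_obs).sum())
    if dropped:
        logger.info("compute_residuals: dropped %d rows on arrays with < %d obs",
                    dropped, min_obs)
    df = df.loc[counts >= min_obs]
    medians = df.groupby(group_cols)["raw_size"].transform("median")
    df["residual"] = df["raw_size"] - medians
    fit = df.groupby(group_cols)["raw_size"].median()
    model.array_fitness = {k: float(v) for k, v in fit.items()}
    residuals = df.loc[:, list(RESIDUAL_COLUMNS)].reset_index(drop=True)
    return residuals, model


def residuals_pipeline(
    table: ColonyTable,
    min_size: float = 1.0,
    max_size: float | None = None,
    min_obs: int = 6,
    per_condition: bool = False,
):
    """Filter -> plate-normalize -> residuals, the standard preprocessing chain.

    When ``max_size`` is None an upper bound of 10x the typical colony size
    (median of per-plate medians) is used.
    """
    if max_size is None:
        plate_medians = table.data.groupby("plate_id")["raw_size"].median()
        max_size = 10.0 * float(plate_medians.median())
    filtered = filter_colonies(table, min_size, max_size)
    normalized, model = normalize_plates(filtered)
    return compute_residuals(normalized, min_obs=min_obs,
                             per_condition=per_condition, model=model)
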