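"""Paired differentials and the dS / S interaction scores.

The dS score quantifies a *differential* genetic interaction between a
query and an array gene across two growth conditions. For each pipeline
replicate the treated residual minus the untreated residual gives a paired
differential delta; under the no-differential-interaction null the deltas
have mean zero, and shared pipeline noise cancels in the subtraction. Two
variants are provided:

``one_sample``
    The paired t-statistic ``mean(delta) / (sd(delta) / sqrt(n))``.

``pooled`` (default)
    A two-sample pooled-variance t-statistic of the pair's deltas against
    all deltas sharing the same array gene (the pair's own deltas
    excluded), which anchors the comparison in the array-wide behaviour.

Neither variant bounds or moderates the sample variance. The static S-style
score retains a minimum variance bound (the median per-pair sd), applied to
single-condition residuals, and serves as the static comparator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dgi.io import ScoreMatrix

logger = logging.getLogger("dgi")

__all__ = ["PairSummary", "compute_differentials", "ds_score", "s_score"]

DIFFERENTIAL_COLUMNS = ("query_id", "array_id", "replicate", "delta")


@dataclass(frozen=True)
class PairSummary:
    """Per-(query, array) scoring summary.

    ``n`` counts the deltas (or residuals) used; ``sd_diff`` is the sample
    (n-1) standard deviation. ``degenerate`` marks pairs with zero spread
    but nonzero mean, whose t-statistic is undefined; their score is NaN.
    """

    query_id: str
    array_id: str
    n: int
    mean_diff: float
    sd_diff: float
    score: float
    degenerate: bool = False


def compute_differentials(
    residuals: pd.DataFrame, treatment: str, reference: str
) -> pd.DataFrame:
    """Paired across-condition differences of residuals.

    ``delta = residual[treatment] - residual[reference]`` matched on
    (query, array, replicate); unpaired measurements are dropped with a
    logged count.
    """
    present = set(residuals["condition"].unique())
    for label in (treatment, reference):
        if label not in present:
            raise ValueError(f"condition {label!r} not present in residual table")
    key = ["query_id", "array_id", "replicate"]
    t = residuals.loc[residuals["condition"] == treatment, key + ["residual"]]
    r = residuals.loc[residuals["condition"] == reference, key + ["residual"]]
    merged = t.merge(r, on=key, how="outer", suffixes=("_t", "_r"))
    paired = merged.dropna(subset=["residual_t", "residual_r"])
    unpaired = len(merged) - len(paired)
    if unpaired:
        logger.info("compute_differentials: dropped %d unpaired measurements", unpaired)
    out = paired[key].copy()
    out["delta"] = paired["residual_t"].to_numpy() - paired["residual_r"].to_numpy()
    return out.reset_index(drop=True)


def _one_sample_t(x: np.ndarray) -> tuple[float, bool]:
    n = x.size
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0.0:
        if m == 0.0:
            return 0.0, False
        return math.nan, True
    return m / (s / math.sqrt(n)), False


def _pooled_t(x: np.ndarray, y: np.ndarray, sd_floor: float = 0.0) -> tuple[float, bool]:
    """Two-sample pooled-variance t of x vs y; x's sd optionally floored."""
    n1, n2 = x.size, y.size
    m1, m2 = float(x.mean()), float(y.mean())
    s1 = max(float(x.std(ddof=1)), sd_floor)
    s2 = float(y.std(ddof=1))
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if m1 == m2:
            return 0.0, False
        return math.nan, True
    return (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)), False


def _assemble_matrix(summaries: list[PairSummary], kind: str) -> ScoreMatrix:
    df = pd.DataFrame(
        {
            "query_id": [s.query_id for s in summaries],
            "array_id": [s.array_id for s in summaries],
            "score": [s.score for s in summaries],
        }
    )
    mat = df.pivot(index="query_id", columns="array_id", values="score")
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = None
    mat.columns.name = None
    return ScoreMatrix(mat, kind=kind)


def ds_score(
    diffs: pd.DataFrame, mode: str = "pooled", min_reps: int = 2
) -> tuple[ScoreMatrix, list[PairSummary]]:
    """Score paired differentials into a queries x arrays dS matrix.

    Pairs with fewer than ``min_reps`` deltas are skipped. In ``pooled``
    mode a pair also needs at least 2 comparison deltas on its array. No
    variance floor is applied.
    """
    if mode not in ("one_sample", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    summaries: list[PairSummary] = []
    low_n = 0
    for array_id, grp in diffs.groupby("array_id", sort=True):
        values = grp["delta"].to_numpy(dtype=float)
        codes, uniques = pd.factorize(grp["query_id"], sort=True)
        for qi, query_id in enumerate(uniques):
            mask = codes == qi
            x = values[mask]
            n = x.size
            if n < min_reps:
                logger.info("ds_score: skipping (%s, %s), n=%d < %d",
                            query_id, array_id, n, min_reps)
                continue
            if n < 4:
                low_n += 1
            mean = float(x.mean())
            sd = float(x.std(ddof=1))
            if mode == "one_sample":
                score, degenerate = _one_sample_t(x)
            else:
                y = values[~mask]
                if y.size < 2:
                    logger.info(
                        "ds_score: skipping (%s, %s), comparison group too small",
                        query_id, array_id)
                    continue
                score, degenerate = _pooled_t(x, y)
            summaries.append(
                PairSummary(str(query_id), str(array_id), n, mean, sd, score, degenerate)
            )
    if low_n:
        logger.warning("ds_score: %d pairs scored with n < 4 replicates "
                       "(t-statistics unstable)", low_n)
    return _assemble_matrix(summaries, kind="dS"), summaries


def s_score(
    residuals: pd.DataFrame, condition: str, min_reps: int = 2
) -> tuple[ScoreMatrix, list[PairSummary]]:
    """Static S-style score of single-condition residuals.

    Pooled two-sample t of the pair's residuals against all residuals
    sharing the array gene, with the pair's sd floored at the dataset-wide
    median per-pair sd.
    """
    sub = residuals.loc[residuals["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present in residual table")
    per_pair_sd = (
        sub.groupby(["query_id", "array_id"])["residual"]
        .agg(["size", lambda v: v.std(ddof=1)])
        .rename(columns={"size": "n", "<lambda_0>": "sd"})
    )
    eligible = per_pair_sd.loc[per_pair_sd["n"] >= 2, "sd"].dropna()
    sd_floor = float(eligible.median()) if len(eligible) else 0.0

    summaries: list[PairSummary] = []
    for array_id, grp in sub.groupby("array_id", sort=True):
        values = grp["residual"].to_numpy(dtype=float)
        codes, uniques = pd.factorize(grp["query_id"], sort=True)
        for qi, query_id in enumerate(uniques):
            mask = codes == qi
            x = values[mask]
            if x.size < min_reps:
                continue
            y = values[~mask]
            if y.size < 2:
                continue
            score, degenerate = _pooled_t(x, y, sd_floor=sd_floor)
            summaries.append(
                PairSummary(
                    str(query_id), str(array_id), int(x.size),
                    float(x.mean()), float(x.std(ddof=1)), score, degenerate,
                )
            )
    return _assemble_matrix(summaries, kind="S"), summaries
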