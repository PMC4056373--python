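"""Interaction-profile similarity and related comparisons.

A gene's interaction profile is its vector of scores against all partners;
the Pearson correlation of two profiles (over mutually observed partners)
measures functional similarity. Differential-profile similarity computed on
dS scores can reveal treatment-specific functional links invisible to
static profiles; the association filter below selects exactly those pairs
(high differential similarity, low static similarity in every condition).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from dgi.io import ScoreMatrix

logger = logging.getLogger("dgi")

__all__ = [
    "profile_similarity",
    "find_differential_associations",
    "bootstrap_correlation_comparison",
    "replicate_correlation_analysis",
]


def profile_similarity(
    scores: ScoreMatrix, axis: str = "query", min_overlap: int = 10
) -> ScoreMatrix:
    """Pairwise Pearson correlation of score profiles.

    ``axis='query'`` correlates row profiles (each query's scores across
    arrays); ``axis='array'`` correlates column profiles. Correlations use
    mutually non-missing entries only; pairs with overlap below
    ``min_overlap`` (or a zero-variance overlap) are missing.
    """
    if axis not in ("query", "array"):
        raise ValueError(f"axis must be 'query' or 'array', got {axis!r}")
    frame = scores.values.T if axis == "query" else scores.values
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 profiles to correlate")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = frame.corr(method="pearson", min_periods=min_overlap)
    n_missing = int(corr.isna().sum().sum())
    if n_missing:
        logger.warning(
            "profile_similarity: %d entries missing (overlap < %d or zero variance)",
            n_missing, min_overlap,
        )
    return ScoreMatrix(
        corr, kind="similarity",
        metadata={"source_kind": scores.kind, "axis": axis, "min_overlap": min_overlap},
    )


def find_differential_associations(
    diff_sim: ScoreMatrix,
    static_sims: list,
    diff_cutoff: float = 0.35,
    static_cutoff: float = 0.15,
    static_rule: str = "all",
) -> list[tuple[str, str]]:
    """Gene pairs with high differential but low static profile similarity.

    A pair qualifies when its differential similarity exceeds
    ``diff_cutoff`` and its static similarities fall below
    ``static_cutoff`` — in every supplied static matrix (``static_rule
    ='all'``, i.e. the max must be low) or in at least one (``'any'``).
    Pairs with any required entry missing are excluded.
    """
    if static_rule not in ("all", "any"):
        raise ValueError(f"static_rule must be 'all' or 'any', got {static_rule!r}")
    genes = list(diff_sim.values.index)
    for sm in static_sims:
        if list(sm.values.index) != genes:
            raise ValueError("similarity matrices do not share a gene universe")
    d = diff_sim.values.to_numpy()
    statics = np.stack([sm.values.to_numpy() for sm in static_sims])
    if static_rule == "all":
        static_ok = (statics < static_cutoff).all(axis=0)
    else:
        static_ok = (statics < static_cutoff).any(axis=0)
    defined = ~np.isnan(d) & ~np.isnan(statics).any(axis=0)
    hit = (d > diff_cutoff) & static_ok & defined
    out = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if hit[i, j]:
                out.append((genes[i], genes[j]))
    return sorted(out)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def bootstrap_correlation_comparison(x, y, n_boot: int = 10000, seed: int = 0) -> float:
    """Paired-bootstrap comparison of two correlation coefficients.

    ``x`` and ``y`` are (n, 2) arrays of paired scores over the same gene
    pairs (e.g. replicate-split halves of two scoring methods). Each
    iteration resamples gene pairs with replacement — the same indices for
    both methods — and compares the two correlations. Returns the one-sided
    p-value ``P[corr(x*) >= corr(y*)]`` with ties counted as 1/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("x and y must be (n, 2) arrays of equal shape")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    count = 0.0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cx = _pearson(x[idx, 0], x[idx, 1])
        cy = _pearson(y[idx, 0], y[idx, 1])
        if np.isnan(cx) or np.isnan(cy) or cx == cy:
            count += 0.5
        elif cx > cy:
            count += 1.0
    return count / n_boot


def replicate_correlation_analysis(
    residuals: pd.DataFrame, n_random: int = 200, seed: int = 0
) -> dict[str, np.ndarray]:
    """Correlation structure of residual profiles across the pipeline.

    Returns three labelled samples of Pearson correlations between residual
    profiles (vectors over array genes):

    - ``cross_condition``: same query and pipeline replicate, the two
      conditions — shared pipeline noise makes these the most correlated;
    - ``within_condition``: same query and condition, different replicates;
    - ``random_queries``: seeded random pairs of different queries.
    """
    conds = sorted(residuals["condition"].unique())
    reps = sorted(residuals["replicate"].unique())
    if len(conds) < 2 or len(reps) < 2:
        raise ValueError("need >= 2 conditions and >= 2 replicates")
    profiles = residuals.pivot_table(
        index=["query_id", "replicate", "condition"],
        columns="array_id", values="residual", aggfunc="first",
    )
    queries = sorted(residuals["query_id"].unique())

    def prof(q, i, c):
        try:
            return profiles.loc[(q, i, c)].to_numpy(dtype=float)
        except KeyError:
            return None

    cross, within = [], []
    for q in queries:
        for i in reps:
            a, b = prof(q, i, conds[0]), prof(q, i, conds[1])
            if a is not None and b is not None:
                r = _pearson(a, b)
                if not np.isnan(r):
                    cross.append(r)
        for c in conds:
            for ii in range(len(reps)):
                for jj in range(ii + 1, len(reps)):
                    a, b = prof(q, reps[ii], c), prof(q, reps[jj], c)
                    if a is not None and b is not None:
                        r = _pearson(a, b)
                        if not np.isnan(r):
                            within.append(r)

    rng = np.random.default_rng(seed)
    random_pairs = []
    keys = list(profiles.index)
    attempts = 0
    while len(random_pairs) < n_random and attempts < 20 * n_random:
        attempts += 1
        k1, k2 = rng.choice(len(keys), size=2, replace=False)
        if keys[k1][0] == keys[k2][0]:
            continue  # require different queries
        r = _pearson(
            profiles.iloc[k1].to_numpy(dtype=float),
            profiles.iloc[k2].to_numpy(dtype=float),
        )
        if not np.isnan(r):
            random_pairs.append(r)

    return {
        "cross_condition": np.array(cross),
        "within_condition": np.array(within),
        "random_queries": np.array(random_pairs),
    }
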