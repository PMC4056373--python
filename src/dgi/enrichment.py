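"""Precision-recall evaluation of score matrices against gene-pair standards.

Scored (query, array) pairs are ranked — by |score| by default, treating
positive and negative interactions equally — and compared against a
standard set of known related pairs. Pairs in the standard that were never
scored are excluded from the recall denominator, so recall is measured over
the evaluable universe only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from dgi.io import ScoreMatrix, StandardPairSet

logger = logging.getLogger("dgi")

__all__ = ["evaluable_universe", "precision_recall", "aupr"]


def evaluable_universe(scores: ScoreMatrix, standard: StandardPairSet) -> StandardPairSet:
    """Restrict a standard to pairs actually scored (non-missing)."""
    scored = set()
    vals = scores.values
    arr = vals.to_numpy()
    rows, cols = np.nonzero(~np.isnan(arr))
    for i, j in zip(rows, cols):
        a, b = str(vals.index[i]), str(vals.columns[j])
        if a != b:
            scored.add((a, b) if a <= b else (b, a))
    kept = standard.pairs & scored
    logger.info(
        "evaluable_universe: %d of %d standard pairs scored", len(kept), len(standard)
    )
    return StandardPairSet(frozenset(kept), standard.universe)


def _unique_pair_scores(scores: ScoreMatrix) -> pd.Series:
    """Non-missing entries as unordered gene pairs.

    In square (e.g. similarity) matrices each pair may appear twice and
    self-pairs sit on the diagonal; entries collapse onto the canonical
    (sorted) pair, keeping the larger-magnitude score, and self-pairs are
    dropped.
    """
    stacked = scores.pair_scores()
    out: dict[tuple[str, str], float] = {}
    for (q, a), v in stacked.items():
        if q == a:
            continue
        pair = (q, a) if q <= a else (a, q)
        if pair not in out or abs(v) > abs(out[pair]):
            out[pair] = float(v)
    series = pd.Series(out, dtype=float)
    series.index = pd.MultiIndex.from_tuples(series.index)
    return series


def precision_recall(
    scores: ScoreMatrix, standard: StandardPairSet, by_magnitude: bool = True
) -> pd.DataFrame:
    """Precision-recall curve of a score ranking against a pair standard.

    One row per rank: pairs sorted by |score| (default) or signed score,
    descending, with ties broken by lexicographic (query, array) order for
    reproducibility. Recall is over the evaluable standard (scored pairs
    only).
    """
    pair_scores = _unique_pair_scores(scores)
    universe = evaluable_universe(scores, standard)
    if len(universe) == 0:
        raise ValueError("no standard pair overlaps the scored universe")
    key = pair_scores.abs() if by_magnitude else pair_scores
    order = sorted(
        pair_scores.index,
        key=lambda qa: (-key.loc[qa], qa[0], qa[1]),
    )
    rows = []
    tp = 0
    n_pos = len(universe)
    for rank, (q, a) in enumerate(order, start=1):
        if (q, a) in universe:
            tp += 1
        rows.append(
            {
                "rank": rank,
                "threshold": float(pair_scores.loc[(q, a)]),
                "precision": tp / rank,
                "recall": tp / n_pos,
            }
        )
    return pd.DataFrame(rows, columns=["rank", "threshold", "precision", "recall"])


def aupr(curve: pd.DataFrame) -> float:
    """Area under a precision-recall curve (step interpolation in recall)."""
    recall = np.concatenate([[0.0], curve["recall"].to_numpy()])
    precision = curve["precision"].to_numpy()
    return float(np.sum(np.diff(recall) * precision))
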