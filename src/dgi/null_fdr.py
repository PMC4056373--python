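"""Empirical null from same-condition replicate pairs and tail FDR.

The null score sample is built by pairing replicates *within* each
condition, differencing them as if they were cross-condition measurements,
pooling the two conditions' pseudo-differentials, and scoring through the
identical dS path. Since both members of a within-condition pair share
condition effects, the resulting scores carry no differential signal and
estimate the score distribution under the no-differential-interaction null.

The FDR at a cutoff is the ratio of the null tail proportion to the
observed tail proportion, clamped to [0, 1], computed per signed tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dgi.io import ScoreMatrix
from dgi.scoring import ds_score

logger = logging.getLogger("dgi")

__all__ = ["NullModel", "build_null", "estimate_fdr", "fdr_curve", "fdr_cutoff"]


@dataclass
class NullModel:
    """Empirical null dS score sample with construction metadata."""

    null_scores: np.ndarray
    scheme: str = "within_condition_pairs"
    seed: int = 0
    mode: str = "pooled"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = np.sort(np.asarray(self.null_scores, dtype=float))
        scores = scores[~np.isnan(scores)]
        self.null_scores = scores
        if self.n_null < 100:
            logger.warning(
                "NullModel: only %d null scores; FDR estimates will be coarse",
                self.n_null,
            )

    @property
    def n_null(self) -> int:
        return int(self.null_scores.size)


def _pair_replicates(reps: list, rng: np.random.Generator) -> list[tuple]:
    """Seeded random perfect matching of replicate labels; odd counts drop one."""
    reps = sorted(reps)
    if len(reps) % 2:
        logger.warning(
            "build_null: odd replicate count %d, dropping replicate %r",
            len(reps), reps[-1],
        )
        reps = reps[:-1]
    order = rng.permutation(len(reps))
    shuffled = [reps[j] for j in order]
    return [(shuffled[k], shuffled[k + 1]) for k in range(0, len(shuffled), 2)]


def build_null(
    residuals: pd.DataFrame,
    scheme: str = "within_condition_pairs",
    mode: str = "pooled",
    seed: int = 0,
) -> NullModel:
    """Score same-condition replicate pairs as if cross-condition.

    Within each condition, replicates are paired by a seeded random perfect
    matching and differenced; the pseudo-differentials of both conditions
    are pooled per gene pair and scored with :func:`dgi.scoring.ds_score`.
    """
    if scheme != "within_condition_pairs":
        raise ValueError(f"unknown null scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    frames = []
    pseudo_rep = 0
    pairings = {}
    for cond in sorted(residuals["condition"].unique()):
        sub = residuals.loc[residuals["condition"] == cond]
        reps = sorted(sub["replicate"].unique())
        if len(reps) < 2:
            raise ValueError(f"condition {cond!r} has < 2 replicates")
        pairs = _pair_replicates(reps, rng)
        pairings[cond] = pairs
        key = ["query_id", "array_id"]
        for r1, r2 in pairs:
            pseudo_rep += 1
            a = sub.loc[sub["replicate"] == r1, key + ["residual"]]
            b = sub.loc[sub["replicate"] == r2, key + ["residual"]]
            merged = a.merge(b, on=key, suffixes=("_1", "_2")).dropna()
            out = merged[key].copy()
            out["replicate"] = pseudo_rep
            out["delta"] = merged["residual_1"].to_numpy() - merged["residual_2"].to_numpy()
            frames.append(out)
    diffs = pd.concat(frames, ignore_index=True)
    _, summaries = ds_score(diffs, mode=mode)
    scores = np.array([s.score for s in summaries if not s.degenerate])
    n_per_pair = sorted(s.n for s in summaries)
    return NullModel(
        scores, scheme=scheme, seed=seed, mode=mode,
        metadata={
            "pairings": pairings,
            "n_pairs_scored": len(summaries),
            "median_deltas_per_pair": (
                float(n_per_pair[len(n_per_pair) // 2]) if n_per_pair else float("nan")
            ),
        },
    )


def _tail_fraction(scores: np.ndarray, cutoff: float, tail: str) -> float:
    if tail == "positive":
        return float(np.mean(scores >= cutoff))
    if tail == "negative":
        return float(np.mean(scores <= cutoff))
    raise ValueError(f"tail must be 'positive' or 'negative', got {tail!r}")


def _observed_values(observed) -> np.ndarray:
    if isinstance(observed, ScoreMatrix):
        vals = observed.values.to_numpy().ravel()
    else:
        vals = np.asarray(observed, dtype=float).ravel()
    return vals[~np.isnan(vals)]


def estimate_fdr(null: NullModel, observed, cutoff: float, tail: str = "positive") -> float:
    """FDR = min(1, null tail proportion / observed tail proportion).

    'Beyond' means ``>= cutoff`` for the positive tail and ``<= cutoff``
    for the negative tail. NaN when no observed score lies beyond the
    cutoff.
    """
    obs = _observed_values(observed)
    p_obs = _tail_fraction(obs, cutoff, tail)
    if p_obs == 0.0:
        logger.warning("estimate_fdr: empty observed %s tail at cutoff %g", tail, cutoff)
        return float("nan")
    p_null = _tail_fraction(null.null_scores, cutoff, tail)
    ratio = p_null / p_obs
    if ratio > 1.0:
        logger.info("estimate_fdr: ratio %.3g clamped to 1 at cutoff %g", ratio, cutoff)
    return min(1.0, ratio)


def fdr_curve(null: NullModel, observed, grid, monotonize: bool = False) -> pd.DataFrame:
    """Evaluate :func:`estimate_fdr` for both tails over a cutoff grid.

    With ``monotonize`` the curve is made non-increasing in score magnitude
    within each tail (isotonic step-down); off by default — the raw ratio
    estimator is reported as-is.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("cutoff grid is empty")
    rows = []
    for tail in ("positive", "negative"):
        cuts = np.sort(grid) if tail == "positive" else np.sort(grid)[::-1]
        fdrs = np.array([estimate_fdr(null, observed, c, tail) for c in cuts])
        if monotonize:
            fdrs = np.fmin.accumulate(fdrs)
        rows.extend(
            {"cutoff": float(c), "tail": tail, "fdr": float(f)}
            for c, f in zip(cuts, fdrs)
        )
    return pd.DataFrame(rows, columns=["cutoff", "tail", "fdr"])


def fdr_cutoff(null: NullModel, observed, target_fdr: float, tail: str = "positive") -> float:
    """Least extreme observed-score cutoff whose estimated FDR <= target.

    NaN when no cutoff attains the target.
    """
    obs = _observed_values(observed)
    candidates = np.unique(obs)
    if tail == "negative":
        candidates = candidates[::-1]
    # candidates run from least to most extreme; return the first that qualifies
    for c in candidates:
        fdr = estimate_fdr(null, obs, c, tail)
        if not np.isnan(fdr) and fdr <= target_fdr:
            return float(c)
    return float("nan")
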