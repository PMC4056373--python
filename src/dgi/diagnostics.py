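"""Variance-decomposition and split-replicate reproducibility diagnostics.

If across-condition measurements were independent, the variance of a
pair's differentials would equal the sum of its per-condition residual
variances. Shared pipeline noise breaks this: with correlation rho between
the conditions' residuals, the differential variance is 2*(1-rho)*sigma**2
instead of 2*sigma**2. The variance decomposition quantifies exactly this
deflation, per double mutant and in the dataset median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dgi.scoring import compute_differentials, ds_score

__all__ = ["VarianceReport", "variance_decomposition", "split_replicate_reproducibility"]


@dataclass
class VarianceReport:
    """Per-pair and median variance decomposition.

    ``per_pair`` has one row per (query, array) with the two per-condition
    static variances, their sum (the differential variance expected under
    independence) and the observed differential variance.
    """

    per_pair: pd.DataFrame
    median_static_var: float
    median_expected_diff_var: float
    median_observed_diff_var: float

    @property
    def deflation_fraction(self) -> float:
        """Fraction of pairs whose observed differential variance is below expected."""
        pp = self.per_pair
        return float((pp["observed_diff_var"] < pp["expected_diff_var"]).mean())


def variance_decomposition(residuals: pd.DataFrame, diffs: pd.DataFrame) -> VarianceReport:
    """Compare observed differential variance with the independence expectation.

    Pairs need >= 2 replicates in each condition and >= 2 differentials;
    others are skipped.
    """
    stat = (
        residuals.groupby(["query_id", "array_id", "condition"])["residual"]
        .agg(["size", "var"])
        .reset_index()
    )
    stat = stat.loc[stat["size"] >= 2]
    wide = stat.pivot_table(
        index=["query_id", "array_id"], columns="condition", values="var"
    ).dropna()
    conds = list(wide.columns)
    if len(conds) != 2:
        raise ValueError("variance decomposition needs exactly two conditions")
    dvar = (
        diffs.groupby(["query_id", "array_id"])["delta"].agg(["size", "var"])
    )
    dvar = dvar.loc[dvar["size"] >= 2, "var"]
    per_pair = wide.join(dvar.rename("observed_diff_var"), how="inner").reset_index()
    per_pair = per_pair.rename(
        columns={conds[0]: f"static_var_{conds[0]}", conds[1]: f"static_var_{conds[1]}"}
    )
    per_pair["expected_diff_var"] = (
        per_pair[f"static_var_{conds[0]}"] + per_pair[f"static_var_{conds[1]}"]
    )
    static_pool = np.concatenate(
        [per_pair[f"static_var_{c}"].to_numpy() for c in conds]
    )
    return VarianceReport(
        per_pair=per_pair,
        median_static_var=float(np.median(static_pool)) if len(per_pair) else math.nan,
        median_expected_diff_var=(
            float(per_pair["expected_diff_var"].median()) if len(per_pair) else math.nan
        ),
        median_observed_diff_var=(
            float(per_pair["observed_diff_var"].median()) if len(per_pair) else math.nan
        ),
    )


def _fisher_ci(r: float, n: int, level_z: float = 1.959964) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return math.nan, math.nan
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    return math.tanh(z - level_z * se), math.tanh(z + level_z * se)


def split_replicate_reproducibility(
    residuals: pd.DataFrame,
    split: tuple,
    treatment: str,
    reference: str,
    top_fractions=(0.001, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0),
    mode: str = "pooled",
) -> pd.DataFrame:
    """Score two disjoint replicate subsets independently and correlate.

    For each top-fraction threshold, pairs are ranked by the mean of
    |score| across the two splits and the Pearson correlation of the two
    splits' scores over the retained pairs is reported with a Fisher-z 95%
    CI. Signal-rich scores grow *more* correlated toward the extreme tail.
    """
    set1, set2 = (set(split[0]), set(split[1]))
    if not set1 or not set2:
        raise ValueError("replicate splits must be nonempty")
    if set1 & set2:
        # overlapping splits are only useful as a consistency check
        logging.getLogger("dgi").warning(
            "split_replicate_reproducibility: splits share replicates %s",
            sorted(set1 & set2),
        )

    def half_scores(rep_set):
        sub = residuals.loc[residuals["replicate"].isin(rep_set)]
        diffs = compute_differentials(sub, treatment, reference)
        _, summaries = ds_score(diffs, mode=mode)
        return pd.Series(
            {(s.query_id, s.array_id): s.score for s in summaries if not s.degenerate}
        )

    s1, s2 = half_scores(set1), half_scores(set2)
    both = pd.DataFrame({"s1": s1, "s2": s2}).dropna()
    both["rank_key"] = (both["s1"].abs() + both["s2"].abs()) / 2.0
    both = both.sort_values("rank_key", ascending=False)

    rows = []
    n_total = len(both)
    for frac in sorted(top_fractions):
        k = max(1, int(math.ceil(frac * n_total)))
        top = both.iloc[:k]
        if len(top) < 3:
            continue
        r = float(np.corrcoef(top["s1"], top["s2"])[0, 1])
        lo, hi = _fisher_ci(r, len(top))
        rows.append(
            {"fraction": frac, "n_pairs": len(top), "correlation": r,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows, columns=["fraction", "n_pairs", "correlation",
                                       "ci_low", "ci_high"])
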