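"""Readers and writers for colony tables, score matrices and gene-pair sets.

All on-disk formats are tab-delimited UTF-8 text with a single header row.
Missing values are written as ``NA``; on read both ``NA`` and the empty
string are accepted. Gene labels are whitespace-stripped and compared
case-sensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dgi")

#: Required columns of the long-format colony table, in canonical order.
COLONY_COLUMNS = (
    "query_id",
    "array_id",
    "replicate",
    "condition",
    "plate_id",
    "row",
    "col",
    "raw_size",
)

#: Key identifying a single measurement.
MEASUREMENT_KEY = ("query_id", "array_id", "replicate", "condition")

_NA_TOKENS = ("NA", "")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ColonyTable:
    """Long-format table of raw (or normalized) colony sizes.

    One row per measurement, keyed by (query gene, array gene, pipeline
    replicate, condition). ``raw_size`` is non-negative or NaN (missing);
    each plate holds the colonies of exactly one (query, replicate,
    condition) triple, as in E-MAP-style screens where a plate carries one
    query crossed against the whole array.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_colony_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ColonyTable):
            return NotImplemented
        a = self.data.sort_values(list(MEASUREMENT_KEY)).reset_index(drop=True)
        b = other.data.sort_values(list(MEASUREMENT_KEY)).reset_index(drop=True)
        return a.equals(b)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def plates(self) -> list[str]:
        return sorted(self.data["plate_id"].unique())

    def with_sizes(self, sizes: pd.Series) -> "ColonyTable":
        """Return a copy whose ``raw_size`` column is replaced by *sizes*."""
        out = self.data.copy()
        out["raw_size"] = np.asarray(sizes, dtype=float)
        return ColonyTable(out)


def _validate_colony_frame(df: pd.DataFrame, source: str | None = None) -> pd.DataFrame:
    missing_cols = [c for c in COLONY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"colony table missing required columns: {missing_cols}")
    df = df.loc[:, list(COLONY_COLUMNS)].copy()
    for col in ("query_id", "array_id", "condition", "plate_id"):
        df[col] = df[col].astype(str).str.strip()
    for col in ("replicate", "row", "col"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if (df[col] < 1).any():
            bad = df.index[df[col] < 1][0]
            raise FormatError(f"column {col!r} must be >= 1 (line {_line_of(bad)})")
    # exact round-trip parse (pandas' fast path can be off by one ulp)
    df["raw_size"] = df["raw_size"].map(
        lambda v: float(v) if isinstance(v, str) else v
    ).astype(float)
    neg = df["raw_size"] < 0
    if neg.any():
        raise FormatError(
            f"negative raw_size at line {_line_of(df.index[neg][0])}"
            + (f" of {source}" if source else "")
        )
    dup = df.duplicated(list(MEASUREMENT_KEY), keep="first")
    if dup.any():
        raise FormatError(
            "duplicate measurement key "
            f"{tuple(df.loc[df.index[dup][0], list(MEASUREMENT_KEY)])} "
            f"at line {_line_of(df.index[dup][0])}"
        )
    # each plate belongs to exactly one (query, replicate, condition)
    owners = df.groupby("plate_id")[["query_id", "replicate", "condition"]].nunique()
    multi = owners[(owners > 1).any(axis=1)]
    if not multi.empty:
        raise FormatError(
            f"plate {multi.index[0]!r} maps to more than one "
            "(query, replicate, condition) triple"
        )
    return df.reset_index(drop=True)


def _line_of(idx: int) -> int:
    # +2: one for the header row, one for 0-based indexing
    return int(idx) + 2


def read_colony_table(path) -> ColonyTable:
    """Read a long-format colony-size TSV into a validated :class:`ColonyTable`."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=list(_NA_TOKENS), keep_default_na=False
    )
    try:
        return ColonyTable(df)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def write_colony_table(table: ColonyTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class ScoreMatrix:
    """Queries x arrays matrix of scores with missing-value support.

    ``kind`` is one of ``dS``, ``S``, ``similarity`` or ``other``.
    Similarity matrices are square and symmetric where both entries are
    defined, with a unit diagonal where defined.
    """

    values: pd.DataFrame
    kind: str = "other"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            raise FormatError("duplicate row ids in score matrix")
        if vals.columns.has_duplicates:
            raise FormatError("duplicate column ids in score matrix")
        vals = vals.astype(float)
        vals.index = vals.index.astype(str).str.strip()
        vals.columns = vals.columns.astype(str).str.strip()
        self.values = vals
        if self.kind == "similarity":
            self._check_similarity()

    def _check_similarity(self) -> None:
        vals = self.values
        if vals.shape[0] != vals.shape[1] or list(vals.index) != list(vals.columns):
            raise FormatError("similarity matrix must be square with matching ids")
        arr = vals.to_numpy()
        both = ~np.isnan(arr) & ~np.isnan(arr.T)
        if not np.allclose(arr[both], arr.T[both], atol=1e-8):
            raise FormatError("similarity matrix is not symmetric")
        diag = np.diag(arr)
        if not np.allclose(diag[~np.isnan(diag)], 1.0, atol=1e-8):
            raise FormatError("similarity matrix diagonal must be 1 where defined")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    def pair_scores(self) -> pd.Series:
        """Non-missing entries as a Series indexed by (row_id, col_id)."""
        stacked = self.values.stack()
        stacked.index.names = ["query_id", "array_id"]
        return stacked


def read_score_matrix(path, kind: str = "other") -> ScoreMatrix:
    """Read a TSV score matrix (first column = row ids, header = column ids)."""
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(_NA_TOKENS),
        keep_default_na=False,
        float_precision="round_trip",
    )
    df.index.name = None
    df.columns.name = None
    return ScoreMatrix(df, kind=kind)


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = out.index.name or "id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


@dataclass(frozen=True)
class StandardPairSet:
    """Unordered, deduplicated set of gene-label pairs (no self-pairs)."""

    pairs: frozenset = frozenset()
    universe: frozenset | None = None

    @staticmethod
    def from_pairs(pairs, universe=None) -> "StandardPairSet":
        canon = set()
        for a, b in pairs:
            a, b = str(a).strip(), str(b).strip()
            if a == b:
                logger.warning("skipping self-pair (%s, %s)", a, b)
                continue
            canon.add((a, b) if a <= b else (b, a))
        uni = frozenset(str(g).strip() for g in universe) if universe is not None else None
        return StandardPairSet(frozenset(canon), uni)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def read_pair_set(path) -> StandardPairSet:
    """Read a two-column TSV of gene pairs; self-pairs are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: pair file needs two columns")
    return StandardPairSet.from_pairs(df.iloc[:, :2].itertuples(index=False))


def write_pair_set(pairs: StandardPairSet, path) -> None:
    df = pd.DataFrame(sorted(pairs.pairs), columns=["gene_a", "gene_b"])
    df.to_csv(path, sep="\t", index=False)
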