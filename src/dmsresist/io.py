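"""Long-format count table I/O and pre-scoring variant filters.

Counts live in a TSV with one row per (variant, condition, replicate,
timepoint): columns ``variant position wt_aa mut_aa condition replicate
timepoint count``. Before scoring, variants are filtered per condition on
three inclusive rules over the replicate x timepoint count grid: mean
count >= 4, fraction of zero cells <= 10/12, and fraction of zero
pre-selection (T0) cells <= 2/3 (defaults match a 3-replicate, 4-timepoint
design; the fractions are configurable for other designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import COUNT_COLUMNS


class CountFormatError(ValueError):
    """A count table violates the format contract (duplicates, negatives...)."""


@dataclass
class FilterThresholds:
    """Inclusive pre-scoring filter thresholds.

    ``min_mean_count``: minimum mean count over the condition's R x T cells.
    ``max_zero_fraction_all``: maximum fraction of zero cells over R x T.
    ``max_zero_fraction_t0``: maximum fraction of zero T0 cells over R.
    """

    min_mean_count: float = 4.0
    max_zero_fraction_all: float = 10.0 / 12.0
    max_zero_fraction_t0: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be non-negative")
        for frac in (self.max_zero_fraction_all, self.max_zero_fraction_t0):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("zero-fraction thresholds must lie in [0, 1]")


def _validate(table: pd.DataFrame, lines: np.ndarray | None = None) -> None:
    """Raise CountFormatError with offending line numbers where known."""

    def where(mask: pd.Series) -> str:
        if lines is None:
            return f"rows {[int(i) for i in table.index[mask][:5]]}"
        return f"lines {[int(i) for i in lines[mask.to_numpy()][:5]]}"

    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise CountFormatError(f"missing columns {missing}")
    neg = table["count"] < 0
    if neg.any():
        raise CountFormatError(f"negative counts at {where(neg)}")
    key = ["variant", "condition", "replicate", "timepoint"]
    dup = table.duplicated(key, keep=False)
    if dup.any():
        raise CountFormatError(f"duplicate (variant, condition, replicate, "
                               f"timepoint) keys at {where(dup)}")


def write_counts(table: pd.DataFrame, path) -> None:
    """Write a count table as TSV (validates before writing)."""
    _validate(table)
    table.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Read and validate a count-table TSV.

    Malformed rows (negative counts, duplicate keys, unparseable numbers)
    are reported with 1-based file line numbers (header is line 1).
    """
    table = pd.read_csv(path, sep="\t")
    lines = np.arange(2, len(table) + 2)  # data starts on line 2
    for col, kind in (("position", int), ("replicate", int), ("timepoint", int)):
        try:
            table[col] = table[col].astype(kind)
        except (ValueError, KeyError) as err:
            raise CountFormatError(f"column {col!r} not parseable: {err}") from err
    bad = pd.to_numeric(table.get("count"), errors="coerce").isna()
    if bad.any():
        raise CountFormatError(
            f"non-numeric counts at lines {list(lines[bad.to_numpy()][:5])}"
        )
    table["count"] = pd.to_numeric(table["count"])
    # integer-valued floats (e.g. written from sampled data) collapse to int
    if np.allclose(table["count"] % 1, 0):
        table["count"] = table["count"].astype(np.int64)
    _validate(table, lines)
    return table[COUNT_COLUMNS]


def filter_variants(
    table: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    condition: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three pre-scoring rules to one condition's counts.

    A variant is retained iff, over the condition's full replicate x
    timepoint grid (missing cells treated as zero counts and flagged),

    (i)   mean count >= ``min_mean_count``,
    (ii)  zero-cell fraction <= ``max_zero_fraction_all``,
    (iii) zero-T0-cell fraction <= ``max_zero_fraction_t0``.

    Returns ``(filtered table, report)`` where the report has one row per
    input variant with ``pass``, ``failed_rules`` (comma-joined rule tags
    ``mean``/``zeros``/``t0_zeros``) and ``n_missing_cells``.
    """
    thresholds = thresholds or FilterThresholds()
    if condition is not None:
        table = table[table["condition"] == condition]
    if table.empty:
        warnings.warn("filter_variants: empty count table", stacklevel=2)
        report = pd.DataFrame(
            columns=["variant", "pass", "failed_rules", "n_missing_cells"]
        )
        return table.copy(), report
    if table["condition"].nunique() > 1:
        raise ValueError("filter_variants operates on a single condition")

    grid = table.pivot_table(
        index="variant",
        columns=["replicate", "timepoint"],
        values="count",
        aggfunc="first",
    )
    # complete the R x T grid so absent cells are counted, not dropped
    full = pd.MultiIndex.from_product(
        [sorted(table["replicate"].unique()), sorted(table["timepoint"].unique())],
        names=["replicate", "timepoint"],
    )
    grid = grid.reindex(columns=full)
    n_missing = grid.isna().sum(axis=1)
    grid = grid.fillna(0.0)  # absent cells behave as zero counts

    mean_ok = grid.mean(axis=1) >= thresholds.min_mean_count
    zero_frac = (grid == 0).mean(axis=1)
    zeros_ok = zero_frac <= thresholds.max_zero_fraction_all
    t0 = grid.loc[:, grid.columns.get_level_values("timepoint") == 0]
    t0_ok = (t0 == 0).mean(axis=1) <= thresholds.max_zero_fraction_t0

    passed = mean_ok & zeros_ok & t0_ok
    failed = pd.Series("", index=grid.index, dtype=object)
    for ok, tag in ((mean_ok, "mean"), (zeros_ok, "zeros"), (t0_ok, "t0_zeros")):
        failed[~ok] = failed[~ok].where(failed[~ok] == "", failed[~ok] + ",") + tag

    report = pd.DataFrame(
        {
            "variant": grid.index,
            "pass": passed.to_numpy(),
            "failed_rules": failed.to_numpy(),
            "n_missing_cells": n_missing.to_numpy(),
        }
    ).reset_index(drop=True)

    keep = set(grid.index[passed])
    return table[table["variant"].isin(keep)].copy(), report
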