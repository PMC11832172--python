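"""Doubling-rate fitness scoring from filtered variant counts.

Counts are wild-type normalized on a log2 scale: for each sample
(replicate, time point) the per-variant ``log2(count + pseudocount)`` is
centered on the synonymous (wild-type-encoding) pool, whose growth defines
zero. The normalized trajectory is regressed on the time-point index
t = 1..T, so the slope beta is in doublings per interval relative to
wild-type: with wild-type at d = 2 doublings per interval, beta = -2 means
the variant's cells are not growing at all (2**(2-2) = 1 per interval) and
beta = 1 means they double three times per interval. Because wild-type
growth is pinned at d in every condition, beta values are directly
comparable across conditions, and the recentered score
``gamma = beta_inh - beta_DMSO`` isolates inhibitor-specific effects from
folding/expression effects.

Replicates are scored independently (one OLS slope per replicate); the
reported beta is the replicate mean and its uncertainty the standard error
across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # sklearn is the package's estimator idiom; keep the import soft
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

from .io import FilterThresholds, filter_variants
from .library import SYNONYMOUS
from .panel import DMSO


class NormalizationError(ValueError):
    """Raised when a condition has no synonymous pool to normalize against."""


@dataclass
class ScoreSet:
    """Per-variant fitness over conditions: beta, its SE, replicate count.

    All three tables share the same variant index (rows) and condition
    columns; cells are NaN where a variant failed that condition's filter.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    n_reps: pd.DataFrame
    variants: pd.DataFrame  # variant, position, wt_aa, mut_aa, vclass

    @property
    def conditions(self) -> list[str]:
        return list(self.beta.columns)

    def to_long(self) -> pd.DataFrame:
        """Long form: variant, condition, beta, se, n_reps (scores TSV)."""
        long = (
            self.beta.stack(future_stack=True)
            .rename("beta")
            .to_frame()
            .join(self.se.stack(future_stack=True).rename("se"))
            .join(self.n_reps.stack(future_stack=True).rename("n_reps"))
            .reset_index()
            .rename(columns={"level_0": "variant", "level_1": "condition"})
        )
        return long.dropna(subset=["beta"]).reset_index(drop=True)


def variant_classes(table: pd.DataFrame) -> pd.Series:
    """Variant class per variant name, derived from wt/mut residues."""
    meta = table.drop_duplicates("variant").set_index("variant")
    cls = pd.Series("missense", index=meta.index, dtype=object)
    cls[meta["mut_aa"] == meta["wt_aa"]] = SYNONYMOUS
    cls[meta["mut_aa"] == "*"] = "nonsense"
    return cls


def normalize(
    table: pd.DataFrame,
    pseudocount: float = 0.5,
    center: str = "median",
) -> pd.DataFrame:
    """Wild-type-normalized log2 trajectories for one condition.

    Returns a wide frame indexed by variant with (replicate, t) columns,
    t = 1..T. Each cell is ``log2(c + pseudocount)`` minus the per-sample
    center (median, or mean, of the synonymous pool on the same scale),
    then anchored at the trajectory's own t = 1 value so trajectories are
    translation-free and slopes untouched.
    """
    if table["condition"].nunique() > 1:
        raise ValueError("normalize operates on a single condition")
    cls = variant_classes(table)
    syn = cls.index[cls == SYNONYMOUS]
    if len(syn) == 0:
        raise NormalizationError(
            f"condition {table['condition'].iat[0]!r} has no synonymous "
            "variants to define the wild-type center"
        )

    grid = table.pivot_table(
        index="variant",
        columns=["replicate", "timepoint"],
        values="count",
        aggfunc="first",
    )
    log = np.log2(grid + pseudocount)
    centers = getattr(log.loc[log.index.intersection(syn)], center)(axis=0)
    m = log - centers
    # anchor each (variant, replicate) trajectory at its first time point
    first = m.loc[:, m.columns.get_level_values("timepoint") == 0]
    first.columns = first.columns.get_level_values("replicate")
    reps = m.columns.get_level_values("replicate")
    m = m - first.loc[:, reps].to_numpy()
    m.columns = pd.MultiIndex.from_arrays(
        [reps, m.columns.get_level_values("timepoint") + 1],
        names=["replicate", "t"],
    )
    return m


def _ols_slopes(m: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate OLS slope of m on t; NaN where a cell is missing."""
    slopes = {}
    for rep in m.columns.get_level_values("replicate").unique():
        block = m[rep]
        t = block.columns.to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("scoring needs at least two time points")
        tc = t - t.mean()
        denom = (tc**2).sum()
        y = block.to_numpy(dtype=float)
        yc = y - y.mean(axis=1, keepdims=True)
        slopes[rep] = yc @ tc / denom
    return pd.DataFrame(slopes, index=m.index)


def score(m: pd.DataFrame) -> pd.DataFrame:
    """Score normalized trajectories: replicate-mean slope and its SE.

    Returns a frame indexed by variant with columns beta, se, n_reps.
    With a single replicate the SE is +inf (no replicate spread).
    """
    slopes = _ols_slopes(m)
    n = slopes.notna().sum(axis=1)
    beta = slopes.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ddof=1 on n=1
        sd = slopes.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    se[n <= 1] = np.inf
    return pd.DataFrame({"beta": beta, "se": se, "n_reps": n})


def score_all(
    table: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    pseudocount: float = 0.5,
    center: str = "median",
    conditions: list[str] | None = None,
) -> ScoreSet:
    """Filter, normalize and score every condition independently.

    Each condition is processed on its own (filtering included), matching
    the per-condition scoring of the experiment; cells are NaN where a
    variant failed that condition's filter. Unknown requested conditions
    are dropped with a warning.
    """
    available = list(dict.fromkeys(table["condition"]))
    if conditions is None:
        conditions = available
    else:
        missing = [c for c in conditions if c not in available]
        if missing:
            warnings.warn(f"conditions absent from counts: {missing}", stacklevel=2)
            conditions = [c for c in conditions if c in available]

    meta_cols = ["variant", "position", "wt_aa", "mut_aa"]
    meta = table[meta_cols].drop_duplicates("variant").set_index("variant")
    meta["vclass"] = variant_classes(table)

    index = meta.index
    beta = pd.DataFrame(index=index, columns=conditions, dtype=float)
    se = pd.DataFrame(index=index, columns=conditions, dtype=float)
    n_reps = pd.DataFrame(index=index, columns=conditions, dtype=float)
    for cond in conditions:
        sub = table[table["condition"] == cond]
        filtered, _ = filter_variants(sub, thresholds)
        if filtered.empty:
            continue
        m = normalize(filtered, pseudocount=pseudocount, center=center)
        scored = score(m)
        beta.loc[scored.index, cond] = scored["beta"]
        se.loc[scored.index, cond] = scored["se"]
        n_reps.loc[scored.index, cond] = scored["n_reps"]
    return ScoreSet(beta=beta, se=se, n_reps=n_reps, variants=meta.reset_index())


def dmso_recenter(scores: ScoreSet, dmso: str = DMSO) -> ScoreSet:
    """Recenter inhibitor scores on the vehicle: gamma = beta_inh - beta_DMSO.

    The vehicle column of the output is identically 0 (with zero SE) where
    the vehicle score exists; other cells combine SEs in quadrature. Cells
    missing in either operand are missing in the output.
    """
    if dmso not in scores.beta.columns:
        raise KeyError(f"score matrix has no {dmso!r} column to recenter on")
    gamma = scores.beta.sub(scores.beta[dmso], axis=0)
    gse = np.sqrt(scores.se.pow(2).add(scores.se[dmso] ** 2, axis=0))
    has_dmso = scores.beta[dmso].notna()
    gamma[dmso] = np.where(has_dmso, 0.0, np.nan)
    gse[dmso] = np.where(has_dmso, 0.0, np.nan)
    n = scores.n_reps.where(gamma.notna())
    return ScoreSet(beta=gamma, se=gse, n_reps=n, variants=scores.variants)


class FitnessScorer(BaseEstimator):
    """Estimator facade over the filter -> normalize -> score pipeline.

    Scikit-learn style: construct with hyperparameters, ``fit`` on a
    long-format count table, then read fitted attributes ``scores_``
    (a :class:`ScoreSet`), ``gamma_`` (vehicle-recentered, when the vehicle
    condition is present) and ``conditions_``.
    """

    def __init__(
        self,
        thresholds: FilterThresholds | None = None,
        pseudocount: float = 0.5,
        center: str = "median",
        dmso: str = DMSO,
    ) -> None:
        self.thresholds = thresholds
        self.pseudocount = pseudocount
        self.center = center
        self.dmso = dmso

    def fit(self, X: pd.DataFrame, y=None) -> "FitnessScorer":
        missing = {"variant", "condition", "replicate", "timepoint", "count"} - set(
            X.columns
        )
        if missing:
            raise ValueError(f"count table lacks columns {sorted(missing)}")
        self.scores_ = score_all(
            X,
            thresholds=self.thresholds,
            pseudocount=self.pseudocount,
            center=self.center,
        )
        self.conditions_ = self.scores_.conditions
        if self.dmso in self.conditions_:
            self.gamma_ = dmso_recenter(self.scores_, dmso=self.dmso)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Long-form scores of the fitted table (beta scale)."""
        if not hasattr(self, "scores_"):
            raise AttributeError("FitnessScorer is not fitted")
        return self.scores_.to_long()
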