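"""Resistance, gain/loss-of-function, hotspot and shared-set analysis.

A *resistance mutation* for an inhibitor grows markedly faster than
wild-type under that inhibitor while not out-growing wild-type in the
vehicle: operationally, a one-sided test of beta_inh > 0.5 at p <= 0.1
(normal approximation on the replicate-derived SE) combined with the
effect-size rule beta_DMSO <= 0. A *resistance position* is any position
carrying at least one resistance mutation for that inhibitor.

Gain/loss-of-function in the differential-sensitivity sense is defined on
the recentered score gamma = beta_inh - beta_DMSO: GOF iff gamma > 0.75,
LOF iff gamma < 0 (both strict); gamma cancels folding/expression effects
and isolates inhibitor sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DEFAULT_TYPE_MAP, DMSO, TYPE_I, TYPE_I_HALF, TYPE_II
from .scoring import ScoreSet, dmso_recenter

GOF = "GOF"
LOF = "LOF"
NEUTRAL = "neutral"
UNCLASSIFIED = "unclassified"


@dataclass
class ClassCutoffs:
    """Decision thresholds for resistance / GOF / LOF classification.

    ``use_se=False`` switches the resistance test to the pure effect-size
    rule beta_inh > threshold, for single-replicate designs without a
    replicate-derived SE.
    """

    resistance_beta_threshold: float = 0.5
    resistance_test_alpha: float = 0.1
    dmso_beta_max: float = 0.0
    gof_gamma_min: float = 0.75
    lof_gamma_max: float = 0.0
    use_se: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.resistance_test_alpha < 1.0:
            raise ValueError("resistance_test_alpha must lie in (0, 1)")


def _upper_tail_p(beta: np.ndarray, se: np.ndarray, null: float) -> np.ndarray:
    """One-sided p for H0: beta <= null, normal approximation.

    Zero SE degenerates to an exact comparison (p = 0/0.5/1); infinite or
    missing SE yields NaN (the caller marks those unclassified).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (beta - null) / se
    z = np.where(se == 0, np.sign(beta - null) * np.inf, z)
    z = np.where((se == 0) & (beta == null), 0.0, z)
    p = stats.norm.sf(z)
    p[~np.isfinite(se) | np.isnan(beta)] = np.nan
    return p


def classify_gof_lof(gamma, cutoffs: ClassCutoffs | None = None):
    """GOF / LOF / neutral label(s) from recentered score(s) gamma."""
    cutoffs = cutoffs or ClassCutoffs()
    g = np.asarray(gamma, dtype=float)
    out = np.where(
        g > cutoffs.gof_gamma_min,
        GOF,
        np.where(g < cutoffs.lof_gamma_max, LOF, NEUTRAL),
    ).astype(object)
    out[np.isnan(g)] = UNCLASSIFIED
    return out.item() if np.isscalar(gamma) or np.ndim(gamma) == 0 else out


def classify_resistance(
    scores: ScoreSet,
    condition: str,
    cutoffs: ClassCutoffs | None = None,
    dmso: str = DMSO,
) -> pd.DataFrame:
    """Per-variant resistance labels for one inhibitor condition.

    Returns a frame with variant metadata plus ``beta``, ``se``,
    ``beta_dmso``, ``gamma``, ``pvalue``, ``is_resistance`` and
    ``gol_class``. Variants missing either score are labelled unclassified
    (``is_resistance`` is NA).
    """
    cutoffs = cutoffs or ClassCutoffs()
    if condition not in scores.beta.columns:
        raise KeyError(f"no scores for condition {condition!r}")
    if dmso not in scores.beta.columns:
        raise KeyError(f"no scores for vehicle condition {dmso!r}")

    beta = scores.beta[condition]
    se = scores.se[condition]
    beta_dmso = scores.beta[dmso]
    gamma = beta - beta_dmso

    if cutoffs.use_se:
        pvalue = pd.Series(
            _upper_tail_p(beta, se, cutoffs.resistance_beta_threshold),
            index=beta.index,
        )
        grows = pvalue <= cutoffs.resistance_test_alpha
    else:
        pvalue = pd.Series(np.nan, index=beta.index)
        grows = beta > cutoffs.resistance_beta_threshold
    resistant = grows & (beta_dmso <= cutoffs.dmso_beta_max)

    classifiable = beta.notna() & beta_dmso.notna()
    if cutoffs.use_se:
        classifiable &= pvalue.notna()
    is_res = pd.Series(pd.NA, index=beta.index, dtype="boolean")
    is_res[classifiable] = resistant[classifiable]

    out = scores.variants.set_index("variant").copy()
    out["condition"] = condition
    out["beta"] = beta
    out["se"] = se
    out["beta_dmso"] = beta_dmso
    out["gamma"] = gamma
    out["pvalue"] = pvalue
    out["is_resistance"] = is_res
    out["gol_class"] = classify_gof_lof(gamma.to_numpy(), cutoffs)
    return out.reset_index()


def classify_all(
    scores: ScoreSet,
    cutoffs: ClassCutoffs | None = None,
    conditions: list[str] | None = None,
    dmso: str = DMSO,
) -> pd.DataFrame:
    """Stacked resistance labels for every inhibitor condition."""
    if conditions is None:
        conditions = [c for c in scores.conditions if c != dmso]
    parts = [
        classify_resistance(scores, cond, cutoffs, dmso=dmso) for cond in conditions
    ]
    return pd.concat(parts, ignore_index=True)


def resistance_positions(labels: pd.DataFrame, condition: str | None = None) -> set:
    """Positions carrying >= 1 resistance mutation (optionally one condition)."""
    sub = labels if condition is None else labels[labels["condition"] == condition]
    hits = sub[sub["is_resistance"].fillna(False).astype(bool)]
    return set(hits["position"].tolist())


def hotspot_counts(
    labels: pd.DataFrame,
    type_map: dict[str, str] | None = None,
    types: tuple[str, ...] = (TYPE_I, TYPE_II, TYPE_I_HALF),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resistance-event counts by position and inhibitor type.

    Each (mutation, inhibitor) resistance event contributes 1 to its
    position x type tile; the per-mutation expansion (position, mut_aa,
    type) is returned alongside, and its row sums reproduce the tiles.
    """
    type_map = type_map or DEFAULT_TYPE_MAP
    hits = labels[labels["is_resistance"].fillna(False).astype(bool)].copy()
    hits["itype"] = hits["condition"].map(type_map)
    hits = hits[hits["itype"].isin(types)]

    def table(index_cols: list[str]) -> pd.DataFrame:
        if hits.empty:
            idx = pd.MultiIndex.from_arrays([[]] * len(index_cols), names=index_cols)
            return pd.DataFrame(0, index=idx, columns=list(types))
        t = (
            hits.groupby(index_cols + ["itype"])
            .size()
            .unstack("itype", fill_value=0)
            .reindex(columns=list(types), fill_value=0)
        )
        t.columns.name = None
        return t

    return table(["position"]), table(["position", "mut_aa"])


def shared_resistance_sets(
    labels: pd.DataFrame,
    type_map: dict[str, str] | None = None,
    types: tuple[str, ...] = (TYPE_I, TYPE_II, TYPE_I_HALF),
) -> dict[frozenset, set]:
    """Venn partition of resistance mutations over inhibitor-type membership.

    A mutation belongs to a type if it is resistant to >= 1 inhibitor of
    that type. Returns the 2**len(types) - 1 exclusive regions keyed by
    frozenset of member types; region sets are disjoint and their union is
    the set of all resistance mutations of those types.
    """
    type_map = type_map or DEFAULT_TYPE_MAP
    hits = labels[labels["is_resistance"].fillna(False).astype(bool)].copy()
    hits["itype"] = hits["condition"].map(type_map)
    hits = hits[hits["itype"].isin(types)]
    membership = hits.groupby("variant")["itype"].agg(frozenset)

    regions: dict[frozenset, set] = {}
    n = len(types)
    for mask in range(1, 2**n):
        key = frozenset(t for i, t in enumerate(types) if mask >> i & 1)
        regions[key] = set(membership.index[membership == key])
    return regions


def venn_counts(regions: dict[frozenset, set]) -> dict[frozenset, int]:
    return {k: len(v) for k, v in regions.items()}


def differential_sensitivity(
    gamma_a: pd.Series,
    gamma_b: pd.Series,
    cutoffs: ClassCutoffs | None = None,
    se_a: pd.Series | None = None,
    se_b: pd.Series | None = None,
) -> tuple[set, set]:
    """Variants GOF under one condition and LOF under the other.

    Returns ``(GOF_A & LOF_B, GOF_B & LOF_A)`` applying the strict gamma
    thresholds; the two sets are disjoint by construction. When SE columns
    are supplied, the GOF arm additionally requires one-sided significance
    of gamma > gof_gamma_min and the LOF arm of gamma < lof_gamma_max at
    the resistance test level (the optional statistically-filtered mode).
    """
    cutoffs = cutoffs or ClassCutoffs()

    def gof(g: pd.Series, se: pd.Series | None) -> pd.Series:
        hit = g > cutoffs.gof_gamma_min
        if se is not None:
            p = pd.Series(_upper_tail_p(g, se, cutoffs.gof_gamma_min), index=g.index)
            hit &= p <= cutoffs.resistance_test_alpha
        return hit.fillna(False)

    def lof(g: pd.Series, se: pd.Series | None) -> pd.Series:
        hit = g < cutoffs.lof_gamma_max
        if se is not None:
            p = pd.Series(
                1.0 - _upper_tail_p(g, se, cutoffs.lof_gamma_max), index=g.index
            )
            hit &= p <= cutoffs.resistance_test_alpha
        return hit.fillna(False)

    shared = gamma_a.index.intersection(gamma_b.index)
    a, b = gamma_a.loc[shared], gamma_b.loc[shared]
    sa = se_a.loc[shared] if se_a is not None else None
    sb = se_b.loc[shared] if se_b is not None else None
    first = set(shared[(gof(a, sa) & lof(b, sb)).to_numpy()])
    second = set(shared[(gof(b, sb) & lof(a, sa)).to_numpy()])
    return first, second


def differential_sensitivity_pair(
    scores: ScoreSet,
    condition_a: str,
    condition_b: str,
    cutoffs: ClassCutoffs | None = None,
    statistical: bool = False,
    dmso: str = DMSO,
) -> tuple[set, set]:
    """Differential sets for an inhibitor pair from a beta-scale ScoreSet."""
    gamma = dmso_recenter(scores, dmso=dmso)
    kwargs = {}
    if statistical:
        kwargs = {"se_a": gamma.se[condition_a], "se_b": gamma.se[condition_b]}
    return differential_sensitivity(
        gamma.beta[condition_a], gamma.beta[condition_b], cutoffs, **kwargs
    )
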