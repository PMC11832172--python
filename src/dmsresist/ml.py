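"""Fitness-prediction protocol: binning, monotone constraints, block splits.

The prediction task regresses inhibitor-condition fitness scores on an
evolutionary-likelihood feature (a protein-language-model log-likelihood
ratio, always included) plus up to 13 optional interpretable biophysical /
chemical features. To curb overfitting on a small, internally correlated
dataset the protocol (i) constrains the regressor to be monotone
increasing in the likelihood feature and decreasing in the
stability-difference feature, (ii) coarsens the 12 remaining features into
4-5 bins represented by the bin median, and (iii) separates train from
test by whole blocks: entire inhibitors, 20% of residue positions, and two
mutant amino-acid identities, so no (position, amino acid, inhibitor)
leaks. Cross-validation folds are blocked the same way. All 2**13 = 8192
feature subsets can be enumerated and ranked by blocked-CV correlation.

This module computes no structural or language-model features; synthetic
feature tables stand in for them (see :func:`synthetic_feature_table`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

from .panel import DMSO

# -- feature roles ----------------------------------------------------------

ESM_LLR = "esm_llr"  # evolutionary likelihood (always included, monotone +1)
STABILITY_DIFF = "ddd_g"  # stability difference between bound states (-1)

#: The 13 optional interpretable feature roles.
OPTIONAL_FEATURES: tuple[str, ...] = (
    STABILITY_DIFF,
    "ddg_bound",  # stability in the inhibitor-type-bound state
    "atp_distance",  # residue C-alpha to ATP centroid
    "inhibitor_distance",  # shortest residue-inhibitor distance
    "rmsf",  # positional flexibility across crystal structures
    "residue_rmsd",  # mutant residue displacement
    "ligand_rmsd",  # re-docked ligand displacement
    "inhibitor_mw",  # inhibitor molecular weight
    "rf_score",  # predicted protein-ligand binding strength
    "pocket_volume",
    "pocket_hydrophobicity",
    "pocket_polarity",
    "residue_volume_change",
)

ALL_FEATURES: tuple[str, ...] = (ESM_LLR,) + OPTIONAL_FEATURES

#: Default monotone-constraint declaration; 0 = unconstrained.
DEFAULT_MONOTONE: dict[str, int] = {
    **{f: 0 for f in ALL_FEATURES},
    ESM_LLR: +1,
    STABILITY_DIFF: -1,
}

#: Features left continuous (the monotone-constrained pair); the rest bin.
UNBINNED_FEATURES: tuple[str, ...] = (ESM_LLR, STABILITY_DIFF)
BINNED_FEATURES: tuple[str, ...] = tuple(
    f for f in OPTIONAL_FEATURES if f not in UNBINNED_FEATURES
)

#: Conditions excluded from ML data: the vehicle and the lone type I-1/2
#: inhibitor (one dataset each would be memorized, not learned).
EXCLUDED_CONDITIONS: tuple[str, ...] = (DMSO, "AMG-458")

TARGET = "fitness"


class ContractError(TypeError):
    """The plugged-in regressor does not satisfy the protocol contract."""


# -- feature binning --------------------------------------------------------


@dataclass
class BinSpec:
    """Bin edges and representative values (bin medians) for one feature."""

    edges: np.ndarray  # len n_bins + 1, strictly increasing
    representatives: np.ndarray  # len n_bins, non-decreasing

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.representatives = np.asarray(self.representatives, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.representatives) != len(self.edges) - 1:
            raise ValueError("need one representative per bin")
        if np.any(np.diff(self.representatives) < 0):
            raise ValueError("bin representatives must be non-decreasing")

    def assign(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map values to representatives; out-of-range clamps to end bins."""
        v = np.asarray(values, dtype=float)
        idx = np.digitize(v, self.edges[1:-1], right=False)
        clamped = (v < self.edges[0]) | (v > self.edges[-1])
        return self.representatives[idx], clamped


def fit_bins(values: np.ndarray, n_bins: int = 5) -> BinSpec:
    """Quantile-edge bins with median representatives.

    Degenerate (near-constant) features collapse to a single bin.
    """
    if not 1 <= n_bins <= 5:
        raise ValueError("protocol uses between one and five bins")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(v, qs))
    if len(edges) < 2:  # constant feature
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    spec_edges = edges.copy()
    idx = np.digitize(v, spec_edges[1:-1], right=False)
    reps = np.array(
        [
            np.median(v[idx == i]) if np.any(idx == i) else np.nan
            for i in range(len(spec_edges) - 1)
        ]
    )
    # empty interior bins inherit a neighboring representative
    if np.any(np.isnan(reps)):
        filled = pd.Series(reps).ffill().bfill().to_numpy()
        reps = filled
    return BinSpec(edges=spec_edges, representatives=reps)


class FeatureBinner(BaseEstimator, TransformerMixin):
    """Coarsen interpretable features to 4-5 bin medians (sklearn-style).

    Parameters
    ----------
    features : features to bin (others pass through unchanged).
    n_bins : bins per feature (4 or 5 in the protocol; <= 5 enforced).
    specs : optional pre-computed ``{feature: BinSpec}`` overriding fitting.
    """

    def __init__(
        self,
        features: tuple[str, ...] = BINNED_FEATURES,
        n_bins: int = 5,
        specs: dict[str, BinSpec] | None = None,
    ) -> None:
        self.features = features
        self.n_bins = n_bins
        self.specs = specs

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureBinner":
        self.specs_ = dict(self.specs) if self.specs else {}
        for f in self.features:
            if f not in X.columns:
                raise KeyError(f"feature table lacks column {f!r}")
            if f not in self.specs_:
                self.specs_[f] = fit_bins(X[f].to_numpy(), self.n_bins)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            raise AttributeError("FeatureBinner is not fitted")
        out = X.copy()
        self.clamped_ = {}
        for f, spec in self.specs_.items():
            if f not in out.columns:
                continue
            binned, clamped = spec.assign(out[f].to_numpy())
            out[f] = binned
            if clamped.any():
                self.clamped_[f] = int(clamped.sum())
                warnings.warn(
                    f"{clamped.sum()} values of {f!r} outside the fitted "
                    "bin range were clamped to the nearest bin",
                    stacklevel=2,
                )
        return out


# -- feature-set enumeration ------------------------------------------------


def enumerate_feature_sets(
    optional_features: tuple[str, ...] = OPTIONAL_FEATURES,
    always_include: str = ESM_LLR,
) -> list[tuple[str, ...]]:
    """All subsets of the optional features, each with the fixed feature.

    13 optional features yield the protocol's 8192 candidate models.
    """
    if always_include in optional_features:
        raise ValueError("the fixed feature cannot also be optional")
    sets: list[tuple[str, ...]] = []
    for r in range(len(optional_features) + 1):
        for combo in combinations(optional_features, r):
            sets.append((always_include,) + combo)
    return sets


# -- block train/test split and blocked CV ----------------------------------


@dataclass
class SplitSpec:
    """Block-holdout declaration for the train/test split."""

    held_out_inhibitors: tuple[str, ...] = ("crizotinib", "glesatinib-analog")
    held_out_position_fraction: float = 0.2
    held_out_amino_acids: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.held_out_position_fraction < 1.0:
            raise ValueError("position holdout fraction must lie in [0, 1)")
        if self.held_out_amino_acids < 0:
            raise ValueError("held-out amino-acid count must be non-negative")


@dataclass
class HoldoutSplit:
    """Resolved block holdout: a row is test iff any of its blocks is held."""

    train_positions: tuple
    train_amino_acids: tuple
    train_inhibitors: tuple
    held_positions: tuple
    held_amino_acids: tuple
    held_inhibitors: tuple
    seed: int

    def masks(self, table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        test = (
            table["inhibitor"].isin(self.held_inhibitors)
            | table["position"].isin(self.held_positions)
            | table["mut_aa"].isin(self.held_amino_acids)
        )
        return ~test, test

    def split(self, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        train, test = self.masks(table)
        return table[train].copy(), table[test].copy()


def make_split(
    positions,
    amino_acids,
    inhibitors,
    spec: SplitSpec | None = None,
) -> HoldoutSplit:
    """Draw the block holdout: whole inhibitors, floor(frac * positions)
    randomly chosen positions, and a fixed number of amino acids."""
    spec = spec or SplitSpec()
    positions = list(positions)
    amino_acids = list(amino_acids)
    inhibitors = list(inhibitors)
    if spec.held_out_amino_acids >= len(amino_acids):
        raise ValueError("cannot hold out every amino acid")
    unknown = set(spec.held_out_inhibitors) - set(inhibitors)
    if unknown:
        raise ValueError(f"held-out inhibitors not in panel: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    n_pos = int(np.floor(spec.held_out_position_fraction * len(positions)))
    held_pos = set(rng.choice(positions, size=n_pos, replace=False).tolist())
    held_aa = set(
        rng.choice(amino_acids, size=spec.held_out_amino_acids, replace=False).tolist()
    )
    held_inh = set(spec.held_out_inhibitors)
    return HoldoutSplit(
        train_positions=tuple(p for p in positions if p not in held_pos),
        train_amino_acids=tuple(a for a in amino_acids if a not in held_aa),
        train_inhibitors=tuple(i for i in inhibitors if i not in held_inh),
        held_positions=tuple(sorted(held_pos)),
        held_amino_acids=tuple(sorted(held_aa)),
        held_inhibitors=tuple(spec.held_out_inhibitors),
        seed=spec.seed,
    )


@dataclass
class CVFold:
    """One blocked validation fold: a position part plus an amino-acid block."""

    positions: tuple
    amino_acids: tuple


def make_cv_folds(
    train_positions,
    train_amino_acids,
    k: int = 10,
    aa_per_fold: int = 2,
    seed: int = 0,
) -> list[CVFold]:
    """Blocked k-fold plan: positions partitioned into k near-equal disjoint
    parts; each fold also gets ``aa_per_fold`` amino acids drawn uniformly
    without replacement within the fold (re-used across folds when
    ``k * aa_per_fold`` exceeds the amino-acid pool).

    Validation fold i = rows whose position is in part i OR whose amino
    acid is in block i; the training half is the complement.
    """
    positions = list(train_positions)
    amino_acids = list(train_amino_acids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(positions):
        raise ValueError("more folds than positions")
    if aa_per_fold > len(amino_acids):
        raise ValueError("amino-acid block larger than the pool")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    order = rng.permutation(len(positions))
    parts = np.array_split(order, k)
    folds = []
    for part in parts:
        aa_block = rng.choice(amino_acids, size=aa_per_fold, replace=False)
        folds.append(
            CVFold(
                positions=tuple(positions[i] for i in part),
                amino_acids=tuple(aa_block.tolist()),
            )
        )
    return folds


class BlockKFold:
    """sklearn-style splitter over a feature table using blocked folds."""

    def __init__(self, folds: list[CVFold]):
        self.folds = folds

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return len(self.folds)

    def split(self, X: pd.DataFrame, y=None, groups=None):
        for fold in self.folds:
            val = (
                X["position"].isin(fold.positions)
                | X["mut_aa"].isin(fold.amino_acids)
            ).to_numpy()
            idx = np.arange(len(X))
            yield idx[~val], idx[val]


# -- regressor contract ------------------------------------------------------

#: Hyperparameter knobs the protocol tunes (names follow the xgboost API).
DEFAULT_HYPERPARAMS: dict = {
    "booster": "gbtree",
    "max_depth": 4,
    "n_estimators": 100,
    "learning_rate": 0.1,
    "gamma": 0.0,
    "colsample_bytree": 1.0,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
    "grow_policy": "depthwise",
}


def sample_hyperparams(rng: np.random.Generator) -> dict:
    """One draw from the tuned hyperparameter space."""
    return {
        "booster": rng.choice(["gbtree", "dart"]).item(),
        "max_depth": int(rng.integers(2, 9)),
        "n_estimators": int(rng.integers(50, 301)),
        "learning_rate": float(10 ** rng.uniform(-2, -0.5)),
        "gamma": float(rng.uniform(0, 5)),
        "colsample_bytree": float(rng.uniform(0.5, 1.0)),
        "reg_alpha": float(10 ** rng.uniform(-3, 1)),
        "reg_lambda": float(10 ** rng.uniform(-3, 1)),
        "grow_policy": rng.choice(["depthwise", "lossguide"]).item(),
    }


class MonotoneGradientBooster(BaseEstimator):
    """Boosted-tree regressor honoring per-feature monotone constraints.

    Thin sklearn-style wrapper over a pluggable backend ("xgboost" by
    default, "sklearn" for HistGradientBoostingRegressor). Construction
    fails with :class:`ContractError` if the backend cannot enforce
    monotone constraints.
    """

    def __init__(
        self,
        features: tuple[str, ...],
        monotone: dict[str, int] | None = None,
        backend: str = "xgboost",
        params: dict | None = None,
    ) -> None:
        self.features = features
        self.monotone = monotone
        self.backend = backend
        self.params = params

    def _constraints(self) -> tuple[int, ...]:
        mono = DEFAULT_MONOTONE if self.monotone is None else self.monotone
        return tuple(int(mono.get(f, 0)) for f in self.features)

    def _build(self):
        params = dict(self.params or DEFAULT_HYPERPARAMS)
        if self.backend == "xgboost":
            from xgboost import XGBRegressor

            return XGBRegressor(
                monotone_constraints=self._constraints(),
                random_state=0,
                n_jobs=1,
                verbosity=0,
                **params,
            )
        if self.backend == "sklearn":
            from sklearn.ensemble import HistGradientBoostingRegressor

            keep = {
                "max_depth": params.get("max_depth"),
                "learning_rate": params.get("learning_rate"),
                "max_iter": params.get("n_estimators", 100),
            }
            return HistGradientBoostingRegressor(
                monotonic_cst=list(self._constraints()), random_state=0, **keep
            )
        raise ContractError(
            f"backend {self.backend!r} does not satisfy the monotone-"
            "constraint regressor contract"
        )

    def fit(self, X: pd.DataFrame, y) -> "MonotoneGradientBooster":
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"feature table lacks {missing}")
        self.model_ = self._build()
        self.model_.fit(X[list(self.features)], np.asarray(y, dtype=float))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("MonotoneGradientBooster is not fitted")
        return np.asarray(self.model_.predict(X[list(self.features)]), dtype=float)


# -- tuning, cross-validation and model selection ----------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def tune_train_select(
    train: pd.DataFrame,
    feature_sets: list[tuple[str, ...]],
    folds: list[CVFold],
    test: pd.DataFrame | None = None,
    target: str = TARGET,
    budget: int = 10,
    seed: int = 0,
    backend: str = "xgboost",
    monotone: dict[str, int] | None = None,
) -> dict:
    """Tune, cross-validate and rank candidate feature sets.

    Per feature set: hyperparameters are searched (``budget`` random
    trials; the first trial is the default configuration) on an internal
    80/20 split of the training rows, minimizing held-out MSE; the tuned
    configuration is then scored by blocked k-fold CV (mean Pearson r and
    MSE); sets are ranked by CV correlation. The best set is refit on the
    full training table and, when ``test`` is given, evaluated per
    inhibitor on the held-out rows.

    Returns a dict with ``leaderboard`` (ranked DataFrame), ``best_model``,
    ``best_features`` and ``test_report``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    y = train[target].to_numpy(dtype=float)

    # internal 80/20 tuning split (random rows, as in the protocol)
    n = len(train)
    perm = rng.permutation(n)
    cut = max(1, int(round(0.8 * n)))
    fit_idx, val_idx = perm[:cut], perm[cut:]
    if len(val_idx) == 0:
        fit_idx, val_idx = perm, perm

    splitter = BlockKFold(folds)
    records = []
    for fs in feature_sets:
        best_mse, best_params = np.inf, dict(DEFAULT_HYPERPARAMS)
        for trial in range(budget):
            params = dict(DEFAULT_HYPERPARAMS) if trial == 0 else sample_hyperparams(rng)
            model = MonotoneGradientBooster(fs, monotone, backend, params)
            model.fit(train.iloc[fit_idx], y[fit_idx])
            mse = float(np.mean((model.predict(train.iloc[val_idx]) - y[val_idx]) ** 2))
            if mse < best_mse:
                best_mse, best_params = mse, params

        rs, mses = [], []
        for tr_idx, va_idx in splitter.split(train):
            if len(va_idx) == 0 or len(tr_idx) == 0:
                continue
            model = MonotoneGradientBooster(fs, monotone, backend, best_params)
            model.fit(train.iloc[tr_idx], y[tr_idx])
            pred = model.predict(train.iloc[va_idx])
            rs.append(_pearson(pred, y[va_idx]))
            mses.append(float(np.mean((pred - y[va_idx]) ** 2)))
        records.append(
            {
                "features": fs,
                "n_features": len(fs),
                "cv_pearson": float(np.nanmean(rs)) if rs else np.nan,
                "cv_mse": float(np.nanmean(mses)) if mses else np.nan,
                "tuning_mse": best_mse,
                "params": best_params,
            }
        )

    leaderboard = (
        pd.DataFrame(records)
        .sort_values("cv_pearson", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    best = leaderboard.iloc[0]
    best_model = MonotoneGradientBooster(
        tuple(best["features"]), monotone, backend, dict(best["params"])
    )
    best_model.fit(train, y)

    test_report = None
    if test is not None and len(test):
        pred = best_model.predict(test)
        ytest = test[target].to_numpy(dtype=float)
        rows = [
            {
                "inhibitor": "overall",
                "pearson_r": _pearson(pred, ytest),
                "mse": float(np.mean((pred - ytest) ** 2)),
                "n": len(test),
            }
        ]
        for inh, sub in test.groupby("inhibitor"):
            p = best_model.predict(sub)
            t = sub[target].to_numpy(dtype=float)
            rows.append(
                {
                    "inhibitor": inh,
                    "pearson_r": _pearson(p, t),
                    "mse": float(np.mean((p - t) ** 2)),
                    "n": len(sub),
                }
            )
        test_report = pd.DataFrame(rows)

    return {
        "leaderboard": leaderboard,
        "best_features": tuple(best["features"]),
        "best_model": best_model,
        "test_report": test_report,
    }


# -- synthetic feature tables ------------------------------------------------


def synthetic_feature_table(
    positions,
    amino_acids: str = "ACDEFGHIKLMNPQRSTVWY",
    inhibitors: tuple[str, ...] = (
        "crizotinib",
        "capmatinib",
        "tepotinib",
        "glumetinib",
        "savolitinib",
        "NVP-BVU972",
        "cabozantinib",
        "glesatinib-analog",
        "merestinib",
    ),
    seed: int = 0,
    noise_sd: float = 0.4,
) -> pd.DataFrame:
    """Synthetic stand-in feature table with a planted signal.

    Real structural and language-model features are out of scope; this
    generator emits plausibly distributed stand-ins keyed by (position,
    mutant amino acid, inhibitor) and a target fitness with the protocol's
    assumed monotone structure: increasing in the evolutionary-likelihood
    feature, decreasing in the stability difference, plus a mild
    inhibitor-distance effect and Gaussian noise. Excluded conditions
    (vehicle and the type I-1/2 inhibitor) are never emitted.
    """
    inhibitors = tuple(i for i in inhibitors if i not in EXCLUDED_CONDITIONS)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    positions = list(positions)
    rows = pd.MultiIndex.from_product(
        [positions, list(amino_acids), list(inhibitors)],
        names=["position", "mut_aa", "inhibitor"],
    ).to_frame(index=False)
    n = len(rows)

    # variant-level features are shared across inhibitors
    nv = len(positions) * len(amino_acids)
    vidx = rows.index // len(inhibitors)
    esm = rng.normal(-4.0, 2.5, size=nv)[vidx]
    dddg = rng.normal(0.0, 1.0, size=nv)[vidx]
    mw = {i: rng.uniform(350, 650) for i in inhibitors}
    pos_dist = {p: rng.uniform(4, 30) for p in positions}

    rows[ESM_LLR] = esm
    rows[STABILITY_DIFF] = dddg
    rows["ddg_bound"] = rng.normal(0.0, 1.2, size=n)
    rows["atp_distance"] = rows["position"].map(pos_dist) + rng.normal(0, 0.5, n)
    rows["inhibitor_distance"] = rows["position"].map(pos_dist) + rng.normal(0, 1.0, n)
    rows["rmsf"] = rng.gamma(2.0, 0.4, size=n)
    rows["residue_rmsd"] = rng.gamma(1.5, 0.3, size=n)
    rows["ligand_rmsd"] = rng.gamma(1.5, 0.5, size=n)
    rows["inhibitor_mw"] = rows["inhibitor"].map(mw)
    rows["rf_score"] = rng.normal(5.5, 0.8, size=n)
    rows["pocket_volume"] = rng.normal(450, 80, size=n)
    rows["pocket_hydrophobicity"] = rng.normal(30, 8, size=n)
    rows["pocket_polarity"] = rng.normal(8, 2, size=n)
    rows["residue_volume_change"] = rng.normal(0, 40, size=n)

    rows[TARGET] = (
        0.35 * (rows[ESM_LLR] - rows[ESM_LLR].mean())
        - 0.5 * rows[STABILITY_DIFF]
        + 0.04 * (rows["inhibitor_distance"] - 15.0)
        + rng.normal(0, noise_sd, size=n)
    )
    return rows
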