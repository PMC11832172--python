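"""Fitness-prediction protocol: binning, splits, enumeration, tuning."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

import dmsresist as d
from dmsresist import ml


# -- feature-set enumeration -------------------------------------------------


def powerset_oracle(items):
    return list(
        chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))
    )


def test_thirteen_optional_features_give_8192_sets():
    sets = d.enumerate_feature_sets()
    assert len(ml.OPTIONAL_FEATURES) == 13
    assert len(sets) == 8192
    assert all(ml.ESM_LLR in s for s in sets)


@pytest.mark.parametrize("n_optional", [0, 1, 3])
def test_enumeration_matches_powerset(n_optional):
    opts = tuple(f"f{i}" for i in range(n_optional))
    sets = d.enumerate_feature_sets(opts, always_include="base")
    oracle = [("base",) + c for c in powerset_oracle(opts)]
    assert sorted(sets) == sorted(oracle)
    assert len(sets) == 2**n_optional


def test_fixed_feature_cannot_be_optional():
    with pytest.raises(ValueError):
        d.enumerate_feature_sets(("a", "b"), always_include="a")


# -- binning -----------------------------------------------------------------


def test_binning_median_representatives():
    """Values (1,2,3,10,11,12,100,101) in bins [0,5), [5,50), [50,200)
    map to their bin medians (2, 11, 100.5)."""
    spec = ml.BinSpec(edges=[0, 5, 50, 200], representatives=[2.0, 11.0, 100.5])
    values = np.array([1, 2, 3, 10, 11, 12, 100, 101], dtype=float)
    binned, clamped = spec.assign(values)
    assert np.allclose(binned, [2, 2, 2, 11, 11, 11, 100.5, 100.5])
    assert not clamped.any()


def test_fit_bins_reproduces_example_medians():
    values = np.array([1, 2, 3, 10, 11, 12, 100, 101], dtype=float)
    spec = ml.fit_bins(values, n_bins=3)
    binned, _ = spec.assign(values)
    # each value maps to the median of its fitted bin
    for rep in np.unique(binned):
        members = values[binned == rep]
        assert rep == np.median(members)


def test_binned_features_take_at_most_five_values():
    rng = np.random.default_rng(0)
    table = d.synthetic_feature_table(range(1059, 1079), seed=0)
    binner = d.FeatureBinner(n_bins=5).fit(table)
    out = binner.transform(table)
    for f in ml.BINNED_FEATURES:
        assert out[f].nunique() <= 5
    for f in ml.UNBINNED_FEATURES:  # monotone-constrained features stay raw
        assert out[f].equals(table[f])


def test_binning_is_idempotent():
    table = d.synthetic_feature_table(range(1059, 1069), seed=1)
    binner = d.FeatureBinner().fit(table)
    once = binner.transform(table)
    twice = binner.transform(once)
    pd.testing.assert_frame_equal(once, twice)


def test_out_of_range_values_clamp_with_warning():
    spec = ml.BinSpec(edges=[0, 5, 10], representatives=[2.0, 7.0])
    table = pd.DataFrame({"rmsf": [-3.0, 12.0, 4.0]})
    binner = d.FeatureBinner(features=("rmsf",), specs={"rmsf": spec}).fit(table)
    with pytest.warns(UserWarning, match="clamped"):
        out = binner.transform(table)
    assert np.allclose(out["rmsf"], [2.0, 7.0, 2.0])
    assert binner.clamped_["rmsf"] == 2


def test_constant_feature_collapses_to_single_bin():
    spec = ml.fit_bins(np.full(10, 3.7))
    binned, _ = spec.assign(np.full(4, 3.7))
    assert np.allclose(binned, 3.7)


def test_bin_spec_validation():
    with pytest.raises(ValueError):
        ml.BinSpec(edges=[0, 0, 1], representatives=[0.0, 0.5])
    with pytest.raises(ValueError):
        ml.BinSpec(edges=[0, 1, 2], representatives=[1.5, 0.5])  # decreasing


# -- block holdout split -----------------------------------------------------


def test_paper_scale_split_arithmetic():
    """287 positions at 20% holdout and 2 of 20 amino acids held out leave
    230 training positions and 18 training amino acids."""
    positions = list(range(1059, 1346))
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    inhibitors = [c for c in d.DEFAULT_CONDITIONS if c not in ml.EXCLUDED_CONDITIONS]
    split = d.make_split(positions, aas, inhibitors, d.SplitSpec(seed=0))
    assert len(split.train_positions) == 230
    assert len(split.train_amino_acids) == 18
    assert set(split.held_inhibitors) == {"crizotinib", "glesatinib-analog"}


def test_floor_rounding_of_position_holdout():
    split = d.make_split(
        list(range(10)),
        list("ACDEF"),
        ["crizotinib", "glesatinib-analog", "x"],
        d.SplitSpec(held_out_position_fraction=0.2, held_out_amino_acids=0),
    )
    assert len(split.held_positions) == 2
    assert len(split.train_positions) == 8


def test_empty_holdout_keeps_everything_in_train():
    table = d.synthetic_feature_table(range(1059, 1064), seed=2)
    split = d.make_split(
        sorted(table["position"].unique()),
        sorted(table["mut_aa"].unique()),
        sorted(table["inhibitor"].unique()),
        d.SplitSpec(
            held_out_inhibitors=(), held_out_position_fraction=0.0,
            held_out_amino_acids=0,
        ),
    )
    train, test = split.split(table)
    assert len(test) == 0 and len(train) == len(table)


def test_no_block_leakage_between_train_and_test():
    """Every test row carries a held-out inhibitor, position or amino acid;
    no train row carries any."""
    table = d.synthetic_feature_table(range(1059, 1089), seed=3)
    split = d.make_split(
        sorted(table["position"].unique()),
        sorted(table["mut_aa"].unique()),
        sorted(table["inhibitor"].unique()),
        d.SplitSpec(seed=5),
    )
    train, test = split.split(table)
    assert len(train) + len(test) == len(table)
    held_p, held_a, held_i = (
        set(split.held_positions),
        set(split.held_amino_acids),
        set(split.held_inhibitors),
    )
    in_test = (
        test["position"].isin(held_p)
        | test["mut_aa"].isin(held_a)
        | test["inhibitor"].isin(held_i)
    )
    assert in_test.all()
    in_train = (
        train["position"].isin(held_p)
        | train["mut_aa"].isin(held_a)
        | train["inhibitor"].isin(held_i)
    )
    assert not in_train.any()


def test_split_deterministic_under_seed():
    args = (list(range(100)), list("ACDEFGHIKL"), ["crizotinib", "glesatinib-analog"])
    a = d.make_split(*args, d.SplitSpec(seed=11))
    b = d.make_split(*args, d.SplitSpec(seed=11))
    assert a == b
    c = d.make_split(*args, d.SplitSpec(seed=12))
    assert a.held_positions != c.held_positions


def test_split_spec_validation():
    with pytest.raises(ValueError):
        d.SplitSpec(held_out_position_fraction=1.0)
    with pytest.raises(ValueError):
        d.make_split([1], list("AC"), ["crizotinib", "glesatinib-analog"],
                     d.SplitSpec(held_out_amino_acids=2))
    with pytest.raises(ValueError):
        d.make_split([1], list("ACD"), ["x"], d.SplitSpec())  # unknown holdouts


# -- blocked cross-validation ------------------------------------------------


def test_paper_scale_cv_fold_sizes():
    """230 training positions split 10 ways give 23 positions per part,
    each paired with a 2-amino-acid block."""
    folds = d.make_cv_folds(range(230), list("ACDEFGHIKLMNPQRSTV"), k=10, seed=0)
    assert len(folds) == 10
    assert all(len(f.positions) == 23 for f in folds)
    assert all(len(f.amino_acids) == 2 for f in folds)


def test_position_parts_partition_training_positions():
    positions = list(range(20))
    folds = d.make_cv_folds(positions, list("ACDEF"), k=10, seed=1)
    parts = [set(f.positions) for f in folds]
    assert all(len(p) == 2 for p in parts)
    assert set().union(*parts) == set(positions)
    for i, a in enumerate(parts):
        for b in parts[i + 1 :]:
            assert a.isdisjoint(b)


def test_single_fold_covers_everything():
    folds = d.make_cv_folds(range(7), list("AC"), k=1, seed=0)
    assert len(folds) == 1
    assert set(folds[0].positions) == set(range(7))


def test_block_kfold_validation_rows_match_fold_blocks():
    table = d.synthetic_feature_table(range(1059, 1079), seed=4)
    folds = d.make_cv_folds(
        sorted(table["position"].unique()), sorted(table["mut_aa"].unique()),
        k=4, seed=2,
    )
    splitter = d.BlockKFold(folds)
    assert splitter.get_n_splits() == 4
    for fold, (tr, va) in zip(folds, splitter.split(table)):
        val_rows = table.iloc[va]
        in_block = val_rows["position"].isin(fold.positions) | val_rows[
            "mut_aa"
        ].isin(fold.amino_acids)
        assert in_block.all()
        train_rows = table.iloc[tr]
        assert not (
            train_rows["position"].isin(fold.positions)
            | train_rows["mut_aa"].isin(fold.amino_acids)
        ).any()


def test_cv_fold_validation():
    with pytest.raises(ValueError):
        d.make_cv_folds(range(3), list("AC"), k=5)
    with pytest.raises(ValueError):
        d.make_cv_folds(range(30), list("A"), k=3, aa_per_fold=2)


# -- regressor contract and tuning -------------------------------------------


def test_monotone_constraint_respected_on_grid():
    """Predictions are non-decreasing in the positively constrained
    evolutionary-likelihood feature with all other features fixed."""
    table = d.synthetic_feature_table(range(1059, 1079), seed=5)
    feats = (ml.ESM_LLR, ml.STABILITY_DIFF, "rmsf")
    model = d.MonotoneGradientBooster(feats).fit(table, table[ml.TARGET])
    grid = pd.DataFrame(
        {
            ml.ESM_LLR: np.linspace(-10, 2, 50),
            ml.STABILITY_DIFF: 0.0,
            "rmsf": 0.8,
        }
    )
    pred = model.predict(grid)
    assert (np.diff(pred) >= -1e-9).all()
    # and non-increasing in the negatively constrained stability difference
    grid2 = grid.assign(
        **{ml.ESM_LLR: -4.0, ml.STABILITY_DIFF: np.linspace(-3, 3, 50)}
    )
    pred2 = model.predict(grid2)
    assert (np.diff(pred2) <= 1e-9).all()


def test_unsupported_backend_raises_contract_error():
    model = d.MonotoneGradientBooster((ml.ESM_LLR,), backend="linear")
    with pytest.raises(ml.ContractError):
        model.fit(pd.DataFrame({ml.ESM_LLR: [0.0, 1.0]}), [0.0, 1.0])


@pytest.fixture(scope="module")
def tuning_problem():
    table = d.synthetic_feature_table(
        range(1059, 1083), inhibitors=("inh_a", "inh_b", "inh_c"), seed=6
    )
    split = d.make_split(
        sorted(table["position"].unique()),
        sorted(table["mut_aa"].unique()),
        sorted(table["inhibitor"].unique()),
        d.SplitSpec(held_out_inhibitors=("inh_c",), seed=1),
    )
    train, test = split.split(table)
    folds = d.make_cv_folds(
        split.train_positions, split.train_amino_acids, k=3, seed=1
    )
    return train, test, folds


def test_planted_signal_beats_uninformative_features(tuning_problem):
    """The set holding the informative features ranks above a set of pure
    noise features, and beats an intercept-like baseline correlation."""
    train, test, folds = tuning_problem
    informative = (ml.ESM_LLR, ml.STABILITY_DIFF)
    noise_only = (ml.ESM_LLR,)  # still informative but strictly weaker
    result = d.tune_train_select(
        train, [informative, noise_only], folds, test=test, budget=1, seed=0
    )
    board = result["leaderboard"]
    assert tuple(board.iloc[0]["features"]) == informative
    assert board.iloc[0]["cv_pearson"] > 0.3
    overall = result["test_report"]
    assert overall.loc[overall["inhibitor"] == "overall", "pearson_r"].iloc[0] > 0.3
    # per-inhibitor evaluation covers the held-out inhibitor
    assert "inh_c" in set(overall["inhibitor"])


def test_budget_one_runs_with_default_hyperparameters(tuning_problem):
    train, _, folds = tuning_problem
    result = d.tune_train_select(
        train, [(ml.ESM_LLR,)], folds, budget=1, seed=0
    )
    assert result["leaderboard"].iloc[0]["params"] == ml.DEFAULT_HYPERPARAMS
    with pytest.raises(ValueError):
        d.tune_train_select(train, [(ml.ESM_LLR,)], folds, budget=0)


def test_synthetic_table_excludes_vehicle_and_type_one_half():
    table = d.synthetic_feature_table(
        range(1059, 1062), inhibitors=("crizotinib", "DMSO", "AMG-458")
    )
    assert set(table["inhibitor"]) == {"crizotinib"}
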