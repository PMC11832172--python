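import pandas as pd
import pytest

import dmsresist as d
from dmsresist.panel import DMSO


@pytest.fixture(scope="session")
def small_library():
    """11-position library slice: 220 aa variants + 1 stop control."""
    return d.build_library(1059, 1069, stop_spacing=11)


@pytest.fixture(scope="session")
def small_design():
    return d.ExperimentDesign(
        n_libraries=1,
        n_replicates=3,
        conditions=("crizotinib", "cabozantinib", DMSO),
    )


@pytest.fixture(scope="session")
def noiseless_run(small_library, small_design):
    """Noiseless simulate -> counts, with one planted resistance mutation."""
    cfg = d.SimConfig(
        noiseless=True,
        seed=7,
        resistance_spec=(d.ResistanceEffect(1060, "K", "crizotinib", 1.5),),
    )
    truth = d.draw_ground_truth(small_library, small_design, cfg)
    counts = d.simulate_experiment(truth, small_design, cfg)
    return truth, counts


@pytest.fixture(scope="session")
def noiseless_scores(noiseless_run):
    truth, counts = noiseless_run
    scorer = d.FitnessScorer(pseudocount=0.0).fit(counts)
    return truth, scorer.scores_


def make_scoreset(beta: dict, se: dict | None = None, n_reps: int = 3):
    """Hand-built ScoreSet from {condition: {variant: value}} dicts."""
    beta_df = pd.DataFrame(beta, dtype=float)
    se_df = (
        pd.DataFrame(se, dtype=float)
        if se is not None
        else pd.DataFrame(0.1, index=beta_df.index, columns=beta_df.columns)
    )
    n_df = pd.DataFrame(float(n_reps), index=beta_df.index, columns=beta_df.columns)
    variants = pd.DataFrame(
        {
            "variant": beta_df.index,
            "position": [int(v[1:-1]) for v in beta_df.index],
            "wt_aa": [v[0] for v in beta_df.index],
            "mut_aa": [v[-1] for v in beta_df.index],
        }
    )
    variants["vclass"] = "missense"
    variants.loc[variants["mut_aa"] == variants["wt_aa"], "vclass"] = "synonymous"
    variants.loc[variants["mut_aa"] == "*", "vclass"] = "nonsense"
    return d.ScoreSet(beta=beta_df, se=se_df, n_reps=n_df, variants=variants)
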