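# dmsresist

Analysis toolkit for pooled-selection deep mutational scanning (DMS) of
kinase inhibitor resistance, modeled on inhibitor screens of the MET
receptor tyrosine kinase domain (residues 1059–1345) in Ba/F3 cells. It is
aimed at groups running or reanalyzing drug-selection DMS experiments:
saturation-mutagenesis libraries grown under a panel of inhibitors plus a
vehicle control, sequenced at several time points, and scored for
per-variant fitness.

The package covers the full desk-side pipeline:

- **Simulation** (`dmsresist.simulate`) — pooled-selection count data with
  known ground-truth fitness: latent abundances grow as `2**(d + β)` per
  interval (wild-type at `d = 2` doublings per interval), sequencing is
  multinomial at configurable depth, the vehicle fitness distribution is a
  bimodal mixture, and inhibitor-specific resistance mutations can be
  planted.
- **Counts & filtering** (`dmsresist.io`) — long-format count TSVs and the
  pre-scoring filters: mean count ≥ 4, zero-cell fraction ≤ 10/12, and
  pre-selection (T0) zero fraction ≤ 2/3 per condition.
- **Scoring** (`dmsresist.scoring`) — wild-type-normalized log2 counts
  (centered on the synonymous pool per sample) regressed on the time-point
  index t = 1..T. The slope β is in doublings per interval relative to
  wild-type: β = −2 means the cells are not growing (`2**(2−2) = 1` per
  interval), β = 1 means they double three times per interval. Replicates
  are scored independently; β is the replicate mean with a replicate SE.
- **Classification** (`dmsresist.classify`) — a *resistance mutation*
  satisfies a one-sided test of β_inh > 0.5 at p ≤ 0.1 together with
  β_DMSO ≤ 0; the recentered score γ = β_inh − β_DMSO defines
  gain-of-function (γ > 0.75) and loss-of-function (γ < 0) for
  differential-sensitivity analysis; hotspot counts, Venn sharing across
  inhibitor types (I / II / I½), and GOF-vs-LOF pair sets are built on top.
- **Comparison** (`dmsresist.compare`) — pairwise-complete Pearson
  correlation matrices over conditions, on raw β or vehicle-recentered γ.
- **ML protocol** (`dmsresist.ml`) — the fitness-prediction scaffolding:
  median-representative feature binning (4–5 bins), monotone-constraint
  declarations (+1 on the evolutionary-likelihood feature, −1 on the
  stability difference), block train/test holdout (whole inhibitors, 20%
  of positions, 2 amino acids), blocked 10-fold CV (23 positions + 2 amino
  acids per part on the default scale), exhaustive enumeration of the 8192
  feature subsets, and a pluggable monotone boosted-tree regressor
  (xgboost by default). Structural and language-model features themselves
  are out of scope; seeded synthetic stand-ins are provided.

## Worked example

Simulate a 38-position library slice under crizotinib, cabozantinib and
DMSO at depth 10⁶ with two planted crizotinib-resistance mutations, then
score and classify:

```python
import dmsresist as d

lib = d.build_library(1059, 1096, stop_spacing=11)
design = d.ExperimentDesign(n_libraries=1, n_replicates=3,
                            conditions=("crizotinib", "cabozantinib", "DMSO"))
cfg = d.SimConfig(seed=42, depth_per_sample=1_000_000,
                  resistance_spec=(d.ResistanceEffect(1084, "R", "crizotinib", 1.5),
                                   d.ResistanceEffect(1092, "I", "crizotinib", 1.2)))
truth = d.draw_ground_truth(lib, design, cfg)
counts = d.simulate_experiment(truth, design, cfg)

scores = d.FitnessScorer().fit(counts).scores_
labels = d.classify_all(scores)
hits = labels[labels["is_resistance"].fillna(False).astype(bool)]
print(hits[["variant", "condition", "beta", "beta_dmso", "gamma", "pvalue"]]
      .round(4).to_string(index=False))
```

```
variant  condition  beta  beta_dmso  gamma  pvalue
 H1084R crizotinib 1.506    -0.1985 1.7045     0.0
 Q1092I crizotinib 1.201    -0.2090 1.4100     0.0
```

Both planted mutations — and nothing else — are called resistant: their
estimated β under crizotinib matches the planted 1.5 and 1.2 within
sequencing noise, their vehicle fitness is ≤ 0, and the one-sided p-value
against β = 0.5 is far below the 0.1 cutoff. The recentered γ column shows
the inhibitor-specific gain. Correlating the γ matrices of the two
inhibitors (`d.pearson_matrix(scores, use_gamma=True)`) gives r = 0.984:
the two conditions share the same loss-of-function structure and differ
only at the planted sites.

The same pipeline is available from the shell:

```sh
dms-resist simulate --config sim.yaml --out counts.tsv --truth truth.tsv
dms-resist score --counts counts.tsv --out scores.tsv
dms-resist classify --scores scores.tsv --out labels.tsv
dms-resist compare --scores scores.tsv --gamma --out corr.tsv
```

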