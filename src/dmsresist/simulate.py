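"""Synthetic pooled-selection count data with known ground-truth fitness.

The generator emulates the selection experiment at the level of variant
abundances and sequencing counts. Each variant v in condition c carries a
true fitness beta on the doubling-rate scale: its cell count multiplies by
``2**(d + beta)`` per sampling interval while wild-type multiplies by
``2**d`` (d = 2 doublings per interval by default). Sequencing of a sample
is multinomial: a fixed expected read depth is allocated across variants in
proportion to their latent abundance.

Ground-truth structure mirrors the observed score distributions: the
vehicle (DMSO) fitness of missense variants is a two-component mixture of
a wild-type-like mode at 0 and a loss-of-function mode near the dead level
-d; nonsense variants are dead everywhere; under an inhibitor every variant
is suppressed to a sensitive level except explicitly planted resistance
mutations, which grow at their stated beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .library import NONSENSE, SYNONYMOUS, Variant, library_frame
from .panel import DMSO

COUNT_COLUMNS = [
    "variant",
    "position",
    "wt_aa",
    "mut_aa",
    "condition",
    "replicate",
    "timepoint",
    "count",
]


@dataclass
class MixtureSpec:
    """Two-component DMSO fitness mixture for missense variants.

    ``wt_weight`` of the mass sits in a wild-type-like mode centered at 0;
    the rest in a loss-of-function mode centered at ``lof_mean`` (defaults
    to the dead level -d at draw time when None).
    """

    wt_weight: float = 0.6
    wt_mean: float = 0.0
    wt_sd: float = 0.2
    lof_mean: float | None = None
    lof_sd: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.wt_weight <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")


@dataclass(frozen=True)
class ResistanceEffect:
    """A planted inhibitor-specific resistance mutation.

    ``beta`` is the fitness under ``condition``; ``dmso_beta`` is the
    variant's vehicle fitness, mildly deleterious by default so the planted
    ground truth satisfies the resistance definition's beta_DMSO <= 0 arm.
    """

    position: int
    mut_aa: str
    condition: str
    beta: float
    dmso_beta: float = -0.2


@dataclass
class SimConfig:
    """Simulation knobs: depth, initial pool, mixture, planted effects."""

    depth_per_sample: float = 1_000_000.0
    pseudo_initial_count: float = 200.0
    dmso_mixture: MixtureSpec = field(default_factory=MixtureSpec)
    resistance_spec: tuple[ResistanceEffect, ...] = ()
    sensitive_level: float | None = None  # None -> dead level -d
    noiseless: bool = False
    sampling: str = "multinomial"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_sample < 0:
            raise ValueError("sequencing depth must be non-negative")
        if self.pseudo_initial_count <= 0:
            raise ValueError("initial cell-equivalent per variant must be positive")
        if self.sampling not in ("multinomial", "poisson"):
            raise ValueError(f"unknown sampling model {self.sampling!r}")
        self.resistance_spec = tuple(self.resistance_spec)


@dataclass
class GroundTruth:
    """True fitness per (variant, condition) plus the library it covers."""

    beta: pd.DataFrame  # index: variant name; columns: conditions
    variants: pd.DataFrame  # library_frame output
    seed: int

    def lookup(self, variant: str, condition: str) -> float:
        return float(self.beta.at[variant, condition])


def draw_ground_truth(
    library: list[Variant],
    design: ExperimentDesign,
    cfg: SimConfig,
) -> GroundTruth:
    """Draw a ground-truth fitness table for every (variant, condition).

    Synonymous variants are 0 everywhere (the wild-type-normalization
    convention); nonsense variants sit at the dead level -d everywhere;
    missense DMSO fitness comes from the two-component mixture; inhibitor
    fitness is ``min(beta_DMSO, sensitive_level)`` except planted
    resistance entries, which receive their stated beta (and dmso_beta).
    """
    d = design.wt_doublings_per_interval
    mix = cfg.dmso_mixture
    lof_mean = -d if mix.lof_mean is None else mix.lof_mean
    sensitive = -d if cfg.sensitive_level is None else cfg.sensitive_level

    frame = library_frame(library)
    names = frame["variant"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))

    n = len(frame)
    is_syn = (frame["vclass"] == SYNONYMOUS).to_numpy()
    is_non = (frame["vclass"] == NONSENSE).to_numpy()

    comp_lof = rng.random(n) >= mix.wt_weight
    dmso = np.where(
        comp_lof,
        rng.normal(lof_mean, mix.lof_sd, size=n),
        rng.normal(mix.wt_mean, mix.wt_sd, size=n),
    )
    dmso[is_syn] = 0.0
    dmso[is_non] = -d

    beta = pd.DataFrame(index=names, columns=list(design.conditions), dtype=float)
    for cond in design.conditions:
        if cond == DMSO:
            beta[cond] = dmso
        else:
            col = np.minimum(dmso, sensitive)
            col[is_syn] = 0.0
            col[is_non] = -d
            beta[cond] = col

    for eff in cfg.resistance_spec:
        target = frame.loc[
            (frame["position"] == eff.position) & (frame["mut_aa"] == eff.mut_aa),
            "variant",
        ]
        if target.empty:
            raise KeyError(
                f"planted effect names variant {eff.mut_aa}@{eff.position} "
                "absent from the library"
            )
        if (
            frame.loc[target.index[0], "vclass"] == SYNONYMOUS
        ):  # would break the wild-type-normalization anchor
            raise ValueError(
                f"cannot plant an effect on synonymous variant "
                f"{target.iloc[0]}: synonymous fitness defines the "
                "wild-type zero"
            )
        if eff.condition not in beta.columns:
            raise KeyError(f"planted effect names unknown condition {eff.condition!r}")
        name = target.iloc[0]
        beta.at[name, eff.condition] = eff.beta
        if DMSO in beta.columns:
            beta.at[name, DMSO] = eff.dmso_beta

    return GroundTruth(beta=beta, variants=frame, seed=cfg.seed)


def _sample_rng(seed: int, replicate: int, cond_idx: int, timepoint: int):
    """Stable per-(replicate, condition, time point) random stream."""
    ss = np.random.SeedSequence(seed, spawn_key=(1, replicate, cond_idx, timepoint))
    return np.random.default_rng(ss)


def simulate_experiment(
    truth: GroundTruth,
    design: ExperimentDesign,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Simulate sequencing counts for one library under the design.

    Latent abundance propagates ``N_v(t) = N0 * 2**((d + beta_vc) * t)``
    per condition; each (condition, replicate, time point) sample draws
    counts multinomially with expected total ``depth_per_sample`` over the
    variant abundance shares (Poisson per variant as a config option). T0
    is drawn once per replicate and shared across conditions when the
    design declares a shared T0. Noiseless mode emits the exact expected
    (float) counts so downstream scoring recovers beta to float tolerance.

    Returns the long-format count table (see :data:`COUNT_COLUMNS`).
    """
    d = design.wt_doublings_per_interval
    frame = truth.variants
    names = frame["variant"].to_numpy()
    n = len(names)
    T = design.n_timepoints
    depth = cfg.depth_per_sample

    missing = [c for c in design.conditions if c not in truth.beta.columns]
    if missing:
        raise KeyError(f"ground truth lacks conditions {missing}")

    def draw(p: np.ndarray, rng) -> np.ndarray:
        if cfg.noiseless:
            return depth * p
        if cfg.sampling == "multinomial":
            return rng.multinomial(int(round(depth)), p).astype(float)
        return rng.poisson(depth * p).astype(float)

    chunks: list[pd.DataFrame] = []
    base = frame[["variant", "position", "wt_aa", "mut_aa"]]
    p0 = np.full(n, 1.0 / n)  # uniform starting pool

    for rep in range(1, design.n_replicates + 1):
        t0_shared = None
        if design.shared_t0:
            t0_shared = draw(p0, _sample_rng(cfg.seed, rep, 0, 0))
        for ci, cond in enumerate(design.conditions):
            beta = truth.beta[cond].reindex(names).to_numpy(dtype=float)
            growth = d + beta  # doublings per interval for this condition
            for t in range(T):
                if t == 0:
                    counts = (
                        t0_shared
                        if t0_shared is not None
                        else draw(p0, _sample_rng(cfg.seed, rep, ci + 1, 0))
                    )
                else:
                    logab = growth * t  # log2 abundance relative to N0
                    logab = logab - logab.max()  # stabilize before exp
                    ab = np.exp2(logab)
                    p = ab / ab.sum()
                    counts = draw(p, _sample_rng(cfg.seed, rep, ci + 1, t))
                chunk = base.copy()
                chunk["condition"] = cond
                chunk["replicate"] = rep
                chunk["timepoint"] = t
                chunk["count"] = counts
                chunks.append(chunk)

    out = pd.concat(chunks, ignore_index=True)[COUNT_COLUMNS]
    if not cfg.noiseless:
        out["count"] = out["count"].astype(np.int64)
    return out
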