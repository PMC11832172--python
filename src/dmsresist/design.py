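"""Pooled-selection experimental design arithmetic.

The screen grows Ba/F3 cells carrying the variant library under IL-3
withdrawal, split across one vehicle (DMSO) and eleven inhibitor
conditions, each held at its IC50. Sequencing samples are taken at T0
(pre-selection, shared across conditions within a replicate) and at three
post-selection harvests spaced every two wild-type cell doublings (~72 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import DEFAULT_CONDITIONS, DMSO


@dataclass
class ExperimentDesign:
    """Design of the pooled competition experiment.

    Attributes
    ----------
    n_libraries
        Independent variant libraries screened in parallel (the study runs
        the wild-type and exon-14-skipped intracellular-domain backgrounds).
    n_replicates
        Biological replicates per library.
    conditions
        Selection conditions; must include the vehicle control for any
        recentering analysis.
    n_post_timepoints
        Harvests after T0, so each trajectory has ``n_post_timepoints + 1``
        time points.
    shared_t0
        Whether the T0 sample is taken once per replicate before the pool
        is split across conditions.
    wt_doublings_per_interval
        Wild-type growth d, in cell doublings per sampling interval; growth
        is cadenced so this is the same in every condition.
    """

    n_libraries: int = 2
    n_replicates: int = 3
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_post_timepoints: int = 3
    shared_t0: bool = True
    wt_doublings_per_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.n_libraries < 1 or self.n_replicates < 1:
            raise ValueError("need at least one library and one replicate")
        if self.n_post_timepoints < 1:
            raise ValueError("need at least one post-selection time point")
        if self.wt_doublings_per_interval <= 0:
            raise ValueError("wild-type doubling rate must be positive")
        if len(self.conditions) == 0:
            raise ValueError("need at least one condition")
        self.conditions = tuple(self.conditions)

    @property
    def n_timepoints(self) -> int:
        return self.n_post_timepoints + 1

    @property
    def has_dmso(self) -> bool:
        return DMSO in self.conditions


def count_samples(design: ExperimentDesign) -> int:
    """Number of sequencing samples the design requires.

    T0 samples: one per (library, replicate) when shared, else one per
    condition as well. Post-selection: one per (library, replicate,
    condition, post time point). The study's default design (2 libraries,
    3 replicates, 12 conditions, shared T0, 3 post-T0 harvests) gives 222.
    """
    t0 = design.n_libraries * design.n_replicates
    if not design.shared_t0:
        t0 *= len(design.conditions)
    post = (
        design.n_libraries
        * design.n_replicates
        * len(design.conditions)
        * design.n_post_timepoints
    )
    return t0 + post
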