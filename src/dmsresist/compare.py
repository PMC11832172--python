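"""Pairwise condition-similarity analysis on fitness score matrices.

Pearson correlation between conditions over shared variants, computed
pairwise-complete so that per-condition filter differences do not null out
the matrix; the companion ``n_pairs`` matrix makes sparsity visible.
Either the raw beta matrix or the vehicle-recentered gamma matrix (vehicle
column dropped) can be correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .panel import DMSO
from .scoring import ScoreSet, dmso_recenter


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson-r matrix over conditions with pair counts."""

    r: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return list(self.r.columns)


def pearson_matrix(
    scores: ScoreSet,
    use_gamma: bool = False,
    min_pairs: int = 3,
    dmso: str = DMSO,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation between condition columns.

    ``use_gamma`` correlates vehicle-recentered scores with the vehicle
    column dropped. Pairs with fewer than ``min_pairs`` shared variants
    get a missing cell and a warning.
    """
    if use_gamma:
        mat = dmso_recenter(scores, dmso=dmso).beta.drop(columns=[dmso])
    else:
        mat = scores.beta
    mat = mat.astype(float)

    r = mat.corr(method="pearson", min_periods=min_pairs)
    notna = mat.notna().astype(int)
    n_pairs = notna.T @ notna

    sparse = n_pairs < min_pairs
    if sparse.to_numpy().any():
        bad = [
            (a, b)
            for a in n_pairs.index
            for b in n_pairs.columns
            if a < b and sparse.at[a, b]
        ]
        if bad:
            warnings.warn(
                f"condition pairs with < {min_pairs} shared variants: {bad}",
                stacklevel=2,
            )
    return CorrelationMatrix(r=r, n_pairs=n_pairs)
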