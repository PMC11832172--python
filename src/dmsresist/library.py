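"""Saturation-mutagenesis library enumeration for the MET kinase domain.

The screened library tiles residue positions 1059-1345 (UniProt MET
numbering: the full kinase domain 1071-1345 plus a short juxtamembrane
stretch), substituting each position with all 20 amino acids -- 19 missense
changes plus the synonymous wild-type codon -- and adding an early-stop
control roughly every 11 positions as a dead-variant anchor.

Variants are value objects; a library is an ordered list of them
(position-major, mutant amino acid alphabetical, stop last), and
:func:`library_frame` gives the tabular view used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

KD_START = 1059
KD_END = 1345

MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONSENSE = "nonsense"

_SYNTHETIC_WT_SEED = 105_913_45  # fixed: the default sequence is a constant


@dataclass(frozen=True, order=True)
class Variant:
    """A single amino-acid substitution in the kinase-domain library.

    ``vclass`` is derived: synonymous iff ``mut_aa == wt_aa``, nonsense iff
    ``mut_aa == '*'``, missense otherwise.
    """

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if not KD_START <= self.position <= KD_END:
            raise ValueError(
                f"position {self.position} outside kinase-domain range "
                f"{KD_START}-{KD_END}"
            )
        if self.wt_aa not in AA_ALPHABET:
            raise ValueError(f"invalid wild-type residue {self.wt_aa!r}")
        if self.mut_aa != STOP and self.mut_aa not in AA_ALPHABET:
            raise ValueError(f"invalid mutant residue {self.mut_aa!r}")

    @property
    def vclass(self) -> str:
        if self.mut_aa == STOP:
            return NONSENSE
        if self.mut_aa == self.wt_aa:
            return SYNONYMOUS
        return MISSENSE

    @property
    def name(self) -> str:
        """Conventional label, e.g. ``D1228N``, ``V1092V``, ``E1172*``."""
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def from_name(cls, name: str) -> "Variant":
        wt, pos, mut = name[0], name[1:-1], name[-1]
        return cls(position=int(pos), wt_aa=wt, mut_aa=mut)


def synthetic_wt_sequence(start_pos: int = KD_START, end_pos: int = KD_END) -> str:
    """Deterministic synthetic stand-in for the wild-type kinase sequence.

    The real MET sequence is not bundled; any fixed sequence supports the
    simulation and scoring machinery, and callers with the true sequence
    pass it to :func:`build_library` instead.
    """
    rng = np.random.default_rng(_SYNTHETIC_WT_SEED)
    n = end_pos - start_pos + 1
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def stop_positions(start_pos: int, end_pos: int, stop_spacing: int) -> list[int]:
    """Early-stop control sites: start_pos, start_pos+spacing, ... <= end_pos."""
    if stop_spacing < 1:
        raise ValueError("stop_spacing must be >= 1")
    return list(range(start_pos, end_pos + 1, stop_spacing))


def build_library(
    start_pos: int = KD_START,
    end_pos: int = KD_END,
    stop_spacing: int = 11,
    wt_sequence: str | None = None,
) -> list[Variant]:
    """Enumerate the saturation-mutagenesis library over a residue range.

    Every position yields the 20 amino-acid substitutions (19 missense + 1
    synonymous); every ``stop_spacing``-th position, anchored at
    ``start_pos``, additionally yields a nonsense control. Ordering is
    position-major, mutant residue alphabetical, stop last, so enumeration
    is idempotent and order-stable.

    Parameters
    ----------
    wt_sequence
        One-letter wild-type sequence covering ``start_pos..end_pos``.
        Defaults to the package's synthetic stand-in sequence.
    """
    if start_pos > end_pos:
        raise ValueError(f"invalid residue range {start_pos}..{end_pos}")
    if start_pos < KD_START or end_pos > KD_END:
        raise ValueError("range must lie within the kinase-domain library span")
    if wt_sequence is None:
        wt_sequence = synthetic_wt_sequence(start_pos, end_pos)
    n = end_pos - start_pos + 1
    if len(wt_sequence) != n:
        raise ValueError(
            f"wild-type sequence length {len(wt_sequence)} != range length {n}"
        )
    stops = set(stop_positions(start_pos, end_pos, stop_spacing))
    out: list[Variant] = []
    for offset in range(n):
        pos = start_pos + offset
        wt = wt_sequence[offset]
        for aa in AA_ALPHABET:
            out.append(Variant(position=pos, wt_aa=wt, mut_aa=aa))
        if pos in stops:
            out.append(Variant(position=pos, wt_aa=wt, mut_aa=STOP))
    return out


def library_frame(library: list[Variant]) -> pd.DataFrame:
    """Tabular view of a library: variant, position, wt_aa, mut_aa, vclass."""
    return pd.DataFrame(
        {
            "variant": [v.name for v in library],
            "position": [v.position for v in library],
            "wt_aa": [v.wt_aa for v in library],
            "mut_aa": [v.mut_aa for v in library],
            "vclass": [v.vclass for v in library],
        }
    )
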