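"""Parallel-reaction-monitoring targets and quantification for the
ubiquitylated H2A C-terminal peptides.

A PRM target is a triply charged diGly peptide precursor plus its singly
charged y3..y7 fragment ions; quantification is the plain sum of the
five fragment intensities (equal total protein input across samples is a
pipeline precondition, so no normalization is applied), and groups are
compared by fold change of means with a Student's t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import Peptide, fragment_mz, make_modification, precursor_mz

__all__ = [
    "PRM_IONS",
    "PRMTarget",
    "PRMQuant",
    "GroupComparison",
    "build_prm_target",
    "quantify_prm",
    "group_compare",
    "target_table",
]

PRM_IONS = ("y3", "y4", "y5", "y6", "y7")

#: The three conserved ubiquitylated H2A C-terminal peptides monitored
#: by the assay, keyed by species.
UBH2A_PEPTIDES: dict[str, str] = {
    "fly": "LLSGVTIAQGGVLPNIQAVLLPKK",
    "mouse": "VTIAQGGVLPNIQAVLLPKK",
    "monkey": "LLGGVTIAQGGVLPNIQAVLLPKK",
}


@dataclass(frozen=True)
class PRMTarget:
    """A targeted precursor with its y3..y7 fragment m/z (charge 1)."""

    peptide: Peptide
    precursor_mz: float
    fragments: tuple[tuple[str, float], ...]

    def fragment_map(self) -> dict[str, float]:
        return dict(self.fragments)


@dataclass(frozen=True)
class PRMQuant:
    """Summed y3..y7 intensity for one sample."""

    sample_id: str
    group: str
    summed_intensity: float


@dataclass(frozen=True)
class GroupComparison:
    fold_change: float     # mean(old) / mean(young); nan when undefined
    t_p: float
    flagged: str = ""


def build_prm_target(
    sequence: str, digly_position: int, charge: int = 3
) -> PRMTarget:
    """PRM target for a diGly peptide.

    The modified lysine must be given explicitly (precursor m/z does not
    depend on it, but fragment identities do: any y ion spanning the
    modified residue carries the +114.04293 remnant).
    """
    if len(sequence) < 8:
        raise ValueError(
            f"peptide of length {len(sequence)} too short for y7 (need >= 8)"
        )
    if sequence[digly_position - 1] != "K":
        raise ValueError(
            f"diGly site {digly_position} is {sequence[digly_position - 1]!r}, "
            "expected K"
        )
    pep = Peptide(
        sequence,
        modifications=(make_modification("diGly", digly_position),),
        charge=charge,
    )
    frags = tuple(
        (f"y{n}", fragment_mz(pep, "y", n, charge=1)) for n in range(3, 8)
    )
    return PRMTarget(pep, precursor_mz(pep, charge), frags)


def quantify_prm(
    fragment_intensities: Mapping[str, float],
    sample_id: str = "",
    group: str = "",
) -> PRMQuant:
    """Summed MS intensity of the y3..y7 ions, no normalization.

    Missing ions are treated as zero with a warning; negative
    intensities are rejected.
    """
    total = 0.0
    for ion in PRM_IONS:
        if ion not in fragment_intensities:
            warnings.warn(f"ion {ion} missing for sample {sample_id!r}; using 0")
            continue
        v = float(fragment_intensities[ion])
        if v < 0:
            raise ValueError(f"negative intensity for {ion}: {v}")
        total += v
    return PRMQuant(sample_id, group, total)


def group_compare(
    young: Sequence[PRMQuant | float],
    old: Sequence[PRMQuant | float],
    equal_var: bool = True,
) -> GroupComparison:
    """Old/young fold change of group means with a two-sided Student's t
    test (equal-variance by default; Welch via ``equal_var=False``)."""

    def values(group):
        return np.array(
            [q.summed_intensity if isinstance(q, PRMQuant) else float(q) for q in group]
        )

    y, o = values(young), values(old)
    if len(y) < 2 or len(o) < 2:
        raise ValueError("need >= 2 samples per group")
    res = stats.ttest_ind(o, y, equal_var=equal_var)
    if y.mean() == 0:
        return GroupComparison(np.nan, float(res.pvalue), flagged="zero-young-mean")
    return GroupComparison(float(o.mean() / y.mean()), float(res.pvalue))


def target_table(targets: Iterable[PRMTarget]) -> pd.DataFrame:
    """PRM target table: peptide, modifications, charge, precursor and
    fragment m/z — the layout fed to the instrument method editor."""
    rows = []
    for t in targets:
        mods = ";".join(
            f"{m.position}:{m.name}:{m.delta_mass:.5f}" for m in t.peptide.modifications
        )
        row = {
            "peptide": t.peptide.sequence,
            "modifications": mods,
            "charge": t.peptide.charge,
            "precursor_mz": round(t.precursor_mz, 4),
        }
        for ion, mz in t.fragments:
            row[f"{ion}_mz"] = round(mz, 4)
        rows.append(row)
    return pd.DataFrame(rows)
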