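"""Peptide-level chemistry for pulse-15N quantification.

Monoisotopic masses, precursor and b/y fragment m/z, theoretical isotope
envelopes at arbitrary heavy-nitrogen enrichment, and in-silico tryptic
digestion.  Residue and element monoisotopic masses come from pyteomics'
IUPAC/CODATA tables; the proton mass is kept as an explicit constant so
that reported m/z values are reproducible to four decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "NATURAL_N15_ABUNDANCE",
    "Modification",
    "Peptide",
    "IsotopeEnvelope",
    "DigestPeptide",
    "MODIFICATION_TABLE",
    "make_modification",
    "peptide_composition",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_mz",
    "isotope_envelope",
    "tryptic_digest",
    "read_fasta",
]

#: Mass of a proton in Da.  Adding z protons and dividing by z converts a
#: neutral monoisotopic mass to the m/z of the z+ charge state.
PROTON_MASS = 1.007276

#: Monoisotopic mass of H2O; a peptide is the residue chain plus one water.
WATER_MASS = _pmass.calculate_mass(formula="H2O")

#: Natural abundance of 15N; envelopes computed at this enrichment
#: reproduce the unlabeled (light-channel) isotope pattern.
NATURAL_N15_ABUNDANCE = 0.003642

#: Heavy-channel atomic 15N enrichment used by default for fully labeled
#: material.  Peptide-level labeling efficiency in a pulse-15N design is
#: higher still because a peptide with many N atoms is heavy if any
#: detectable fraction of its envelope is shifted.
DEFAULT_N15_ENRICHMENT = 0.995

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Modification:
    """A fixed or variable modification at a 1-based residue position.

    ``composition`` is optional: modifications registered only as mass
    shifts contribute to masses and m/z but not to isotope-envelope
    element counts.
    """

    position: int
    name: str
    delta_mass: float
    composition: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_mass):
            raise ValueError(f"modification {self.name!r}: delta_mass must be finite")


# Shipped modification formulas.  delta masses are derived from the
# elemental formulas so they are exact to the underlying atomic masses;
# rounded to 2 decimals they reproduce +57.02, +15.99 and +114.04.
_MOD_FORMULAS: dict[str, str] = {
    "carbamidomethyl": "C2H3NO",   # iodoacetamide adduct on Cys
    "oxidation": "O",              # Met oxidation
    "diGly": "C4H6N2O2",           # Gly-Gly ubiquitin remnant on Lys
}

MODIFICATION_TABLE: dict[str, float] = {
    name: _pmass.calculate_mass(formula=f) for name, f in _MOD_FORMULAS.items()
}


def make_modification(name: str, position: int) -> Modification:
    """Build a :class:`Modification` from the shipped table."""
    if name not in MODIFICATION_TABLE:
        raise KeyError(
            f"unknown modification {name!r}; known: {sorted(MODIFICATION_TABLE)}"
        )
    comp = dict(_pmass.Composition(formula=_MOD_FORMULAS[name]))
    return Modification(position, name, MODIFICATION_TABLE[name], comp)


@dataclass(frozen=True)
class Peptide:
    """A modified peptide sequence, optionally with a charge state."""

    sequence: str
    modifications: tuple[Modification, ...] = ()
    charge: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad or not self.sequence:
            offender = sorted(bad)[0] if bad else "<empty>"
            raise ValueError(
                f"invalid residue code {offender!r} in sequence {self.sequence!r}"
            )
        for mod in self.modifications:
            if not 1 <= mod.position <= len(self.sequence):
                raise ValueError(
                    f"modification {mod.name!r} at position {mod.position} outside "
                    f"peptide of length {len(self.sequence)}"
                )
        if self.charge is not None and self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Truncated, renormalized isotopologue envelope.

    ``masses`` are strictly increasing; ``abundances`` sum to 1 within
    1e-9 after truncation renormalization.
    """

    masses: tuple[float, ...]
    abundances: tuple[float, ...]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.masses, self.abundances))

    def most_abundant_mass(self) -> float:
        return self.masses[int(np.argmax(self.abundances))]


def peptide_composition(peptide: Peptide) -> dict[str, int]:
    """Elemental composition of a peptide: residue sum + one water + any
    modification formulas.  Mass-shift-only modifications are skipped
    (they participate in masses, not element counts)."""
    comp = _pmass.Composition(sequence=peptide.sequence)
    for mod in peptide.modifications:
        if mod.composition is not None:
            for el, n in mod.composition.items():
                comp[el] = comp.get(el, 0) + n
    return {el: int(n) for el, n in comp.items() if n}


def monoisotopic_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification
    mass shifts (additive)."""
    base = _pmass.calculate_mass(sequence=peptide.sequence)
    return base + sum(m.delta_mass for m in peptide.modifications)


def precursor_mz(peptide: Peptide, charge: int | None = None) -> float:
    """m/z of the [M + zH]^z+ precursor."""
    z = charge if charge is not None else peptide.charge
    if z is None or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (monoisotopic_mass(peptide) + z * PROTON_MASS) / z


def fragment_mz(peptide: Peptide, ion_series: str, n: int, charge: int = 1) -> float:
    """m/z of the b_n or y_n backbone fragment ion.

    y ions carry the n C-terminal residues plus water; b ions carry the
    n N-terminal residues without water.  Modifications on residues
    inside the fragment span are included.
    """
    if ion_series not in ("b", "y"):
        raise ValueError(f"ion_series must be 'b' or 'y', got {ion_series!r}")
    L = len(peptide.sequence)
    if not 1 <= n < L:
        raise ValueError(f"ion length {n} out of range [1, {L - 1}]")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if ion_series == "y":
        span = range(L - n + 1, L + 1)  # 1-based residue positions in fragment
        sub = peptide.sequence[L - n:]
        residue_mass = _pmass.calculate_mass(sequence=sub) - WATER_MASS
        neutral = residue_mass + WATER_MASS
    else:
        span = range(1, n + 1)
        sub = peptide.sequence[:n]
        neutral = _pmass.calculate_mass(sequence=sub) - WATER_MASS
    neutral += sum(m.delta_mass for m in peptide.modifications if m.position in span)
    return (neutral + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# Isotope envelopes
# ---------------------------------------------------------------------------

def _element_isotopes(element: str, n15_enrichment: float) -> list[tuple[int, float, float]]:
    """(neutron offset, mass, abundance) for each stable isotope of
    ``element``.  The nitrogen channel uses the supplied 15N abundance."""
    if element == "N":
        m14 = _pmass.nist_mass["N"][14][0]
        m15 = _pmass.nist_mass["N"][15][0]
        p = n15_enrichment
        return [(0, m14, 1.0 - p), (1, m15, p)]
    table = _pmass.nist_mass[element]
    isos = [(a, m, ab) for a, (m, ab) in table.items() if a != 0 and ab > 0.0]
    if not isos:
        raise ValueError(f"no isotope abundance data for element {element!r}")
    isos.sort()
    a0 = isos[0][0]
    return [(a - a0, m, ab) for a, m, ab in isos]


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]):
    """Convolve two (abundance, mass-expectation) envelopes indexed by
    neutron offset.  mass-expectation[k] = sum over isotopologues in bin k
    of probability * mass, so bin mass = expectation / abundance."""
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)
    m = np.convolve(ma, pb) + np.convolve(pa, mb)
    return p, m


def _power(dist: tuple[np.ndarray, np.ndarray], n: int):
    """Envelope of n identical atoms by binary exponentiation."""
    result = (np.array([1.0]), np.array([0.0]))
    base = dist
    while n > 0:
        if n & 1:
            result = _convolve(result, base)
        base = _convolve(base, base)
        n >>= 1
    return result


def isotope_envelope(
    composition: Mapping[str, int],
    n15_enrichment: float = NATURAL_N15_ABUNDANCE,
    truncate_at: float = 0.999,
) -> IsotopeEnvelope:
    """Theoretical isotope envelope of an elemental composition.

    Peaks are aggregated by total neutron count (nominal isotopologue),
    each reported at the abundance-weighted mean mass of its bin.  The
    envelope is truncated once cumulative abundance reaches
    ``truncate_at`` and renormalized to sum to 1.

    ``n15_enrichment`` is the atomic fraction of 15N; the natural value
    reproduces the unlabeled envelope, 0.995 the heavy channel of a
    metabolically labeled sample.
    """
    if not 0.0 <= n15_enrichment <= 1.0:
        raise ValueError(f"n15_enrichment must be in [0, 1], got {n15_enrichment}")
    total = (np.array([1.0]), np.array([0.0]))
    for el, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for element {el!r}: {count}")
        if count == 0:
            continue
        isos = _element_isotopes(el, n15_enrichment)
        offsets = [o for o, _, _ in isos]
        p = np.zeros(max(offsets) + 1)
        m = np.zeros_like(p)
        for o, mass_i, ab in isos:
            p[o] += ab
            m[o] += ab * mass_i
        total = _convolve(total, _power((p, m), int(count)))
    p, mexp = total
    keep = p > 0.0
    masses = mexp[keep] / p[keep]
    abunds = p[keep]
    order = np.argsort(masses)
    masses, abunds = masses[order], abunds[order]
    cum = np.cumsum(abunds)
    cut = int(np.searchsorted(cum, truncate_at) + 1)
    masses, abunds = masses[:cut], abunds[:cut]
    abunds = abunds / abunds.sum()
    return IsotopeEnvelope(tuple(masses.tolist()), tuple(abunds.tolist()))


# ---------------------------------------------------------------------------
# In-silico digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide with its 1-based inclusive span in the protein."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def tryptic_digest(
    protein_sequence: str, missed_cleavages: int = 0
) -> list[DigestPeptide]:
    """Tryptic peptides with protein-coordinate spans.

    Cleaves after K or R except when the next residue is P; emits every
    peptide with 0..``missed_cleavages`` internal cleavage sites.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = protein_sequence
    if not seq:
        return []
    # cut points: index i means a cleavage between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, len(seq)):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(len(seq))
    peptides: list[DigestPeptide] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[i], cuts[j]
            peptides.append(
                DigestPeptide(seq[start:end], start + 1, end, j - i - 1)
            )
    return peptides


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader: first token of the description line is the
    protein id; sequences are uppercased with whitespace stripped."""
    proteins: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    proteins[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.upper())
    if name is not None:
        proteins[name] = "".join(chunks)
    return proteins
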