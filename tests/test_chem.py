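"""Peptide chemistry: masses, m/z, envelopes, digestion."""

import itertools
import math

import numpy as np
import pytest

from pulsen15.chem import (
    MODIFICATION_TABLE,
    NATURAL_N15_ABUNDANCE,
    PROTON_MASS,
    WATER_MASS,
    Peptide,
    fragment_mz,
    isotope_envelope,
    make_modification,
    monoisotopic_mass,
    peptide_composition,
    precursor_mz,
    tryptic_digest,
)
from pyteomics import mass as pmass


class TestComposition:
    def test_glycine_is_residue_plus_water(self):
        comp = peptide_composition(Peptide("G"))
        assert comp == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_diglycine_hand_sum(self):
        assert peptide_composition(Peptide("GG")) == {"C": 4, "H": 8, "N": 2, "O": 3}

    def test_h2a_peptide_composition_mass(self):
        comp = peptide_composition(Peptide("LLSGVTIAQGGVLPNIQAVLLPKK"))
        m = sum(pmass.nist_mass[el][0][0] * n for el, n in comp.items())
        assert m == pytest.approx(2428.478, abs=1e-3)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            Peptide("GBG")

    def test_mod_position_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            Peptide("GG", modifications=(make_modification("diGly", 5),))


class TestMass:
    def test_glycine_monoisotopic(self):
        assert monoisotopic_mass(Peptide("G")) == pytest.approx(75.03203, abs=1e-5)

    def test_zero_delta_mod_is_identity(self):
        from pulsen15.chem import Modification

        plain = monoisotopic_mass(Peptide("PEPTIDE"))
        modded = monoisotopic_mass(
            Peptide("PEPTIDE", modifications=(Modification(1, "null", 0.0),))
        )
        assert plain == modded

    def test_mouse_ub_peptide_mass_back_calculated_from_mz(self):
        pep = Peptide("VTIAQGGVLPNIQAVLLPKK",
                      modifications=(make_modification("diGly", 19),))
        expected = 725.1071 * 3 - 3 * PROTON_MASS
        assert monoisotopic_mass(pep) == pytest.approx(expected, abs=2e-3)

    def test_modification_table_printed_shifts(self):
        assert round(MODIFICATION_TABLE["diGly"], 2) == 114.04
        assert round(MODIFICATION_TABLE["carbamidomethyl"], 2) == 57.02
        assert round(MODIFICATION_TABLE["oxidation"], 2) == 15.99


class TestPrecursorMz:
    @pytest.mark.parametrize(
        "sequence, mz",
        [
            ("LLSGVTIAQGGVLPNIQAVLLPKK", 848.5143),
            ("VTIAQGGVLPNIQAVLLPKK", 725.1071),
            ("LLGGVTIAQGGVLPNIQAVLLPKK", 838.5108),
        ],
    )
    def test_ubh2a_triply_charged(self, sequence, mz):
        pep = Peptide(sequence,
                      modifications=(make_modification("diGly", len(sequence) - 1),))
        assert round(precursor_mz(pep, 3), 4) == mz

    def test_additive_in_modifications(self):
        base = Peptide("PEPTIDEK")
        mod = Peptide("PEPTIDEK", modifications=(make_modification("diGly", 8),))
        delta = precursor_mz(mod, 2) - precursor_mz(base, 2)
        assert delta == pytest.approx(MODIFICATION_TABLE["diGly"] / 2, abs=1e-12)

    @pytest.mark.parametrize("z", [0, -1])
    def test_nonpositive_charge_rejected(self, z):
        with pytest.raises(ValueError):
            precursor_mz(Peptide("PEPTIDEK"), z)


class TestFragmentMz:
    def test_y1_of_lysine_terminated_peptide(self):
        assert fragment_mz(Peptide("GGK"), "y", 1) == pytest.approx(147.11280, abs=1e-5)

    def test_ladder_conservation(self):
        pep = Peptide("ELVISLIVESK")
        L = len(pep)
        total = fragment_mz(pep, "y", L - 1) + fragment_mz(pep, "b", 1)
        assert total == pytest.approx(monoisotopic_mass(pep) + 2 * PROTON_MASS, abs=1e-9)

    def test_y3_with_digly_inside_fragment(self):
        pep = Peptide("LLSGVTIAQGGVLPNIQAVLLPKK",
                      modifications=(make_modification("diGly", 23),))
        assert fragment_mz(pep, "y", 3) == pytest.approx(486.30345, abs=1e-4)

    def test_y_ladder_steps_are_residue_masses(self):
        pep = Peptide("ACDEFGHIK")
        seq = pep.sequence
        for n in range(2, len(seq)):
            step = fragment_mz(pep, "y", n) - fragment_mz(pep, "y", n - 1)
            residue = pmass.calculate_mass(sequence=seq[len(seq) - n]) - WATER_MASS
            assert step == pytest.approx(residue, abs=1e-6)

    @pytest.mark.parametrize("n", [0, 9, 20])
    def test_out_of_range_ion_length(self, n):
        with pytest.raises(ValueError):
            fragment_mz(Peptide("ACDEFGHIK"), "y", n)


def brute_force_envelope(composition, n15_enrichment):
    """Independent oracle: enumerate every isotopologue count vector per
    element (multinomial), combine across elements by cartesian product,
    aggregate by total neutron offset with probability-weighted masses."""
    from pulsen15.chem import _element_isotopes

    per_element = []
    for el, n in composition.items():
        isos = _element_isotopes(el, n15_enrichment)
        states = []  # (offset_total, mass_total, probability) for n atoms
        ks = [k for k, _, _ in isos]
        for counts in itertools.product(range(n + 1), repeat=len(isos)):
            if sum(counts) != n:
                continue
            prob = math.factorial(n)
            off = 0
            m = 0.0
            for (k, mass_i, ab), c in zip(isos, counts):
                prob = prob // math.factorial(c)
                off += k * c
                m += mass_i * c
            p = prob * math.prod(ab ** c for (_, _, ab), c in zip(isos, counts))
            states.append((off, m, p))
        per_element.append(states)
    bins = {}
    for combo in itertools.product(*per_element):
        off = sum(s[0] for s in combo)
        m = sum(s[1] for s in combo)
        p = math.prod(s[2] for s in combo)
        a, me = bins.get(off, (0.0, 0.0))
        bins[off] = (a + p, me + p * m)
    offs = sorted(bins)
    abunds = np.array([bins[o][0] for o in offs])
    masses = np.array([bins[o][1] / bins[o][0] for o in offs])
    return masses, abunds


class TestIsotopeEnvelope:
    def test_single_nitrogen_closed_form(self):
        p = 0.37
        env = isotope_envelope({"N": 1}, n15_enrichment=p, truncate_at=1.0)
        assert env.abundances == pytest.approx((1 - p, p), abs=1e-12)

    def test_natural_abundance_base_peak_is_monoisotopic(self):
        comp = peptide_composition(Peptide("PEPTIDEK"))
        env = isotope_envelope(comp)
        mono = sum(pmass.nist_mass[el][0][0] * n for el, n in comp.items())
        assert env.most_abundant_mass() == pytest.approx(mono, abs=1e-6)

    @pytest.mark.parametrize("enrichment", [NATURAL_N15_ABUNDANCE, 0.5, 0.995])
    def test_matches_enumeration_oracle(self, enrichment):
        comp = peptide_composition(Peptide("GG"))  # C4H8N2O3, 17 atoms
        assert sum(comp.values()) <= 30
        masses, abunds = brute_force_envelope(comp, enrichment)
        env = isotope_envelope(comp, enrichment, truncate_at=1.0)
        assert np.allclose(env.abundances, abunds, atol=1e-9)
        assert np.allclose(env.masses, masses, atol=1e-9)

    def test_sulfur_bearing_molecule_against_oracle(self):
        comp = {"C": 2, "H": 5, "N": 1, "O": 2, "S": 1}  # cysteine-like
        masses, abunds = brute_force_envelope(comp, NATURAL_N15_ABUNDANCE)
        env = isotope_envelope(comp, truncate_at=1.0)
        assert np.allclose(env.abundances, abunds, atol=1e-9)

    def test_truncation_renormalizes_to_one(self):
        comp = peptide_composition(Peptide("LLSGVTIAQGGVLPNIQAVLLPKK"))
        env = isotope_envelope(comp, n15_enrichment=0.995)
        assert sum(env.abundances) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(env.masses) > 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            isotope_envelope({"C": -1})


class TestDigestion:
    def test_proline_suppression(self):
        peps = [p.sequence for p in tryptic_digest("AKPR", 0)]
        assert peps == ["AKPR"]

    def test_missed_cleavage_enumeration_with_spans(self):
        got0 = {(p.sequence, p.start, p.end) for p in tryptic_digest("AKRG", 0)}
        assert got0 == {("AK", 1, 2), ("R", 3, 3), ("G", 4, 4)}
        got1 = {(p.sequence, p.start, p.end) for p in tryptic_digest("AKRG", 1)}
        assert got1 == got0 | {("AKR", 1, 3), ("RG", 3, 4)}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_missed_partition_reconstructs_protein(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        peps = tryptic_digest(seq, 0)
        assert "".join(p.sequence for p in peps) == seq
        # spans tile the protein with 1-based inclusive coordinates
        pos = 1
        for p in peps:
            assert p.start == pos
            pos = p.end + 1

    def test_higher_missed_cleavage_is_superset(self):
        seq = "MKAVRPKLLGGKRES"
        sets = [
            {(p.sequence, p.start, p.end) for p in tryptic_digest(seq, k)}
            for k in range(3)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_empty_sequence(self):
        assert tryptic_digest("", 1) == []
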