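"""Theoretical isotope envelopes at natural and heavy 15N enrichment.

The light (14N) and heavy (15N) forms of the same peptide produce
distinct envelopes; the number of nitrogen atoms sets the spacing
between the pair, which is what makes paired-channel extraction
possible in a metabolic labeling experiment.
"""

from pulsen15.chem import (
    Peptide,
    isotope_envelope,
    make_modification,
    peptide_composition,
)

pep = Peptide("VTIAQGGVLPNIQAVLLPKK",
              modifications=(make_modification("diGly", 19),))
comp = peptide_composition(pep)
print(f"composition: {comp}  ({comp['N']} nitrogen atoms)")

for label, enrichment in [("light (natural 15N)", 0.003642),
                          ("heavy (99.5% 15N)", 0.995)]:
    env = isotope_envelope(comp, n15_enrichment=enrichment)
    top = sorted(env.peaks, key=lambda p: -p[1])[:5]
    print(f"\n{label} (five most abundant peaks):")
    for mass, ab in sorted(top):
        print(f"  {mass:10.4f} Da   {ab:6.3f}")

light = isotope_envelope(comp, 0.003642)
heavy = isotope_envelope(comp, 0.995)
shift = heavy.most_abundant_mass() - light.most_abundant_mass()
print(f"\nmost-abundant-peak shift light -> heavy: {shift:.3f} Da "
      f"(~1 Da per nitrogen, here {comp['N']} N)")
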