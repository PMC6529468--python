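"""Build PRM targets for the ubiquitylated H2A C-terminal peptides.

The three peptides (fly, mouse, monkey) carry one GlyGly remnant on the
internal lysine of the C-terminal KK motif and are monitored as 3+
precursors; the printed numbers are the m/z values a method editor
needs: the precursor and the singly charged y3..y7 fragments.
"""

from pulsen15.prm import UBH2A_PEPTIDES, build_prm_target, target_table

targets = []
for species, seq in UBH2A_PEPTIDES.items():
    target = build_prm_target(seq, digly_position=len(seq) - 1, charge=3)
    targets.append(target)
    print(f"{species:7s} {seq}  precursor {target.precursor_mz:.4f} (3+)")

print()
print(target_table(targets).to_string(index=False))
print()
print("Fragment m/z are identical across species because the three "
      "peptides share the same C-terminal seven residues (the y ions).")
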