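"""Simulate a pulse-15N experiment and recover per-protein turnover.

Generates a 300-protein head-tissue experiment (chase from day 5,
sampling at 5/30/60 d, multiplicative intensity noise 0.1, label purity
0.995), estimates each peptide's heavy/light ratio by regression through
the origin of the paired chromatograms, aggregates peptides to proteins
by the median (two peptides required), and compares the estimates with
the generator's ground truth.
"""

import numpy as np

from pulsen15.quantify import quantify_experiment
from pulsen15.simulate import GeneratorConfig, simulate_experiment

cfg = GeneratorConfig(n_proteins=300, rng_seed=42)
proteome, psms, xics = simulate_experiment(cfg)
print(f"simulated {len(proteome.proteins)} proteins, "
      f"{psms.shape[0]} PSMs, {xics['xic_id'].nunique()} XIC pairs")

total = quantify_experiment(psms, xics, mode="total")
truth = proteome.truth_table().set_index("protein_id")

errors = [
    abs(rec.n15_fraction - truth.loc[rec.protein_id, f"f_obs_{rec.age_days:g}d"])
    for rec in total.itertuples(index=False)
]
print(f"quantified {total['protein_id'].nunique()} proteins "
      f"(two-peptide rule) across {total['age_days'].nunique()} ages")
print(f"median |error| of the heavy-share estimate: {np.median(errors):.4f}")
print(f"fraction of protein/age estimates within 0.03 of truth: "
      f"{np.mean(np.array(errors) <= 0.03):.3f}")
print()
print("The heavy share (15N%) is the fraction of a protein's signal "
      "still carried by molecules made before the diet switch; a value "
      "near 1 at day 60 marks a protein that barely turns over.")
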