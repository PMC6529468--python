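"""Classify long-lived (LLP) and extremely long-lived (ELLP) proteins.

Runs the full chain on synthetic data for three tissue presets, flags
LLPs (>= 10% heavy signal retained at day 60), clusters trajectories
with fuzzy c-means, takes the slowest cluster with the > 70% individual
retention floor as ELLPs, and counts cross-tissue overlaps.
"""

from pulsen15.quantify import quantify_experiment
from pulsen15.simulate import GeneratorConfig, simulate_experiment
from pulsen15.turnover import (
    build_trajectory_matrix,
    classify_llp,
    fcm_cluster,
    identify_ellp,
    intersection_counts,
    llp_summary,
)

ellp_sets = {}
for tissue in ("head", "muscle", "testis"):
    cfg = GeneratorConfig(n_proteins=400, rng_seed=7).with_tissue_preset(tissue)
    proteome, psms, xics = simulate_experiment(cfg)
    total = quantify_experiment(psms, xics, mode="total")
    traj = build_trajectory_matrix(total)
    n_llp, n_total, pct = llp_summary(classify_llp(traj))
    fcm = fcm_cluster(traj, c=3, seed=7)
    ellps = identify_ellp(fcm, traj)
    ellp_sets[tissue] = ellps
    print(f"{tissue:7s} LLP {n_llp}/{n_total} ({pct}%)   ELLP {len(ellps)}")

print()
for combo, n in intersection_counts(ellp_sets).items():
    if len(combo) > 1:
        print(f"ELLPs shared by {' & '.join(combo)}: {n}")
print()
print("Muscle shows the largest long-lived share and testis the "
      "smallest, mirroring post-mitotic somatic tissue versus the "
      "mitotically active germline.  (Protein ids here are synthetic, "
      "so overlap counts reflect the simulation, not biology.)")
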