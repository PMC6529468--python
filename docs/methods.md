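# Methods

## Model

A pulse-chase metabolic labeling experiment is modeled per protein as a
two-pool system. All molecules present at the chase start (day 5) carry
the heavy label; molecules synthesized afterwards are light. The old
pool decays with first-order kinetics,

    f_old(t) = exp(−k · (t − t_chase)),   t ≥ t_chase = 5 d,

with a protein-specific rate constant k (per day). First-order decay is
the minimal kinetic model consistent with a single heavy-share readout
per age; nothing in the pipeline depends on it beyond the generator and
the ground-truth bookkeeping, so a different kinetic law would only
change the simulation, not the estimators.

The observable at the peptide level is the pair of co-eluting light and
heavy XICs. The heavy share of the signal is

    ¹⁵N% = I_H / (I_L + I_H) = p · f_old(t),

where p is the label purity — the probability that an old-pool molecule
actually presents as heavy. Recovery tests therefore compare estimates
against `f_obs = p · f_old`, the quantity the data actually encode; with
the default p = 0.995 the day-5 baseline is 99.5% heavy, matching the
near-complete labeling a pulse design achieves.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `label_purity` | 0.995 | atomic/molecular fraction of old-pool signal observed as heavy |
| `noise_sigma` | 0.1 | log-scale s.d. of multiplicative per-scan, per-channel intensity noise |
| `peptides_per_protein_mean` | 4 | 1 + Poisson peptide count per protein |
| `psm_depth` | 2 | expected extra PSMs per peptide per age |
| `ub_old_bias_beta` | 1 | odds multiplier favouring the old pool when a diGly PSM samples a molecule |
| `llp_threshold` | 0.10 | day-60 retention floor for LLP (inclusive) |
| `ellp_floor` | 0.70 | individual day-60 retention floor for ELLP (strict) |
| `r2_threshold` | 0.5 | squared-correlation filter on a paired-XIC fit |
| FCM `c`, `m` | 4, 2.0 | cluster count and fuzzifier |

The turnover-rate mixture has three log-normal components placed so the
median day-60 retention is ≈ 0.02 (fast), ≈ 0.40 (slow/long-lived) and
≈ 0.85 (extremely long-lived); absolute k values are calibration
choices for realistic fixtures, not measured quantities. Tissue presets
reweight the mixture (head 55% / muscle 79% / testis 31% combined
slow+extreme mass) to emulate the contrast between post-mitotic somatic
tissue and the mitotically active germline.

## Estimators and numerical choices

**Pair ratio.** The heavy/light ratio of one XIC pair is the
least-squares slope through the origin of heavy on light across scans,
`r = Σ l·h / Σ l²` — the paired-chromatogram regression family of
estimators used for metabolic-label quantification. Fit quality is the
squared Pearson correlation of the two traces; pairs below the
threshold fall back to the area ratio (or are rejected when the
fallback is disabled). A pair with zero light signal maps to proportion
1.0 rather than an infinite ratio so all downstream math stays in
[0, 1]; a pair with no signal at all is rejected with a zero-signal
flag. The proportion is r / (1 + r), which makes the estimate invariant
to any common intensity scaling.

**Protein roll-up.** Protein ¹⁵N% is the median of accepted peptide
proportions (median, not mean, for outlier robustness). Two peptides
per age are required in total-proteome mode; one ubiquitylated peptide
suffices in ubiquitylome mode. No renormalization of later ages to the
day-5 baseline is applied by default, since the baseline is ≈ 1 by
construction.

**Trajectory clustering.** Fuzzy c-means with the standard alternating
updates (membership `u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)}`, centers as
`u^m`-weighted means), objective `Σ u_ij^m d_ij²`. Trajectories are
clustered on the raw [0, 1] scale (no z-scoring: all dimensions share
units). Initialization is a random membership matrix from the seeded
RNG; five restarts keep the lowest objective; convergence is a maximum
center shift below 1e-6 or 300 iterations. A point within 1e-6 of a
center receives full membership there (zero-distance convention).
Hard assignment is argmax membership with ties to the lowest cluster
index. The default c = 4 is configurable and always reported; analyses
on the synthetic three-class mixture use c = 3 so the cluster structure
matches the number of generated kinetic classes — with more clusters
than classes the slowest class can split and the ELLP cluster rule
would pick up only a fragment of it.

**ELLP rule.** The ELLP cluster is the one whose center has the highest
day-60 value; membership of that cluster is intersected with the strict
individual floor ¹⁵N%(60 d) > 0.70.

**Ubiquitylome statistics.** Channel proportions are exact PSM counts
(no floating point). The ubiquitylome-vs-total comparison matches
proteins by id and emits both the fraction of proteins with a strictly
higher ubiquitylome ¹⁵N% (a paired summary) and the two-sided
Mann–Whitney–Wilcoxon rank-sum p on the matched value sets
(tie-corrected), plus a paired Wilcoxon signed-rank p, because a
scatter-plot comparison can be read either way. diGly sites are mapped
to protein coordinates as `site = peptide_start + mod_position − 1`
(all coordinates 1-based inclusive), deduplicated on (protein, site); a
diGly on a peptide's C-terminal residue is implausible under tryptic
cleavage and is logged but kept for audit.

**PRM.** Targets carry the 3+ precursor and singly charged y3–y7 ions;
fragment charge 1+ is assumed for these short y ions. The diGly site is
a required explicit parameter: precursor m/z is site-invariant but any
y ion spanning the modified lysine shifts by +114.04293 Da. For the
shipped H2A peptides the remnant is placed on the first lysine of the
C-terminal KK motif. Quantification is the plain sum of the five
fragment intensities — equal total protein input across samples is a
stated precondition, so no normalization is applied — and groups are
compared as fold change of means with an equal-variance Student's t
test (Welch by flag).

**Chemistry.** Residue and element monoisotopic masses and natural
abundances come from pyteomics' reference tables; the proton mass is
the constant 1.007276 Da. Isotope envelopes are computed by convolving
per-element isotope distributions (binary exponentiation over atom
counts), aggregating isotopologues by total neutron count and reporting
each nominal peak at its abundance-weighted mean mass; the nitrogen
channel takes an arbitrary ¹⁵N abundance, so the same routine produces
the light envelope (natural 0.003642) and the heavy envelope (default
enrichment 0.995). Envelopes are truncated at cumulative abundance
0.999 and renormalized. Modifications registered only as mass shifts
participate in masses but not in envelope element counts; diGly,
carbamidomethyl and oxidation ship with formulas. Tryptic digestion
cleaves after K/R except before P and enumerates 0..n missed
cleavages with 1-based inclusive protein spans. I and L are distinct
characters with identical mass.

## What the generator does and does not emulate

Emulated: the 3-age chase design, per-protein kinetic heterogeneity
(three-component rate mixture), peptide-level paired XICs with
Gaussian elution and multiplicative noise, PSM channel sampling with
label impurity, diGly sites with an old-pool sampling bias, and
tissue-level differences in kinetic composition.

Not emulated: raw spectra, peak detection/deisotoping, retention-time
drift, interference between co-eluting species, decoy/FDR search
behaviour, antibody enrichment efficiency, or correlations between
protein abundance and turnover. Passing recovery tests therefore show
that the estimators are correct and well-calibrated for the stated
noise model, not that they are robust to every artifact of real
LC-MS/MS data.

Determinism: one root seed per run; per-protein child RNG streams are
derived with `SeedSequence(seed, spawn_key=...)`, so outputs are
byte-identical across runs and stable under any iteration order.

## Problem sizes

Recovery analyses run at 500 proteins (≈ 2 000 peptides, ≈ 23 000 PSMs
across three ages), which gives the LLN-driven checks (noise-averaged
recovery, channel proportions, type-I calibration at 1 000 null
replicates of n = 100 vs 100) comfortable resolution at desk scale;
the whole synthetic pipeline completes in a few seconds.

## Known limitations

- The regression estimator assumes the light trace is noise-free as a
  regressor; at noise well above the default the slope acquires a mild
  attenuation bias. The median roll-up hides this for multi-peptide
  proteins.
- `f_obs = p · f_old` treats impurity as a constant channel leak; real
  impurity redistributes envelope mass in a composition-dependent way.
- FCM cluster count is a user choice; no internal model selection
  (e.g. fuzzy partition coefficient) is performed.
- The site histogram counts unique (protein, site) pairs and cannot
  distinguish isoforms sharing a peptide.
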