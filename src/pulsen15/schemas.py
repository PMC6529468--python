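"""Canonical column orders for the TSV tables exchanged between stages."""

PSM_COLUMNS = [
    "psm_id", "protein_id", "peptide_id", "peptide_sequence", "charge",
    "channel", "tissue", "age_days", "mod_positions", "peptide_start", "xic_id",
]

XIC_COLUMNS = ["xic_id", "scan_time", "light_intensity", "heavy_intensity"]

TRUTH_BASE_COLUMNS = [
    "protein_id", "turnover_class", "k_per_day", "abundance",
    "n_peptides", "n_ub_sites", "ub_sites",
]
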