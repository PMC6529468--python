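"""Old-pool bias statistics for the diGly-enriched ubiquitylome.

Quantifies how ubiquitylation distributes over old (heavy-labeled)
versus newly synthesized (light) proteins: heavy-PSM proportions,
per-protein heavy-share comparison between ubiquitylome and total
proteome with a Mann-Whitney-Wilcoxon rank-sum test, and diGly site
bookkeeping (unique-site counts per protein).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProportionReport",
    "UbComparison",
    "SiteHistogram",
    "psm_channel_proportions",
    "compare_protein_n15",
    "site_count_distribution",
    "map_peptide_site_to_protein",
    "extract_ub_sites",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProportionReport:
    """Heavy-PSM share of a PSM subset; counts are exact integers."""

    subset: str
    n_psm_total: int
    n_psm_15n: int

    @property
    def percent_15n(self) -> int:
        """Heavy share as a whole percent (half-up)."""
        return int(np.floor(100.0 * self.n_psm_15n / self.n_psm_total + 0.5))

    @property
    def fraction_15n(self) -> float:
        return self.n_psm_15n / self.n_psm_total


def psm_channel_proportions(
    psms: pd.DataFrame, subset: str = "total_proteome", mask=None
) -> ProportionReport:
    """Count heavy (15N) PSMs in a subset of the PSM table."""
    sub = psms if mask is None else psms.loc[mask]
    if len(sub) == 0:
        raise ValueError(f"no PSMs left after applying filter {subset!r}")
    n_heavy = int((sub["channel"] == "15N").sum())
    return ProportionReport(subset, len(sub), n_heavy)


@dataclass(frozen=True)
class UbComparison:
    """Ubiquitylome vs total-proteome per-protein heavy-share comparison."""

    n_matched: int
    fraction_higher_in_ub: float
    mannwhitney_p: float       # unpaired rank-sum on the matched value sets
    wilcoxon_p: float          # paired signed-rank on the per-protein deltas


def compare_protein_n15(
    total: pd.DataFrame,
    ub: pd.DataFrame,
    value_col: str = "n15_fraction",
    alternative: str = "two-sided",
) -> UbComparison:
    """Compare per-protein heavy shares between the ubiquitylome and the
    total proteome, matched by protein id.

    Emits the fraction of matched proteins whose ubiquitylated form has
    the strictly higher heavy share, the two-sided Mann-Whitney-Wilcoxon
    rank-sum p on the two matched value sets (tie-corrected), and the
    paired Wilcoxon signed-rank p as a companion statistic.
    """
    merged = total.merge(ub, on="protein_id", suffixes=("_total", "_ub"))
    if len(merged) < 2:
        raise ValueError(f"need >= 2 matched proteins, got {len(merged)}")
    t = merged[f"{value_col}_total"].to_numpy(dtype=float)
    u = merged[f"{value_col}_ub"].to_numpy(dtype=float)
    frac = float(np.mean(u > t))
    mw = stats.mannwhitneyu(u, t, alternative=alternative)
    diffs = u - t
    if np.allclose(diffs, 0):
        wp = 1.0
    else:
        wp = float(stats.wilcoxon(u, t, alternative=alternative,
                                  zero_method="wilcox").pvalue)
    return UbComparison(len(merged), frac, float(mw.pvalue), wp)


@dataclass(frozen=True)
class SiteHistogram:
    """Unique diGly sites per protein, binned as reported: 'exactly one'
    and 'more than one' partition the proteins; 'more than 10' is a
    sub-bin of 'more than one'."""

    n_proteins: int
    exactly_1: int
    more_than_1: int
    more_than_10: int


def site_count_distribution(
    sites: pd.DataFrame, quantified_only: bool = False
) -> SiteHistogram:
    """Per-protein unique-site histogram.

    ``sites`` needs columns protein_id, site; duplicates on
    (protein_id, site) are counted once.  With ``quantified_only`` the
    table must carry a boolean 'quantified' column (one quantified
    ubiquitylated peptide suffices to report a protein)."""
    if quantified_only:
        sites = sites.loc[sites["quantified"].astype(bool)]
    uniq = sites.drop_duplicates(subset=["protein_id", "site"])
    counts = uniq.groupby("protein_id")["site"].size()
    return SiteHistogram(
        n_proteins=int(len(counts)),
        exactly_1=int((counts == 1).sum()),
        more_than_1=int((counts > 1).sum()),
        more_than_10=int((counts > 10).sum()),
    )


def map_peptide_site_to_protein(
    peptide_start: int, mod_position: int, protein_length: int | None = None
) -> int:
    """Protein coordinate of a peptide-level modification site.

    Both coordinates are 1-based; site = peptide_start + mod_position - 1.
    """
    if peptide_start < 1 or mod_position < 1:
        raise ValueError("peptide_start and mod_position are 1-based (>= 1)")
    site = peptide_start + mod_position - 1
    if protein_length is not None and site > protein_length:
        raise ValueError(
            f"site {site} exceeds protein length {protein_length}"
        )
    return site


def extract_ub_sites(psms: pd.DataFrame) -> pd.DataFrame:
    """diGly site records from the PSM table: one row per
    (protein_id, site, tissue, age) with channel-resolved PSM counts.

    diGly entries are recognized by name in the mod_positions field
    ("pos:name:delta;...").  A diGly on the peptide's C-terminal residue
    is implausible under tryptic cleavage (trypsin does not cut after a
    modified lysine) and is logged, not dropped.
    """
    rows = []
    for rec in psms.itertuples(index=False):
        mods = getattr(rec, "mod_positions", "") or ""
        if not isinstance(mods, str) or not mods:
            continue
        for token in mods.split(";"):
            pos_s, name, _delta = token.split(":")
            if name != "diGly":
                continue
            pos = int(pos_s)
            seq = getattr(rec, "peptide_sequence", "") or ""
            if seq and pos == len(seq):
                logger.warning(
                    "diGly on C-terminal residue of peptide %s (PSM %s): "
                    "implausible under tryptic cleavage; kept for audit",
                    rec.peptide_id, rec.psm_id,
                )
            site = map_peptide_site_to_protein(int(rec.peptide_start), pos)
            rows.append(
                {
                    "protein_id": rec.protein_id,
                    "site": site,
                    "tissue": rec.tissue,
                    "age_days": rec.age_days,
                    "channel": rec.channel,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["protein_id", "site", "tissue", "age_days", "n_14n", "n_15n"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.assign(
            n_14n=(df["channel"] == "14N").astype(int),
            n_15n=(df["channel"] == "15N").astype(int),
        )
        .groupby(["protein_id", "site", "tissue", "age_days"], as_index=False)[
            ["n_14n", "n_15n"]
        ]
        .sum()
    )
    return out
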