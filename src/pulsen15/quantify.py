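"""Peptide ratio estimation from paired light/heavy chromatograms and
roll-up to per-protein heavy-channel proportions.

The per-peptide heavy/light ratio is the least-squares slope through the
origin of the heavy trace regressed on the light trace across scans
(Census-style paired-chromatogram ratio), with a squared-correlation
fit filter; the heavy proportion is ratio / (1 + ratio).  Proteins are
aggregated as the median of accepted peptide proportions, requiring two
peptides in total-proteome mode and one in ubiquitylome mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "XICPair",
    "PeptideQuant",
    "estimate_pair_ratio",
    "n15_proportion",
    "rollup_protein",
    "quantify_experiment",
]


@dataclass(frozen=True)
class XICPair:
    """Co-eluting light (14N) and heavy (15N) intensity traces."""

    times: np.ndarray
    light: np.ndarray
    heavy: np.ndarray

    def __post_init__(self) -> None:
        t, l, h = map(np.asarray, (self.times, self.light, self.heavy))
        if not (len(t) == len(l) == len(h)):
            raise ValueError("times, light and heavy must have equal lengths")
        if len(t) < 3:
            raise ValueError(f"need >= 3 scans, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("scan times must be strictly increasing")
        if np.any(l < 0) or np.any(h < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class PeptideQuant:
    """Quantification result for one peptide at one age."""

    peptide_id: str
    ratio_heavy_over_light: float  # may be inf when light signal is zero
    n15_proportion: float
    fit_r2: float
    method: Literal["regression", "area"]
    rejected: bool = False
    reject_reason: str = ""


def n15_proportion(light_area: float, heavy_area: float) -> float:
    """Heavy share of the total signal: heavy / (light + heavy)."""
    if light_area < 0 or heavy_area < 0:
        raise ValueError("areas must be non-negative")
    total = light_area + heavy_area
    if total == 0:
        raise ValueError("light and heavy areas are both zero")
    return heavy_area / total


def estimate_pair_ratio(
    xic: XICPair,
    r2_threshold: float = 0.5,
    peptide_id: str = "",
    use_area_fallback: bool = True,
) -> PeptideQuant:
    """Heavy/light ratio of one XIC pair.

    Regression-through-origin slope of heavy on light across scans, with
    the squared Pearson correlation of the two traces as fit quality.
    Pairs below ``r2_threshold`` fall back to the area ratio (or are
    rejected when ``use_area_fallback`` is off).  A pair with zero light
    signal maps to proportion 1.0 so downstream math stays in [0, 1].
    """
    l = np.asarray(xic.light, dtype=float)
    h = np.asarray(xic.heavy, dtype=float)
    if not np.any(l > 0) and not np.any(h > 0):
        return PeptideQuant(peptide_id, np.nan, np.nan, 0.0, "regression",
                            rejected=True, reject_reason="zero-signal")
    if not np.any(l > 0):
        return PeptideQuant(peptide_id, np.inf, 1.0, 1.0, "area")
    if not np.any(h > 0):
        return PeptideQuant(peptide_id, 0.0, 0.0, 1.0, "area")
    slope = float(np.dot(l, h) / np.dot(l, l))
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(l, h)[0, 1]
    r2 = 0.0 if not np.isfinite(r) else float(r * r)
    if r2 >= r2_threshold:
        ratio = slope
        method: Literal["regression", "area"] = "regression"
        rejected, reason = False, ""
    elif use_area_fallback:
        ratio = float(h.sum() / l.sum())
        method = "area"
        rejected, reason = False, ""
    else:
        return PeptideQuant(peptide_id, slope, slope / (1 + slope), r2,
                            "regression", rejected=True, reject_reason="low-r2")
    return PeptideQuant(peptide_id, ratio, ratio / (1.0 + ratio), r2, method,
                        rejected=rejected, reject_reason=reason)


def rollup_protein(
    quants: pd.DataFrame,
    mode: Literal["total", "ubiquitylome"] = "total",
) -> pd.DataFrame:
    """Aggregate peptide quants to protein heavy proportions.

    ``quants`` needs columns protein_id, tissue, age_days,
    n15_proportion, rejected.  Rejected peptides are dropped; the protein
    value is the median peptide proportion; proteins require >= 2
    peptides per age in total mode and >= 1 in ubiquitylome mode.
    """
    min_peptides = 2 if mode == "total" else 1
    ok = quants.loc[~quants["rejected"].astype(bool)]
    grouped = (
        ok.groupby(["protein_id", "tissue", "age_days"], as_index=False)
        .agg(n15_fraction=("n15_proportion", "median"),
             n_peptides=("n15_proportion", "size"))
    )
    return grouped.loc[grouped["n_peptides"] >= min_peptides].reset_index(drop=True)


def _pivot_xics(xics: pd.DataFrame) -> dict[str, XICPair]:
    pairs: dict[str, XICPair] = {}
    for xic_id, g in xics.groupby("xic_id", sort=False):
        g = g.sort_values("scan_time")
        pairs[xic_id] = XICPair(
            times=g["scan_time"].to_numpy(dtype=float),
            light=g["light_intensity"].to_numpy(dtype=float),
            heavy=g["heavy_intensity"].to_numpy(dtype=float),
        )
    return pairs


def quantify_experiment(
    psms: pd.DataFrame,
    xics: pd.DataFrame,
    r2_threshold: float = 0.5,
    mode: Literal["total", "ubiquitylome"] = "total",
    ub_only: bool | None = None,
) -> pd.DataFrame:
    """Run the peptide-to-protein quantification chain on table inputs.

    One ratio per distinct (peptide, age) XIC pair; diGly-bearing PSMs
    (non-empty mod_positions) are the ubiquitylome subset.  Returns the
    protein turnover table (protein_id, tissue, age_days, n15_fraction,
    n_peptides).
    """
    if ub_only is None:
        ub_only = mode == "ubiquitylome"
    sel = psms["mod_positions"].fillna("").astype(str) != ""
    subset = psms.loc[sel] if ub_only else psms.loc[~sel]
    pairs = _pivot_xics(xics)
    keys = subset[["protein_id", "peptide_id", "tissue", "age_days", "xic_id"]].drop_duplicates()
    rows = []
    for rec in keys.itertuples(index=False):
        pair = pairs.get(rec.xic_id)
        if pair is None:
            continue
        q = estimate_pair_ratio(pair, r2_threshold=r2_threshold,
                                peptide_id=rec.peptide_id)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "peptide_id": rec.peptide_id,
                "tissue": rec.tissue,
                "age_days": rec.age_days,
                "n15_proportion": q.n15_proportion,
                "fit_r2": q.fit_r2,
                "method": q.method,
                "rejected": q.rejected,
            }
        )
    quants = pd.DataFrame(rows)
    if quants.empty:
        return pd.DataFrame(
            columns=["protein_id", "tissue", "age_days", "n15_fraction", "n_peptides"]
        )
    return rollup_protein(quants, mode=mode)
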