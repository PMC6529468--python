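"""Seeded synthetic pulse-15N experiments with known ground truth.

Emulates the study design: animals fully labeled with heavy nitrogen,
switched to a light diet at day 5, tissues sampled at days 5/30/60.  Each
protein's old (heavy-labeled) pool decays by first-order kinetics,
f_old(t) = exp(-k (t - t_chase)); peptide-level signals are paired
light/heavy extracted-ion chromatograms with multiplicative log-normal
noise, and diGly (ubiquitylated) spectra can be biased toward the old
pool through a configurable odds multiplier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TurnoverClass",
    "GeneratorConfig",
    "SimProtein",
    "SimulatedProteome",
    "TISSUE_PRESETS",
    "simulate_proteome",
    "simulate_xic_pair",
    "simulate_ub_psms",
    "simulate_experiment",
    "write_fixture",
]

CHASE_START_DAY = 5.0


@dataclass(frozen=True)
class TurnoverClass:
    """One component of the turnover-rate mixture.

    Rates k (per day) are log-normal: log k ~ N(log_k_mean, log_k_sigma).
    """

    name: str
    weight: float
    log_k_mean: float
    log_k_sigma: float


def _k_for_retention(f60: float, chase_days: float = 55.0) -> float:
    """Rate constant whose old-pool retention after the chase equals f60."""
    return float(-np.log(f60) / chase_days)


# Default three-component mixture: fast-turnover bulk, long-lived, and
# extremely long-lived.  Medians are placed so the extreme class retains
# ~85% heavy signal at day 60 (above the 70% floor), the slow class ~40%
# (above the 10% long-lived cutoff), and the fast class ~2%.
DEFAULT_CLASSES = (
    TurnoverClass("fast", 0.45, float(np.log(_k_for_retention(0.02))), 0.30),
    TurnoverClass("slow", 0.45, float(np.log(_k_for_retention(0.40))), 0.35),
    TurnoverClass("extreme", 0.10, float(np.log(_k_for_retention(0.85))), 0.25),
)

#: Tissue presets: mixture weights chosen so the expected long-lived and
#: extremely long-lived shares match the tissue-specific proportions seen
#: in fly head, muscle and testis (somatic tissues rich in long-lived
#: proteins, mitotically active germline poor in them).
TISSUE_PRESETS: dict[str, tuple[float, float, float]] = {
    # (fast, slow, extreme) weights
    "head": (0.45, 0.46, 0.09),
    "muscle": (0.21, 0.53, 0.26),
    "testis": (0.69, 0.21, 0.10),
}


@dataclass
class GeneratorConfig:
    """Full parameterization of a simulated pulse-15N experiment."""

    n_proteins: int = 500
    peptides_per_protein_mean: float = 4.0
    ages_days: tuple[float, ...] = (5.0, 30.0, 60.0)
    chase_start_day: float = CHASE_START_DAY
    turnover_classes: tuple[TurnoverClass, ...] = DEFAULT_CLASSES
    label_purity: float = 0.995
    noise_sigma: float = 0.1
    psm_depth: float = 2.0
    ub_site_density: float = 1.0
    ub_old_bias_beta: float = 1.0
    tissue: str = "head"
    n_scans: int = 9
    base_intensity: float = 1e6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.turnover_classes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"turnover class weights must sum to 1, got {w}")
        if not 0.0 < self.label_purity <= 1.0:
            raise ValueError("label_purity must be in (0, 1]")
        if self.ub_old_bias_beta < 0:
            raise ValueError("ub_old_bias_beta must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def with_tissue_preset(self, tissue: str) -> "GeneratorConfig":
        """Config with mixture weights set to a tissue preset."""
        weights = TISSUE_PRESETS[tissue]
        classes = tuple(
            dataclasses.replace(c, weight=w)
            for c, w in zip(DEFAULT_CLASSES, weights)
        )
        return dataclasses.replace(self, turnover_classes=classes, tissue=tissue)


@dataclass
class SimProtein:
    protein_id: str
    turnover_class: str
    k: float
    abundance: float
    length: int
    peptide_ids: list[str]
    ub_sites: list[int]

    def f_old(self, age_days: float, chase_start: float = CHASE_START_DAY) -> float:
        """True old-pool fraction at ``age_days``; 1.0 before the chase."""
        dt = max(age_days - chase_start, 0.0)
        return float(np.exp(-self.k * dt))


@dataclass
class SimulatedProteome:
    proteins: list[SimProtein]
    config: GeneratorConfig

    def truth_table(self) -> pd.DataFrame:
        """Ground truth per protein: rate, true old fractions f_old and
        the expected observable heavy share f_obs = purity * f_old."""
        purity = self.config.label_purity
        rows = []
        for p in self.proteins:
            row = {
                "protein_id": p.protein_id,
                "turnover_class": p.turnover_class,
                "k_per_day": p.k,
                "abundance": p.abundance,
                "n_peptides": len(p.peptide_ids),
                "n_ub_sites": len(p.ub_sites),
                "ub_sites": ";".join(map(str, p.ub_sites)),
            }
            for age in self.config.ages_days:
                f = p.f_old(age, self.config.chase_start_day)
                row[f"f_old_{age:g}d"] = f
                row[f"f_obs_{age:g}d"] = purity * f
            rows.append(row)
        from .schemas import TRUTH_BASE_COLUMNS

        cols = TRUTH_BASE_COLUMNS + [
            f"{kind}_{age:g}d"
            for age in self.config.ages_days
            for kind in ("f_old", "f_obs")
        ]
        return pd.DataFrame(rows, columns=cols)


def _spawn(seed: int, *keys: int) -> np.random.Generator:
    """Independent child RNG stream keyed by integers, reproducible under
    any iteration order."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


def simulate_proteome(config: GeneratorConfig) -> SimulatedProteome:
    """Draw a proteome: per-protein turnover class, rate, abundance,
    surrogate peptides, and diGly site positions.  Deterministic for a
    given seed."""
    rng = _spawn(config.rng_seed, 1)
    weights = np.array([c.weight for c in config.turnover_classes])
    proteins: list[SimProtein] = []
    pep_counter = 0
    for i in range(config.n_proteins):
        cls_idx = int(rng.choice(len(weights), p=weights))
        cls = config.turnover_classes[cls_idx]
        k = float(rng.lognormal(cls.log_k_mean, cls.log_k_sigma))
        abundance = float(rng.lognormal(0.0, 1.0))
        length = int(max(50, rng.normal(350, 100)))
        n_pep = 1 + int(rng.poisson(max(config.peptides_per_protein_mean - 1, 0)))
        pep_ids = [f"pep{pep_counter + j:06d}" for j in range(n_pep)]
        pep_counter += n_pep
        n_sites = int(rng.poisson(config.ub_site_density))
        n_sites = min(n_sites, length)
        sites = sorted(rng.choice(np.arange(1, length + 1), size=n_sites, replace=False).tolist()) if n_sites else []
        proteins.append(
            SimProtein(
                protein_id=f"prot{i:05d}",
                turnover_class=cls.name,
                k=k,
                abundance=abundance,
                length=length,
                peptide_ids=pep_ids,
                ub_sites=[int(s) for s in sites],
            )
        )
    return SimulatedProteome(proteins, config)


def simulate_xic_pair(
    f_old: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    abundance: float = 1.0,
):
    """One paired light/heavy extracted-ion chromatogram.

    A Gaussian elution profile is split between the heavy trace (weight
    purity * f_old) and the light trace (the complement); each scan of
    each channel then gets independent multiplicative log-normal noise.
    Returns (times, light, heavy) arrays.
    """
    from .quantify import XICPair

    n = config.n_scans
    times = np.arange(n, dtype=float)
    center = (n - 1) / 2.0
    width = n / 5.0
    profile = config.base_intensity * abundance * np.exp(
        -0.5 * ((times - center) / width) ** 2
    )
    f_obs = config.label_purity * f_old
    heavy = profile * f_obs
    light = profile * (1.0 - f_obs)
    if config.noise_sigma > 0:
        heavy = heavy * np.exp(rng.normal(0.0, config.noise_sigma, size=n))
        light = light * np.exp(rng.normal(0.0, config.noise_sigma, size=n))
    return XICPair(times=times, light=light, heavy=heavy)


def heavy_channel_probability(f_old: float, beta: float, purity: float = 1.0) -> float:
    """Probability that a spectrum samples the old (heavy) pool when old
    molecules are favoured by odds multiplier ``beta``.

    P = beta*f / (beta*f + (1-f)) with f the observable old fraction;
    beta = 1 is unbiased sampling.  Degenerate all-new pools (f = 0 or
    beta = 0 with f < 1) give 0.
    """
    f = purity * f_old
    num = beta * f
    den = beta * f + (1.0 - f)
    if den == 0.0:
        # f == 1 and beta == 0: no molecule can be sampled as old under
        # zero odds; define the probability as 0.
        return 0.0
    return num / den


def simulate_ub_psms(
    proteome: SimulatedProteome, age_days: float, rng: np.random.Generator
) -> list[dict]:
    """diGly PSMs for one age, channel-biased toward the old pool by
    ``ub_old_bias_beta``.  Returns plain row dicts (table assembly lives
    in :func:`simulate_experiment`)."""
    cfg = proteome.config
    rows: list[dict] = []
    for prot in proteome.proteins:
        f = prot.f_old(age_days, cfg.chase_start_day)
        p_heavy = heavy_channel_probability(f, cfg.ub_old_bias_beta, cfg.label_purity)
        for site in prot.ub_sites:
            n_psm = 1 + rng.poisson(cfg.psm_depth)
            mod_pos = int(rng.integers(1, 16))
            pep_start = max(site - mod_pos + 1, 1)
            mod_pos = site - pep_start + 1
            for _ in range(n_psm):
                channel = "15N" if rng.random() < p_heavy else "14N"
                rows.append(
                    {
                        "protein_id": prot.protein_id,
                        "site": site,
                        "peptide_start": pep_start,
                        "mod_position": mod_pos,
                        "channel": channel,
                        "age_days": age_days,
                    }
                )
    return rows


def simulate_experiment(config: GeneratorConfig):
    """Full synthetic experiment for one tissue.

    Returns ``(proteome, psms, xics)`` where ``psms`` follows the PSM
    table schema (one row per peptide-spectrum match, diGly subset
    flagged by non-empty mod_positions) and ``xics`` is the long-format
    paired chromatogram table (one XIC pair per peptide per age).
    """
    proteome = simulate_proteome(config)
    cfg = config
    psm_rows: list[dict] = []
    xic_rows: list[dict] = []
    psm_counter = 0
    for pi, prot in enumerate(proteome.proteins):
        rng = _spawn(cfg.rng_seed, 2, pi)
        for age in cfg.ages_days:
            f = prot.f_old(age, cfg.chase_start_day)
            f_obs = cfg.label_purity * f
            for pep_id in prot.peptide_ids:
                xic_id = f"x_{pep_id}_{age:g}"
                pair = simulate_xic_pair(f, cfg, rng, abundance=prot.abundance)
                for t, l, h in zip(pair.times, pair.light, pair.heavy):
                    xic_rows.append(
                        {
                            "xic_id": xic_id,
                            "scan_time": t,
                            "light_intensity": l,
                            "heavy_intensity": h,
                        }
                    )
                n_psm = 1 + rng.poisson(cfg.psm_depth)
                for _ in range(n_psm):
                    channel = "15N" if rng.random() < f_obs else "14N"
                    psm_rows.append(
                        {
                            "psm_id": f"psm{psm_counter:07d}",
                            "protein_id": prot.protein_id,
                            "peptide_id": pep_id,
                            "peptide_sequence": "",
                            "charge": 2,
                            "channel": channel,
                            "tissue": cfg.tissue,
                            "age_days": age,
                            "mod_positions": "",
                            "peptide_start": 0,
                            "xic_id": xic_id,
                        }
                    )
                    psm_counter += 1
        # diGly subset: dedicated ub-peptides per site, channel drawn with
        # the old-pool bias, plus an XIC pair per site/age for quantification
        ub_rng = _spawn(cfg.rng_seed, 3, pi)
        for age in cfg.ages_days:
            f = prot.f_old(age, cfg.chase_start_day)
            p_heavy = heavy_channel_probability(f, cfg.ub_old_bias_beta, cfg.label_purity)
            for si, site in enumerate(prot.ub_sites):
                pep_id = f"ubpep_{prot.protein_id}_{site}"
                xic_id = f"x_{pep_id}_{age:g}"
                # the ub-XIC heavy share follows the biased sampling odds
                f_eff = p_heavy / cfg.label_purity if cfg.label_purity else 0.0
                pair = simulate_xic_pair(
                    min(f_eff, 1.0), cfg, ub_rng, abundance=prot.abundance
                )
                for t, l, h in zip(pair.times, pair.light, pair.heavy):
                    xic_rows.append(
                        {
                            "xic_id": xic_id,
                            "scan_time": t,
                            "light_intensity": l,
                            "heavy_intensity": h,
                        }
                    )
                mod_pos = int(ub_rng.integers(1, 16))
                pep_start = max(site - mod_pos + 1, 1)
                mod_pos = site - pep_start + 1
                n_psm = 1 + ub_rng.poisson(cfg.psm_depth)
                for _ in range(n_psm):
                    channel = "15N" if ub_rng.random() < p_heavy else "14N"
                    psm_rows.append(
                        {
                            "psm_id": f"psm{psm_counter:07d}",
                            "protein_id": prot.protein_id,
                            "peptide_id": pep_id,
                            "peptide_sequence": "",
                            "charge": 3,
                            "channel": channel,
                            "tissue": cfg.tissue,
                            "age_days": age,
                            "mod_positions": f"{mod_pos}:diGly:114.04293",
                            "peptide_start": pep_start,
                            "xic_id": xic_id,
                        }
                    )
                    psm_counter += 1
    from .schemas import PSM_COLUMNS, XIC_COLUMNS

    psms = pd.DataFrame(psm_rows, columns=PSM_COLUMNS)
    xics = pd.DataFrame(xic_rows, columns=XIC_COLUMNS)
    return proteome, psms, xics


def write_fixture(
    proteome: SimulatedProteome,
    psms: pd.DataFrame,
    xics: pd.DataFrame,
    directory,
) -> dict[str, Path]:
    """Write psms.tsv, xics.tsv, truth.tsv and config.yaml to a
    directory; byte-identical across runs for a fixed seed."""
    from .io import write_tsv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": directory / "psms.tsv",
        "xics": directory / "xics.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.yaml",
    }
    write_tsv(psms, paths["psms"], seed=proteome.config.rng_seed)
    write_tsv(xics, paths["xics"], seed=proteome.config.rng_seed)
    write_tsv(proteome.truth_table(), paths["truth"], seed=proteome.config.rng_seed)
    cfg = dataclasses.asdict(proteome.config)
    cfg["turnover_classes"] = [dataclasses.asdict(c) for c in proteome.config.turnover_classes]
    cfg["ages_days"] = list(proteome.config.ages_days)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
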