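"""Table schemas, configuration and the end-to-end pipeline.

All tables are tab-delimited UTF-8 with a mandatory header row and '.'
decimal separator; coordinates (protein sites, peptide spans) are
1-based inclusive.  Output files carry a provenance header (tool
version, config hash, seed) in '#'-prefixed comment lines and are
written atomically (temp file + rename) so no partial file survives a
failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .quantify import quantify_experiment
from .simulate import GeneratorConfig, simulate_experiment, write_fixture
from .turnover import (
    build_trajectory_matrix,
    classify_llp,
    fcm_cluster,
    identify_ellp,
    llp_summary,
)
from .ubiquitylome import (
    compare_protein_n15,
    extract_ub_sites,
    psm_channel_proportions,
    site_count_distribution,
)

__all__ = [
    "PSM_COLUMNS",
    "XIC_COLUMNS",
    "MalformedRow",
    "PSMTableError",
    "read_psm_table",
    "read_xic_table",
    "write_tsv",
    "read_tsv",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

from .schemas import PSM_COLUMNS, XIC_COLUMNS  # noqa: E402  (canonical order)

_CHANNEL_NORMALIZATION = {"14n": "14N", "15n": "15N"}


@dataclass(frozen=True)
class MalformedRow:
    line_number: int  # 1-based line in the file, header included
    reason: str


class PSMTableError(ValueError):
    def __init__(self, message: str, malformed: list[MalformedRow] = ()):  # noqa: D107
        super().__init__(message)
        self.malformed = list(malformed)


def read_psm_table(path, skip_bad: bool = False) -> pd.DataFrame:
    """Read and validate a PSM table.

    Channel labels are normalized case-insensitively to {14N, 15N};
    malformed rows (bad channel, non-numeric age) are collected with
    their line numbers and abort the run unless ``skip_bad``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PSMTableError(f"missing required column(s): {', '.join(missing)}")
    bad: list[MalformedRow] = []
    channels = df["channel"].str.lower().map(_CHANNEL_NORMALIZATION)
    ages = pd.to_numeric(df["age_days"], errors="coerce")
    starts = pd.to_numeric(df["peptide_start"], errors="coerce")
    charges = pd.to_numeric(df["charge"], errors="coerce")
    for idx in df.index:
        line = idx + 2  # header on line 1
        if pd.isna(channels.iloc[idx]):
            bad.append(MalformedRow(line, f"unrecognized channel {df['channel'].iloc[idx]!r}"))
        if pd.isna(ages.iloc[idx]):
            bad.append(MalformedRow(line, f"non-numeric age_days {df['age_days'].iloc[idx]!r}"))
        if pd.isna(starts.iloc[idx]):
            bad.append(MalformedRow(line, f"non-numeric peptide_start {df['peptide_start'].iloc[idx]!r}"))
    if bad and not skip_bad:
        report = "; ".join(f"line {b.line_number}: {b.reason}" for b in bad[:20])
        raise PSMTableError(f"{len(bad)} malformed row(s): {report}", bad)
    ok = channels.notna() & ages.notna() & starts.notna()
    out = df.loc[ok].copy()
    out["channel"] = channels.loc[ok]
    out["age_days"] = ages.loc[ok]
    out["peptide_start"] = starts.loc[ok].astype(int)
    out["charge"] = charges.loc[ok].fillna(0).astype(int)
    if bad:
        logger.warning("skipped %d malformed PSM row(s)", len(bad))
    return out.reset_index(drop=True)


def read_xic_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in XIC_COLUMNS if c not in df.columns]
    if missing:
        raise PSMTableError(f"missing required column(s): {', '.join(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path, seed: int | None = None,
              config_hash: str | None = None) -> Path:
    """Atomically write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [
        f"# pulsen15 {__version__}",
        f"# seed: {'-' if seed is None else seed}",
        f"# config: {config_hash or '-'}",
    ]
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Pipeline configuration: thresholds, clustering settings, seed."""

    out_dir: str = "results"
    seed: int = 0
    llp_threshold: float = 0.10
    ellp_floor: float = 0.70
    r2_threshold: float = 0.5
    fcm_clusters: int = 4
    fcm_fuzzifier: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    run_prm: bool = False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    psms_path: str | None = None   # when set, read inputs instead of simulating
    xics_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("llp_threshold", "ellp_floor", "r2_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            from .simulate import TurnoverClass
            classes = gen.pop("turnover_classes", None)
            if classes:
                gen["turnover_classes"] = tuple(TurnoverClass(**c) for c in classes)
            if "ages_days" in gen:
                gen["ages_days"] = tuple(gen["ages_days"])
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = dataclasses.asdict(self)
        for key in ("out_dir", "psms_path", "xics_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Quantify -> classify turnover -> ubiquitylome statistics.

    Inputs are either simulated from ``config.generator`` or read from
    ``psms_path``/``xics_path``.  Identical config + seed produce
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    seed = config.seed

    if config.psms_path:
        logger.info("stage: read inputs")
        psms = read_psm_table(config.psms_path)
        xics = read_xic_table(config.xics_path)
        truth = None
    else:
        logger.info("stage: simulate")
        gen = dataclasses.replace(config.generator, rng_seed=config.seed)
        proteome, psms, xics = simulate_experiment(gen)
        truth = proteome.truth_table()

    paths: dict[str, Path] = {}

    logger.info("stage: quantify")
    total = quantify_experiment(psms, xics, r2_threshold=config.r2_threshold,
                                mode="total")
    ub = quantify_experiment(psms, xics, r2_threshold=config.r2_threshold,
                             mode="ubiquitylome")
    paths["protein_turnover"] = write_tsv(total, out / "protein_turnover.tsv", seed, h)
    paths["ub_protein_turnover"] = write_tsv(ub, out / "ub_protein_turnover.tsv", seed, h)

    logger.info("stage: classify-turnover")
    traj = build_trajectory_matrix(total, ages=tuple(config.generator.ages_days))
    flags = classify_llp(traj, threshold=config.llp_threshold)
    fcm = fcm_cluster(traj, c=config.fcm_clusters, m=config.fcm_fuzzifier,
                      tol=config.fcm_tol, max_iter=config.fcm_max_iter,
                      seed=seed)
    ellps = identify_ellp(fcm, traj, retention_floor=config.ellp_floor)
    hard = fcm.hard_assignment()
    classification = pd.DataFrame(
        {
            "protein_id": traj.index,
            "is_llp": flags.to_numpy(),
            "is_ellp": [pid in ellps for pid in traj.index],
            "cluster": hard,
            "membership": fcm.membership[range(len(traj)), hard].round(6),
        }
    )
    paths["classification"] = write_tsv(classification, out / "classification.tsv", seed, h)

    logger.info("stage: ub-stats")
    is_ub = psms["mod_positions"].fillna("").astype(str) != ""
    reports = [
        psm_channel_proportions(psms, "total_proteome", ~is_ub),
        psm_channel_proportions(psms, "ubiquitylome", is_ub),
    ]
    prop_df = pd.DataFrame(
        [
            {"subset": r.subset, "n_psm_total": r.n_psm_total,
             "n_psm_15N": r.n_psm_15n, "percent_15N": r.percent_15n}
            for r in reports
        ]
    )
    paths["ub_proportions"] = write_tsv(prop_df, out / "ub_proportions.tsv", seed, h)

    sites = extract_ub_sites(psms)
    paths["ub_sites"] = write_tsv(sites, out / "ub_sites.tsv", seed, h)
    hist = site_count_distribution(sites.rename(columns={"site": "site"}))
    hist_df = pd.DataFrame(
        [
            {"bin": "exactly_1", "n_proteins": hist.exactly_1},
            {"bin": "more_than_1", "n_proteins": hist.more_than_1},
            {"bin": "more_than_10", "n_proteins": hist.more_than_10},
        ]
    )
    paths["ub_site_histogram"] = write_tsv(hist_df, out / "ub_site_histogram.tsv", seed, h)

    # per-protein ub vs total comparison at the oldest age
    oldest = max(config.generator.ages_days)
    tot_old = total.loc[total["age_days"] == oldest]
    ub_old = ub.loc[ub["age_days"] == oldest]
    try:
        cmp_res = compare_protein_n15(tot_old, ub_old)
        cmp_df = pd.DataFrame(
            [{"age_days": oldest, "n_matched": cmp_res.n_matched,
              "fraction_higher_in_ub": cmp_res.fraction_higher_in_ub,
              "mannwhitney_p": cmp_res.mannwhitney_p,
              "wilcoxon_p": cmp_res.wilcoxon_p}]
        )
        paths["ub_comparison"] = write_tsv(cmp_df, out / "ub_comparison.tsv", seed, h)
    except ValueError as exc:
        logger.warning("ub comparison skipped: %s", exc)

    if truth is not None:
        paths["truth"] = write_tsv(truth, out / "truth.tsv", seed, h)

    n_llp, n_total, pct = llp_summary(flags)
    summary = pd.DataFrame(
        [
            {"metric": "n_proteins_trajectory", "value": len(traj)},
            {"metric": "n_llp", "value": n_llp},
            {"metric": "llp_percent", "value": pct},
            {"metric": "n_ellp", "value": len(ellps)},
        ]
    )
    paths["summary"] = write_tsv(summary, out / "summary.tsv", seed, h)
    return paths
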