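"""Long-lived protein classification from heavy-share trajectories.

A protein quantified at all sampled ages yields a trajectory of heavy
(old-pool) proportions.  Long-lived proteins (LLPs) retain at least 10%
heavy signal at day 60; extremely long-lived proteins (ELLPs) are the
slowest-turnover trajectory cluster, found by fuzzy c-means, further
requiring individual day-60 retention above 70%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FCMResult",
    "build_trajectory_matrix",
    "classify_llp",
    "llp_summary",
    "fcm_cluster",
    "identify_ellp",
    "cross_tissue_overlap",
]

DEFAULT_LLP_THRESHOLD = 0.10
DEFAULT_ELLP_FLOOR = 0.70


def build_trajectory_matrix(
    protein_turnover: pd.DataFrame, ages: Sequence[float] = (5.0, 30.0, 60.0)
) -> pd.DataFrame:
    """Pivot the protein turnover table into proteins x ages, keeping
    only proteins quantified at every requested age (complete rows)."""
    wide = protein_turnover.pivot_table(
        index="protein_id", columns="age_days", values="n15_fraction"
    )
    missing = [a for a in ages if a not in wide.columns]
    if missing:
        raise ValueError(f"requested ages absent from table: {missing}")
    wide = wide.loc[:, list(ages)].dropna()
    wide.columns = [float(c) for c in wide.columns]
    return wide


def classify_llp(
    traj: pd.DataFrame, threshold: float = DEFAULT_LLP_THRESHOLD, age: float = 60.0
) -> pd.Series:
    """LLP flag per protein: day-60 heavy share >= threshold (inclusive,
    'at least 10%')."""
    if age not in traj.columns:
        raise ValueError(f"column for age {age} missing from trajectory matrix")
    return traj[age] >= threshold


def llp_summary(flags: Iterable[bool]) -> tuple[int, int, float]:
    """(n_LLP, n_total, percentage) with half-up rounding to 1 decimal."""
    flags = list(flags)
    if not flags:
        raise ValueError("empty flag set")
    n_llp = int(sum(bool(f) for f in flags))
    n_total = len(flags)
    pct = float(
        (Decimal(100 * n_llp) / Decimal(n_total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return n_llp, n_total, pct


@dataclass
class FCMResult:
    """Fuzzy c-means output: soft memberships and cluster centers."""

    membership: np.ndarray        # (n, c), rows sum to 1
    centers: np.ndarray           # (c, n_ages)
    fuzzifier: float
    n_iterations: int
    converged: bool
    objective: float
    objective_history: np.ndarray
    seed: int

    def hard_assignment(self) -> np.ndarray:
        """argmax membership; ties resolved to the lowest cluster index."""
        return np.argmax(self.membership, axis=1)


def _fcm_once(
    x: np.ndarray, c: int, m: float, tol: float, max_iter: int,
    rng: np.random.Generator,
):
    n = x.shape[0]
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    history = []
    converged = False
    centers = np.zeros((c, x.shape[1]))
    for it in range(1, max_iter + 1):
        um = u ** m
        centers_new = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers_new[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-12  # coincident with a center: full membership there
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
            soft = inv / inv.sum(axis=1, keepdims=True)
        hard = zero / np.maximum(zero.sum(axis=1)[:, None], 1)
        u = np.where(zero.any(axis=1)[:, None], hard, soft)
        history.append(float((u ** m * d2).sum()))
        shift = np.abs(centers_new - centers).max() if it > 1 else np.inf
        centers = centers_new
        if shift < tol:
            converged = True
            break
    return u, centers, it, converged, np.array(history)


def fcm_cluster(
    traj: pd.DataFrame | np.ndarray,
    c: int = 4,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_restarts: int = 5,
) -> FCMResult:
    """Fuzzy c-means on raw heavy-share trajectories.

    Standard alternating updates: centers are membership^m-weighted
    means; membership u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)).  The
    membership matrix is initialized at random from the seeded RNG;
    ``n_restarts`` restarts keep the run with the lowest objective.
    Deterministic for a given seed.
    """
    x = np.asarray(traj, dtype=float)
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if np.unique(x, axis=0).shape[0] < c:
        raise ValueError(
            f"need at least {c} distinct trajectories for {c} clusters"
        )
    root = np.random.SeedSequence(seed)
    best = None
    for child in root.spawn(n_restarts):
        rng = np.random.default_rng(child)
        u, centers, n_iter, converged, hist = _fcm_once(x, c, m, tol, max_iter, rng)
        if best is None or hist[-1] < best[4][-1]:
            best = (u, centers, n_iter, converged, hist)
    u, centers, n_iter, converged, hist = best
    return FCMResult(
        membership=u, centers=centers, fuzzifier=m, n_iterations=n_iter,
        converged=converged, objective=float(hist[-1]),
        objective_history=hist, seed=seed,
    )


def identify_ellp(
    fcm: FCMResult,
    traj: pd.DataFrame,
    retention_floor: float = DEFAULT_ELLP_FLOOR,
    age: float = 60.0,
) -> set[str]:
    """Extremely long-lived proteins: members of the cluster whose
    center has the highest day-60 heavy share, individually retaining
    strictly more than ``retention_floor`` at day 60."""
    age_idx = list(traj.columns).index(age)
    slowest = int(np.argmax(fcm.centers[:, age_idx]))
    hard = fcm.hard_assignment()
    in_cluster = hard == slowest
    above = traj[age].to_numpy() > retention_floor
    return set(traj.index[in_cluster & above])


def cross_tissue_overlap(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every exclusive region of the Venn partition over the
    named protein-id sets (identifiers compared as exact strings)."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(sets)
    regions: dict[tuple[str, ...], int] = {}
    universe = set().union(*sets.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            regions[combo] = len(inside)
    return regions


def intersection_counts(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Plain (non-exclusive) intersection sizes for every combination."""
    names = list(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set(sets[combo[0]])
            for name in combo[1:]:
                inter &= sets[name]
            out[combo] = len(inter)
    return out
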