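"""LLP/ELLP classification, fuzzy c-means, cross-tissue overlaps."""

import numpy as np
import pandas as pd
import pytest

from pulsen15.turnover import (
    build_trajectory_matrix,
    classify_llp,
    cross_tissue_overlap,
    fcm_cluster,
    identify_ellp,
    intersection_counts,
    llp_summary,
)


def traj_frame(values, ids=None, ages=(5.0, 30.0, 60.0)):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=ids, columns=list(ages))


def three_group_traj(n_per_group=20, seed=0, spread=0.01):
    """Three tight, well-separated trajectory groups."""
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[1.0, 0.95, 0.85], [1.0, 0.6, 0.4], [1.0, 0.1, 0.02]]
    )
    rows, labels = [], []
    for g, c in enumerate(centers):
        rows.append(c + rng.normal(0, spread, size=(n_per_group, 3)))
        labels += [g] * n_per_group
    x = np.clip(np.vstack(rows), 0, 1)
    return traj_frame(x), np.array(labels), centers


class TestClassifyLLP:
    def test_threshold_is_inclusive(self):
        traj = traj_frame([[1.0, 0.5, 0.10], [1.0, 0.5, 0.099]])
        flags = classify_llp(traj)
        assert flags.tolist() == [True, False]

    def test_missing_60d_column_rejected(self):
        traj = traj_frame([[1.0, 0.5]], ages=(5.0, 30.0))
        with pytest.raises(ValueError):
            classify_llp(traj)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        traj = traj_frame(rng.random((50, 3)))
        n_prev = None
        for thr in (0.05, 0.1, 0.3, 0.7):
            n = classify_llp(traj, threshold=thr).sum()
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_flags_agree_with_truth_enumeration(self, default_experiment,
                                                default_turnover):
        cfg, proteome, psms, xics = default_experiment
        traj = build_trajectory_matrix(default_turnover)
        truth = proteome.truth_table().set_index("protein_id")
        flags = classify_llp(traj)
        expected = truth.loc[traj.index, "f_obs_60d"] >= 0.10
        assert (flags == expected).mean() >= 0.95


class TestLLPSummary:
    @pytest.mark.parametrize(
        "n_llp, n_total, pct",
        [(1715, 3074, 55.8), (1502, 1903, 78.9), (928, 3034, 30.6)],
    )
    def test_reported_tissue_percentages(self, n_llp, n_total, pct):
        flags = [True] * n_llp + [False] * (n_total - n_llp)
        assert llp_summary(flags) == (n_llp, n_total, pct)

    def test_half_up_rounding(self):
        # 1/16 = 6.25% -> 6.3 under half-up (banker's would give 6.2)
        assert llp_summary([True] + [False] * 15)[2] == 6.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            llp_summary([])


class TestFCM:
    def test_membership_rows_sum_to_one(self):
        traj, _, _ = three_group_traj()
        res = fcm_cluster(traj, c=3, seed=0)
        assert np.allclose(res.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_monotone_nonincreasing(self):
        traj, _, _ = three_group_traj(seed=5, spread=0.05)
        res = fcm_cluster(traj, c=4, seed=2)
        assert np.all(np.diff(res.objective_history) <= 1e-12)

    def test_separated_groups_match_nearest_centroid_oracle(self):
        traj, labels, centers = three_group_traj()
        res = fcm_cluster(traj, c=3, seed=0)
        hard = res.hard_assignment()
        # oracle: nearest true group mean
        x = traj.to_numpy()
        means = np.array([x[labels == g].mean(axis=0) for g in range(3)])
        oracle = np.argmin(
            ((x[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        # map fcm cluster ids to oracle ids via centers
        mapping = np.argmin(
            ((res.centers[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        assert np.array_equal(mapping[hard], oracle)
        assert np.abs(res.centers[mapping.argsort()] - means).max() < 5e-3

    def test_centers_within_data_bounding_box(self):
        traj, _, _ = three_group_traj(seed=3)
        res = fcm_cluster(traj, c=3, seed=1)
        x = traj.to_numpy()
        assert np.all(res.centers >= x.min(axis=0) - 1e-9)
        assert np.all(res.centers <= x.max(axis=0) + 1e-9)

    def test_coincident_point_gets_full_membership(self):
        x = np.array([[0.0, 0.0, 0.0]] * 10 + [[1.0, 1.0, 1.0]] * 10)
        res = fcm_cluster(traj_frame(x), c=2, seed=0)
        # every point sits exactly on its converged cluster center
        assert np.allclose(np.max(res.membership, axis=1), 1.0)

    def test_deterministic_given_seed(self):
        traj, _, _ = three_group_traj(seed=7, spread=0.05)
        r1 = fcm_cluster(traj, c=4, seed=9)
        r2 = fcm_cluster(traj, c=4, seed=9)
        assert np.array_equal(r1.membership, r2.membership)
        assert np.array_equal(r1.centers, r2.centers)

    def test_too_few_distinct_rows_rejected(self):
        x = np.array([[0.5, 0.5, 0.5]] * 10)
        with pytest.raises(ValueError):
            fcm_cluster(traj_frame(x), c=2, seed=0)

    @pytest.mark.parametrize("kwargs", [{"c": 1}, {"m": 1.0}, {"m": 0.5}])
    def test_invalid_parameters(self, kwargs):
        traj, _, _ = three_group_traj()
        with pytest.raises(ValueError):
            fcm_cluster(traj, seed=0, **{"c": 3, **kwargs})


class TestIdentifyELLP:
    def test_retention_floor_is_strict(self):
        traj = traj_frame(
            [[1.0, 0.9, 0.71], [1.0, 0.9, 0.70], [1.0, 0.1, 0.02],
             [1.0, 0.12, 0.03], [1.0, 0.88, 0.72], [1.0, 0.09, 0.01]]
        )
        res = fcm_cluster(traj, c=2, seed=0)
        ellps = identify_ellp(res, traj)
        assert "P0" in ellps and "P4" in ellps
        assert "P1" not in ellps  # exactly at the floor: excluded
        assert "P2" not in ellps

    def test_noiseless_recovery_is_exact(self, noiseless_experiment):
        from pulsen15.quantify import quantify_experiment

        cfg, proteome, psms, xics = noiseless_experiment
        total = quantify_experiment(psms, xics, mode="total")
        traj = build_trajectory_matrix(total)
        res = fcm_cluster(traj, c=3, seed=1)
        ellps = identify_ellp(res, traj)
        truth = proteome.truth_table().set_index("protein_id")
        expected = {
            pid for pid in traj.index
            if truth.loc[pid, "turnover_class"] == "extreme"
            and truth.loc[pid, "f_obs_60d"] > 0.70
        }
        assert ellps == expected


class TestOverlap:
    def test_disjoint_sets(self):
        counts = intersection_counts({"a": {"x"}, "b": {"y"}, "c": {"z"}})
        assert counts[("a", "b")] == 0 and counts[("a", "b", "c")] == 0

    def test_identical_sets(self):
        s = {"p1", "p2", "p3"}
        counts = intersection_counts({"head": set(s), "muscle": set(s)})
        assert counts[("head", "muscle")] == 3

    def test_three_set_enumeration(self):
        sets = {"s1": {"A", "B", "C"}, "s2": {"B", "C", "D"}, "s3": {"C"}}
        inter = intersection_counts(sets)
        assert inter[("s1", "s2", "s3")] == 1
        regions = cross_tissue_overlap(sets)
        assert regions[("s1", "s2", "s3")] == 1      # {C}
        assert regions[("s1", "s2")] == 1            # {B}
        assert regions[("s1",)] == 1                 # {A}
        assert regions[("s2",)] == 1                 # {D}
        assert sum(regions.values()) == 4            # |union|

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            cross_tissue_overlap({"only": {"x"}})
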