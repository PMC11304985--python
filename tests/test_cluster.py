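import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqrec import cluster
from conftest import tiny_epochs


class TestAverageTrials:
    def test_identical_trials_mean_equals_trial(self):
        ep = tiny_epochs(n_trials_per_cond=4, seed=0)
        ep.data[:] = ep.data[0]
        means = cluster.average_trials(ep)
        assert np.allclose(means["memorized"], ep.data[0])

    def test_mean_matches_two_pass_summation(self):
        ep = tiny_epochs(n_trials_per_cond=8, seed=1)
        means = cluster.average_trials(ep)
        cond = ep.trials["condition"].to_numpy()
        keep = ep.trials["correct"].to_numpy() & (cond == "novel")
        acc = np.zeros(ep.data.shape[1:])
        for i in np.flatnonzero(keep):
            acc += ep.data[i]
        assert np.max(np.abs(means["novel"] - acc / keep.sum())) < 1e-12

    def test_incorrect_trials_excluded(self):
        ep = tiny_epochs(n_trials_per_cond=6, seed=2)
        idx = ep.trials.index[ep.trials["condition"] == "memorized"][0]
        before = cluster.average_trials(ep)["memorized"]
        ep.trials.loc[idx, "correct"] = False
        after = cluster.average_trials(ep)["memorized"]
        assert not np.allclose(before, after)

    def test_condition_without_correct_trials_rejected(self):
        ep = tiny_epochs(n_trials_per_cond=3, seed=3)
        ep.trials.loc[ep.trials["condition"] == "novel", "correct"] = False
        with pytest.raises(ValueError):
            cluster.average_trials(ep)


class TestCombinePlanar:
    def test_pythagorean_triple(self):
        assert cluster.combine_planar_pair(np.array([3.0]),
                                           np.array([4.0]))[0] == 5.0
        assert cluster.combine_planar_pair(np.zeros(3), np.zeros(3)).max() == 0

    def test_matches_rss_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 50))
        out = cluster.combine_planar_pair(a, b)
        assert np.max(np.abs(out - np.sqrt(a**2 + b**2))) < 1e-12
        assert (out >= 0).all()

    def test_epoch_level_combination(self):
        ep = tiny_epochs(n_trials_per_cond=2, n_sites=3, seed=1)
        combined = cluster.combine_planar(ep.data[0], ep.channels)
        assert combined.shape == (3, ep.data.shape[2])
        g = [i for i, ch in enumerate(ep.channels)
             if ch.kind == "planar_grad" and ch.site == 1]
        expected = np.sqrt(ep.data[0, g[0]]**2 + ep.data[0, g[1]]**2)
        assert np.allclose(combined[1], expected)

    def test_unpaired_gradiometer_rejected(self):
        ep = tiny_epochs(n_trials_per_cond=2, n_sites=2, seed=1)
        chs = list(ep.channels)
        object.__setattr__(chs[0], "pair_index", None) if False else None
        import dataclasses
        chs[0] = dataclasses.replace(chs[0], pair_index=None)
        with pytest.raises(ValueError):
            cluster.combine_planar(ep.data[0], chs)


class TestMassTTests:
    def test_identical_stacks_give_zero_t(self):
        a = np.random.default_rng(0).standard_normal((6, 4, 10))
        with pytest.warns(UserWarning):
            t, p = cluster.mass_ttests(a, a.copy())
        assert np.all(t == 0) and np.all(p == 1)

    def test_matches_textbook_paired_t(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((9, 3, 5))
        b = rng.standard_normal((9, 3, 5))
        t, p = cluster.mass_ttests(a, b)
        d = a - b
        n = d.shape[0]
        expected = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))
        assert np.max(np.abs(t - expected)) < 1e-10
        expected_p = 2 * stats.t.sf(np.abs(expected), n - 1)
        assert np.max(np.abs(p - expected_p)) < 1e-10

    def test_null_calibration_one_percent(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((12, 100, 50))
        b = rng.standard_normal((12, 100, 50))
        _, p = cluster.mass_ttests(a, b)
        frac = (p < 0.01).mean()
        assert 0.007 <= frac <= 0.013

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            cluster.mass_ttests(np.zeros((1, 2, 3)), np.zeros((1, 2, 3)))


class TestBinarize:
    def grid(self):
        return np.arange(12).reshape(3, 4)

    def test_nothing_significant_gives_zero_matrix(self):
        t = np.ones((12, 5))
        p = np.full((12, 5), 0.5)
        m = cluster.binarize(t, p, np.arange(5.0), 0.01, "positive",
                             self.grid())
        assert not m.values.any()

    def test_positive_and_negative_are_disjoint(self):
        rng = np.random.default_rng(3)
        t = rng.standard_normal((12, 20))
        p = rng.uniform(0, 0.05, (12, 20))
        times = np.arange(20.0)
        pos = cluster.binarize(t, p, times, 0.01, "positive", self.grid())
        neg = cluster.binarize(t, p, times, 0.01, "negative", self.grid())
        assert not np.logical_and(pos.values, neg.values).any()

    def test_count_matches_direct_comparison(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal((12, 20))
        p = rng.uniform(0, 0.05, (12, 20))
        m = cluster.binarize(t, p, np.arange(20.0), 0.01, "positive",
                             self.grid())
        assert m.values.sum() == ((p < 0.01) & (t > 0)).sum()

    def test_structural_cells_stay_empty(self):
        grid = np.full((3, 4), -1)
        grid.flat[1:] = np.arange(11)  # cell (0, 0) holds no sensor
        t = np.ones((11, 5))
        p = np.zeros((11, 5))
        m = cluster.binarize(t, p, np.arange(5.0), 0.01, "positive", grid)
        assert not m.values[0, 0].any()
        assert m.values[m.occupied].all()

    def test_sign_flip_mirrors_binarizations(self):
        rng = np.random.default_rng(5)
        t = rng.standard_normal((12, 20))
        p = rng.uniform(0, 0.05, (12, 20))
        times = np.arange(20.0)
        pos = cluster.binarize(t, p, times, 0.01, "positive", self.grid())
        neg_flipped = cluster.binarize(-t, p, times, 0.01, "negative",
                                       self.grid())
        assert np.array_equal(pos.values, neg_flipped.values)


def flood_fill_clusters(values, connectivity_fn):
    """Recursive flood-fill component labelling (independent oracle)."""
    values = values.astype(bool)
    seen = np.zeros_like(values)
    sizes = []
    import sys
    sys.setrecursionlimit(100000)

    def fill(cell):
        stack = [cell]
        count = 0
        while stack:
            c = stack.pop()
            if seen[c] or not values[c]:
                continue
            seen[c] = True
            count += 1
            stack.extend(n for n in connectivity_fn(c, values.shape))
        return count

    for idx in np.argwhere(values):
        idx = tuple(idx)
        if not seen[idx]:
            sizes.append(fill(idx))
    return sorted(sizes, reverse=True)


def face_neighbors(cell, shape):
    for ax in range(3):
        for d in (-1, 1):
            n = list(cell)
            n[ax] += d
            if 0 <= n[ax] < shape[ax]:
                yield tuple(n)


class TestFindClusters:
    def test_single_one_gives_single_cluster(self):
        v = np.zeros((4, 4, 6), dtype=bool)
        v[2, 1, 3] = True
        cl = cluster.find_clusters(v)
        assert len(cl) == 1 and cl[0].size == 1

    def test_full_block_is_one_cluster(self):
        v = np.zeros((5, 5, 5), dtype=bool)
        v[1:4, 1:4, 1:4] = True
        cl = cluster.find_clusters(v)
        assert len(cl) == 1 and cl[0].size == 27

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random((6, 6, 8)) < 0.3
        ours = sorted((c.size for c in cluster.find_clusters(v)),
                      reverse=True)
        oracle = flood_fill_clusters(v, face_neighbors)
        assert ours == oracle

    def test_time_window_reported_in_seconds(self):
        v = np.zeros((2, 2, 10), dtype=bool)
        v[0, 0, 4:7] = True
        times = np.linspace(0, 0.9, 10)
        cl = cluster.find_clusters(v, times=times)
        assert cl[0].time_window == (pytest.approx(0.4), pytest.approx(0.6))


def make_matrix(values, occupied=None, times=None):
    values = np.asarray(values, dtype=bool)
    if occupied is None:
        occupied = np.ones(values.shape[:2], dtype=bool)
    if times is None:
        times = np.arange(values.shape[-1], dtype=float)
    return cluster.BinaryStatMatrix(values, occupied, "positive", 0.01,
                                    times)


class TestClusterMCS:
    def test_all_zero_matrix_has_no_clusters(self):
        res = cluster.mcs_cluster_test(make_matrix(np.zeros((4, 4, 5))),
                                       n_perms=200, seed=0)
        assert res.clusters == []

    def test_permutation_conserves_ones(self):
        # with every occupied cell set to 1, conservation forces every
        # permutation's max cluster to equal the total count
        v = np.ones((3, 3, 4), dtype=bool)
        occ = np.ones((3, 3), dtype=bool)
        occ[0, 0] = False
        v[0, 0] = False
        res = cluster.mcs_cluster_test(make_matrix(v, occ), n_perms=150,
                                       seed=1)
        assert np.all(res.null_max_sizes == 8 * 4)

    def test_injected_block_is_significant(self):
        rng = np.random.default_rng(2)
        v = rng.random((10, 10, 50)) < 0.01
        v[2:7, 2:8, 10:35] = True  # 30% of cells, contiguous
        res = cluster.mcs_cluster_test(make_matrix(v), n_perms=1000, seed=3)
        top = res.clusters[0]
        assert top.significant
        assert top.mcs_p < 0.001

    def test_enlarging_a_cluster_never_raises_its_p(self):
        pvals = []
        for extent in (5, 15, 30):
            v = np.zeros((8, 8, 40), dtype=bool)
            v[2:5, 2:5, 5:5 + extent] = True
            res = cluster.mcs_cluster_test(make_matrix(v), n_perms=400,
                                           seed=4)
            pvals.append(res.clusters[0].mcs_p)
        assert pvals[0] >= pvals[1] >= pvals[2]

    def test_cluster_sizes_invariant_under_grid_symmetry(self):
        rng = np.random.default_rng(5)
        v = rng.random((7, 5, 12)) < 0.15
        a = [c.size for c in cluster.find_clusters(v)]
        b = [c.size for c in cluster.find_clusters(v[::-1])]
        c_ = [c.size for c in cluster.find_clusters(v.transpose(1, 0, 2))]
        assert sorted(a) == sorted(b) == sorted(c_)

    def test_per_timeslice_scope_also_conserves(self):
        v = np.zeros((4, 4, 6), dtype=bool)
        v[:2, :2, :] = True
        res = cluster.mcs_cluster_test(make_matrix(v), n_perms=120,
                                       scope="per_timeslice", seed=6)
        # 4 ones per slice guaranteed in every permutation
        assert res.null_max_sizes.min() >= 1

    def test_low_perm_count_warns(self):
        v = np.zeros((3, 3, 3), dtype=bool)
        v[0, 0, 0] = True
        with pytest.warns(UserWarning):
            cluster.mcs_cluster_test(make_matrix(v), n_perms=50, seed=0)


class TestMagnetometerFollowup:
    def test_empty_window_yields_no_followup(self):
        out = cluster.magnetometer_followup(
            np.zeros((3, 4, 10)), np.zeros((3, 4, 10)),
            np.linspace(0, 1, 10), None)
        assert not out.ran
        out2 = cluster.magnetometer_followup(
            np.zeros((3, 4, 10)), np.zeros((3, 4, 10)),
            np.linspace(0, 1, 10), (0.5, 0.5))
        assert not out2.ran

    def test_full_window_equals_direct_mcs(self):
        rng = np.random.default_rng(7)
        grid = np.arange(12).reshape(3, 4)
        a = rng.standard_normal((8, 12, 20))
        b = rng.standard_normal((8, 12, 20))
        a[:, 3:6, 5:15] += 2.0
        times = np.linspace(0, 1.9, 20)
        direct = cluster.sensor_mcs(a, b, times, grid=grid, n_perms=200,
                                    seed=1, tmin=0.0, tmax=2.0)
        follow = cluster.magnetometer_followup(a, b, times, (0.0, 2.0),
                                               grid=grid, n_perms=200, seed=1)
        assert follow.ran
        assert ([c.size for c in follow.positive.clusters]
                == [c.size for c in direct.positive.clusters])


class TestToneWindows:
    def test_constant_map_gives_identical_aggregates(self):
        times = np.arange(0, 1.4, 1 / 150)
        m = np.full((4, times.size), 3.3)
        out = cluster.tone_window_average(m, times)
        assert out.shape == (4, 5)
        assert np.allclose(out, 3.3)

    def test_boundary_sample_belongs_to_one_window(self):
        times = np.array([0.0, 0.125, 0.25, 0.375, 0.5, 0.75, 1.0, 1.25])
        m = np.zeros((1, times.size))
        m[0, 2] = 1.0  # the sample at exactly 250 ms
        out = cluster.tone_window_average(m, times)
        assert (out != 0).sum() == 1
        assert out[0, 1] != 0  # half-open bins: 0.25 s opens the second bin

    def test_aggregates_match_slice_means(self):
        rng = np.random.default_rng(8)
        times = np.arange(0, 1.3, 1 / 150)
        m = rng.standard_normal((3, times.size))
        out = cluster.tone_window_average(m, times)
        sel = (times >= 0.5) & (times < 0.75)
        assert np.allclose(out[:, 2], m[:, sel].mean(axis=1))

    def test_short_map_rejected(self):
        times = np.arange(0, 1.0, 1 / 150)
        with pytest.raises(ValueError):
            cluster.tone_window_average(np.zeros((2, times.size)), times)


class TestBehaviorScan:
    def test_perfect_correlation_spans_series(self):
        rng = np.random.default_rng(0)
        b = rng.standard_normal(12)
        d = np.tile(b[:, None], (1, 30))
        res = cluster.behavior_scan(d, b, n_perms=200, seed=0)
        assert len(res.clusters) == 1
        assert res.clusters.iloc[0]["length"] == 30

    def test_run_identification_matches_scan_oracle(self):
        rng = np.random.default_rng(1)
        binary = (rng.random(200) < 0.3).astype(int)
        runs = cluster.runs_of_ones(binary)
        # brute-force scan
        expected, cur = [], None
        for i, v in enumerate(binary):
            if v and cur is None:
                cur = i
            if not v and cur is not None:
                expected.append((cur, i))
                cur = None
        if cur is not None:
            expected.append((cur, len(binary)))
        assert runs == expected
        assert cluster.max_run_length(binary) == max(
            (b - a for a, b in expected), default=0)

    def test_vectorized_max_run_matches_scalar(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((40, 64)) < 0.4).astype(int)
        vec = cluster._max_run_rows(rows)
        scalar = np.array([cluster.max_run_length(r) for r in rows])
        assert np.array_equal(vec, scalar)

    def test_constant_behavior_warns_and_is_null(self):
        d = np.random.default_rng(3).standard_normal((10, 20))
        with pytest.warns(UserWarning):
            res = cluster.behavior_scan(d, np.full(10, 2.0), n_perms=150,
                                        seed=0)
        assert len(res.clusters) == 0

    def test_group_anova_mode_detects_group_effect(self):
        rng = np.random.default_rng(4)
        groups = np.array(["a", "b", "c"] * 7)
        d = 0.1 * rng.standard_normal((21, 25))
        d[groups == "a", 5:20] += 2.0
        res = cluster.behavior_scan(d, None, groups=groups, n_perms=500,
                                    seed=1)
        sig = res.clusters[res.clusters["significant"]]
        assert len(sig) >= 1
        assert sig.iloc[0]["length"] >= 10


def test_cluster_table_layout():
    v = np.zeros((3, 4, 6), dtype=bool)
    v[1, 1, 2:5] = True
    grid = np.arange(12).reshape(3, 4)
    m = cluster.BinaryStatMatrix(v, np.ones((3, 4), bool), "positive", 0.01,
                                 np.arange(6.0), grid=grid)
    res = cluster.mcs_cluster_test(m, n_perms=150, seed=0)
    table = cluster.cluster_table(res, grid)
    assert table.iloc[0]["size"] == 3
    assert table.iloc[0]["sites"] == "5"
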