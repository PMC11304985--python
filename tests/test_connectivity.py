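import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqrec import connectivity as con
from seqrec import synth


class TestSelectFastest:
    def trials(self, rts, correct=None):
        n = len(rts)
        return pd.DataFrame({
            "condition": ["memorized", "novel"] * (n // 2),
            "correct": correct if correct is not None else [True] * n,
            "rt_ms": rts,
        })

    def test_matches_sort_then_head_oracle(self):
        rng = np.random.default_rng(0)
        t = self.trials(rng.uniform(1000, 3000, 40))
        sel = con.select_fastest_correct(t, k=5)
        for cond in ("memorized", "novel"):
            sub = t[(t["condition"] == cond) & t["correct"]]
            oracle = set(sub.sort_values("rt_ms").index[:5])
            assert set(sel) & set(sub.index) == oracle

    def test_equal_rts_keep_first_k_in_order(self):
        t = self.trials([2000.0] * 20)
        sel = con.select_fastest_correct(t, k=3)
        mem = t.index[t["condition"] == "memorized"]
        assert sorted(set(sel) & set(mem)) == list(mem[:3])

    def test_k_equal_one_takes_single_fastest(self):
        t = self.trials([5000, 900, 3000, 800, 1000, 700])
        sel = con.select_fastest_correct(t, k=1)
        # fastest memorized sits at index 4 (1000 ms), fastest novel at 5
        assert set(sel) == {4, 5}

    def test_short_supply_takes_all_with_warning(self):
        correct = [True, True, False, False, True, False]
        t = self.trials([1.0] * 6, correct)
        with pytest.warns(UserWarning):
            sel = con.select_fastest_correct(t, k=20)
        assert set(sel) == {0, 1, 4}


class TestBandEnvelope:
    def test_unit_sinusoid_envelope_is_one(self):
        fs = 150.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        for filt in ("fft", "butter"):
            env = con.band_envelope(x, (2, 8), fs, filter=filt)
            interior = env[150:-150]  # 1 s guard on each side
            assert np.abs(interior - 1.0).max() < 0.02

    def test_am_carrier_envelope_tracks_modulator(self):
        fs = 150.0
        t = np.arange(int(10 * fs)) / fs
        mod = 0.6 + 0.3 * np.sin(2 * np.pi * 0.5 * t)
        x = mod * np.sin(2 * np.pi * 10 * t)
        env = con.band_envelope(x, (5, 15), fs)
        r = np.corrcoef(env[75:-75], mod[75:-75])[0, 1]
        assert r > 0.95

    def test_zero_input_gives_zero_envelope(self):
        assert con.band_envelope(np.zeros((3, 200)), (2, 8), 150.0).max() == 0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            con.band_envelope(np.zeros(100), (2, 90), 150.0)

    def test_band_at_nyquist_allowed_for_gamma(self):
        env = con.band_envelope(np.random.default_rng(0).standard_normal(300),
                                (32, 75), 150.0)
        assert np.isfinite(env).all()


class TestSFC:
    def test_diagonal_is_one_and_symmetric(self):
        env = np.random.default_rng(0).random((12, 100))
        r = con.sfc(env)
        assert np.allclose(np.diag(r), 1.0)
        assert np.max(np.abs(r - r.T)) < 1e-12
        assert (np.abs(r) <= 1).all()

    def test_independent_noise_has_small_mean_correlation(self):
        env = np.random.default_rng(1).random((30, 600))
        r = con.sfc(env)
        iu = np.triu_indices(30, 1)
        assert np.abs(r[iu]).mean() < 0.1

    def test_matches_pairwise_pearson_oracle(self):
        env = np.random.default_rng(2).random((6, 40))
        r = con.sfc(env)
        for i in range(6):
            for j in range(6):
                if i != j:
                    expected = stats.pearsonr(env[i], env[j]).statistic
                    assert r[i, j] == pytest.approx(expected, abs=1e-10)

    def test_constant_envelope_zeroed_with_warning(self):
        env = np.random.default_rng(3).random((4, 50))
        env[2] = 5.0
        with pytest.warns(UserWarning):
            r = con.sfc(env)
        assert np.all(r[2, [0, 1, 3]] == 0)
        assert r[2, 2] == 1.0


class TestBandANOVA:
    def test_dfs_for_67_participants_and_5_bands(self):
        rng = np.random.default_rng(0)
        gm = pd.DataFrame(rng.random((67, 5)),
                          columns=[b.name for b in con.DEFAULT_BANDS])
        res = con.band_anova(gm)
        assert (res.df_between, res.df_within) == (4, 330)

    def test_identical_band_means_give_zero_f(self):
        gm = pd.DataFrame(np.tile(np.random.default_rng(1).random(10),
                                  (3, 1)).T, columns=list("abc"))
        res = con.band_anova(gm)
        assert res.f == pytest.approx(0.0, abs=1e-20)

    def test_boosted_band_wins_all_tukey_pairs(self):
        rng = np.random.default_rng(2)
        gm = pd.DataFrame(0.1 * rng.standard_normal((30, 5)),
                          columns=[b.name for b in con.DEFAULT_BANDS])
        gm["theta"] += 1.0
        res = con.band_anova(gm)
        theta_pairs = res.tukey[(res.tukey["band_a"] == "theta")
                                | (res.tukey["band_b"] == "theta")]
        assert (theta_pairs["pvalue"] < 0.001).all()
        for _, row in theta_pairs.iterrows():
            diff = row["mean_diff"]
            assert diff > 0 if row["band_a"] == "theta" else diff < 0


class TestEdgeWilcoxon:
    def test_identical_stacks_give_zero_z(self):
        a = np.random.default_rng(0).random((8, 5, 5))
        a = (a + a.transpose(0, 2, 1)) / 2
        z = con.edge_wilcoxon(a, a.copy())
        assert np.all(z == 0)

    def test_matches_scipy_signed_rank_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.random((12, 4, 4))
        b = rng.random((12, 4, 4))
        a, b = [(x + x.transpose(0, 2, 1)) / 2 for x in (a, b)]
        z = con.edge_wilcoxon(a, b)
        for i in range(4):
            for j in range(i + 1, 4):
                res = stats.wilcoxon(a[:, i, j], b[:, i, j],
                                     correction=False, method="approx")
                assert abs(z[i, j]) == pytest.approx(abs(res.zstatistic),
                                                     abs=1e-10)

    def test_swapping_task_and_baseline_flips_signs(self):
        rng = np.random.default_rng(2)
        a = rng.random((10, 6, 6))
        b = rng.random((10, 6, 6))
        a, b = [(x + x.transpose(0, 2, 1)) / 2 for x in (a, b)]
        assert np.allclose(con.edge_wilcoxon(a, b),
                           -con.edge_wilcoxon(b, a))


class TestDegreeMCS:
    def test_degree_equals_row_sum_oracle(self):
        rng = np.random.default_rng(0)
        B = rng.random((20, 20))
        B = (B + B.T) / 2
        deg = con.weighted_degree(B)
        oracle = np.array([
            sum(B[v, u] for u in range(20) if u != v) for v in range(20)
        ])
        assert np.max(np.abs(deg - oracle)) < 1e-12

    def test_permutations_conserve_edge_weights_and_degree_sum(self):
        rng = np.random.default_rng(1)
        B = rng.random((15, 15))
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        res = con.degree_mcs(B, n_perms=200, seed=2, keep_null=True)
        total = 2 * B[np.triu_indices(15, 1)].sum()
        assert np.allclose(res.null_degrees.sum(axis=1), total)
        assert np.allclose(res.degree.sum(), total)

    def test_hub_row_is_the_only_significant_node(self):
        rng = np.random.default_rng(3)
        B = 0.05 * rng.standard_normal((30, 30))
        B = (B + B.T) / 2
        B[4, :] = B[:, 4] = 3.0
        np.fill_diagonal(B, 0)
        res = con.degree_mcs(B, n_perms=500, seed=4)
        assert res.significant[4]
        assert res.significant.sum() == 1

    def test_significance_invariant_under_node_relabelling(self):
        rng = np.random.default_rng(5)
        B = 0.05 * rng.standard_normal((20, 20))
        B = (B + B.T) / 2
        B[7, :] = B[:, 7] = 2.0
        np.fill_diagonal(B, 0)
        perm = rng.permutation(20)
        res1 = con.degree_mcs(B, n_perms=400, seed=6)
        res2 = con.degree_mcs(B[np.ix_(perm, perm)], n_perms=400, seed=6)
        assert np.array_equal(res1.significant[perm], res2.significant)

    def test_pvalue_rule_uses_per_band_alpha(self):
        rng = np.random.default_rng(7)
        B = rng.random((10, 10))
        B = (B + B.T) / 2
        with pytest.warns(UserWarning):
            res = con.degree_mcs(B, n_perms=99, alpha=0.001, n_bands=5,
                                 rule="pvalue")
        assert res.alpha_per_band == pytest.approx(2.0e-4)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            con.degree_mcs(np.arange(9.0).reshape(3, 3))


class TestHubRecoveryPipeline:
    def test_degree_mcs_recovers_injected_hubs(self):
        """End-to-end: shared-envelope hubs -> SFC -> Wilcoxon -> degree MCS
        flags the hub set and at most 2 non-hubs in the hub band.

        The signed-rank z per edge saturates at sqrt(3n)/2 for n
        participants, so separating 8 hubs (7 saturated edges each) from the
        sqrt(89) degree noise floor requires a large cohort; 100 synthetic
        participants with the node-wise permutation null give the power this
        recovery check needs.
        """
        hubs = frozenset(range(8))
        gt = synth.GroundTruth(hub_parcels=hubs, hub_band=(2.0, 8.0))
        task_stack, base_stack = [], []
        for p in range(100):
            task, base = synth.generate_parcels(
                n_trials=20, ground_truth=gt, shared_envelope_r=0.9,
                seed=100 + p, noise_sd=0.5, p_correct=1.0)
            mats = connectivity_band(task, base)
            task_stack.append(mats["task"])
            base_stack.append(mats["baseline"])
        B = con.edge_wilcoxon(np.stack(task_stack), np.stack(base_stack))
        res = con.degree_mcs(B, n_perms=1000, seed=0, pool="nodewise")
        flagged = set(np.flatnonzero(res.significant))
        assert hubs <= flagged
        assert len(flagged - hubs) <= 2


def connectivity_band(task, base, band=con.DEFAULT_BANDS[1]):
    return {
        role: con.sfc(con.band_envelope(con.mean_trial(ps, k), band,
                                        task.sfreq))
        for role, ps, k in (("task", task, 10), ("baseline", base, None))
    }
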