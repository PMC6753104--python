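import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netcomm as nc
from netcomm import ValidationError
from netcomm.communication import CohortTensor


def tensor_from_delta(delta_ij, n=3, i=0, j=1):
    """Minimal tensor whose (i, j) pairwise differences equal ``delta_ij``."""
    k = len(delta_ij)
    values = np.zeros((n, n, k))
    values[i, j, :] = delta_ij
    return CohortTensor(values, subject_ids=[f"s{x}" for x in range(k)],
                        measure="synthetic")


class TestPairwise:
    def test_hand_computed_t_statistic(self):
        # delta = [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641, df=2, p = 0.0742
        res = nc.pairwise_asymmetry_test(tensor_from_delta([1.0, 2.0, 3.0]))
        assert res.A[0, 1] == pytest.approx(3.4641016, abs=1e-6)
        assert res.p_raw[0, 1] == pytest.approx(0.074180, abs=1e-5)

    def test_symmetric_tensor_gives_zero_statistics(self, rng):
        base = rng.uniform(size=(5, 5, 4))
        sym = base + base.transpose(1, 0, 2)
        tensor = CohortTensor(sym, subject_ids=list("abcd"), measure="synthetic")
        res = nc.pairwise_asymmetry_test(tensor)
        assert np.array_equal(res.A, np.zeros((5, 5)))
        assert not res.sig.any()

    def test_antisymmetry_exact(self, rng):
        values = rng.uniform(size=(6, 6, 8))
        tensor = CohortTensor(values, subject_ids=[f"s{k}" for k in range(8)],
                              measure="synthetic")
        res = nc.pairwise_asymmetry_test(tensor)
        assert np.array_equal(res.A, -res.A.T)
        assert np.array_equal(res.p_raw, res.p_raw.T)
        assert np.array_equal(res.sig, res.sig.T)

    def test_bonferroni_arithmetic_exact(self, rng):
        values = rng.uniform(size=(6, 6, 5))
        tensor = CohortTensor(values, subject_ids=[f"s{k}" for k in range(5)],
                              measure="synthetic")
        res = nc.pairwise_asymmetry_test(tensor)
        m = 6 * 5 // 2
        iu, ju = np.triu_indices(6, 1)
        assert np.array_equal(res.p_corrected[iu, ju],
                              np.minimum(1.0, res.p_raw[iu, ju] * m))

    def test_zero_variance_sentinel(self):
        res = nc.pairwise_asymmetry_test(tensor_from_delta([2.0, 2.0, 2.0]))
        assert np.isposinf(res.A[0, 1]) and np.isneginf(res.A[1, 0])
        assert res.p_raw[0, 1] == 0.0
        res0 = nc.pairwise_asymmetry_test(tensor_from_delta([0.0, 0.0, 0.0]))
        assert res0.A[0, 1] == 0.0 and res0.p_raw[0, 1] == 1.0

    def test_single_subject_directs_to_single_network_index(self):
        tensor = CohortTensor(np.zeros((3, 3, 1)), subject_ids=["s0"],
                              measure="synthetic")
        with pytest.raises(ValidationError, match="single_network_asymmetry"):
            nc.pairwise_asymmetry_test(tensor)

    def test_signed_rank_agrees_in_sign_with_t_for_strong_effects(self, rng):
        values = rng.normal(size=(5, 5, 12))
        values += np.fromfunction(lambda i, j, k: 0.8 * (i < j), (5, 5, 12))
        tensor = CohortTensor(values, subject_ids=[f"s{k}" for k in range(12)],
                              measure="synthetic")
        res_t = nc.pairwise_asymmetry_test(tensor, test="t")
        res_w = nc.pairwise_asymmetry_test(tensor, test="signed_rank")
        strong = np.abs(res_t.A) > 3
        assert (np.sign(res_w.A[strong]) == np.sign(res_t.A[strong])).all()


class TestRegional:
    def test_symmetric_tensor_all_neutral(self, rng):
        base = rng.uniform(size=(5, 5, 6))
        sym = base + base.transpose(1, 0, 2)
        tensor = CohortTensor(sym, subject_ids=[f"s{k}" for k in range(6)],
                              measure="synthetic")
        table = nc.regional_asymmetry_test(tensor)
        assert (table["role"] == "neutral").all()
        assert np.allclose(table["a"], 0.0)

    def test_inflated_sender_recovered_and_brute_force_agreement(self, rng):
        n, k = 4, 6
        values = rng.uniform(size=(n, n, k))
        values[0, :, :] += 1.0  # node 0 sends with higher efficiency
        idx = np.arange(n)
        values[idx, idx, :] = 0
        tensor = CohortTensor(values, subject_ids=[f"s{x}" for x in range(k)],
                              measure="synthetic")
        table = nc.regional_asymmetry_test(tensor)
        assert table.iloc[0]["role"] == "sender"
        assert table.iloc[0]["a"] > 0
        # brute-force recomputation of S, R, delta, t
        for i in range(n):
            S = np.array([values[i, [x for x in range(n) if x != i], kk].mean()
                          for kk in range(k)])
            R = np.array([values[[x for x in range(n) if x != i], i, kk].mean()
                          for kk in range(k)])
            d = S - R
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(k))
            assert table.iloc[i]["a"] == pytest.approx(t_ref, abs=1e-9)
            assert table.iloc[i]["s"] == pytest.approx(S.mean(), abs=1e-12)

    def test_navigation_aggregates_use_median(self):
        values = np.zeros((3, 3, 5))
        values[0, 1, :] = [1, 1, 1, 1, 100]  # outlier subject
        tensor = CohortTensor(values, subject_ids=[f"s{x}" for x in range(5)],
                              measure="nav")
        table = nc.regional_asymmetry_test(tensor)
        assert table.iloc[0]["s"] == pytest.approx(0.5)  # median of S(0, k)


class TestDownsample:
    def test_hand_average(self):
        E = np.zeros((4, 4))
        E[0, 2], E[0, 3], E[1, 2], E[1, 3] = 2, 3, 4, 5
        part = {"n0": "A", "n1": "A", "n2": "B", "n3": "B"}
        down, subs = nc.subsystem_downsample(E, part)
        assert subs == ["A", "B"]
        assert down[0, 1] == pytest.approx(3.5)

    def test_constant_matrix_stays_constant(self):
        E = np.full((6, 6), 7.0)
        np.fill_diagonal(E, 0)
        part = {f"n{k}": f"g{k % 2}" for k in range(6)}
        down, _ = nc.subsystem_downsample(E, part)
        off = ~np.eye(2, dtype=bool)
        assert np.allclose(down[off], 7.0)
        assert np.allclose(np.diag(down), 7.0)  # self-pairs excluded

    def test_singleton_partition_is_identity_off_diagonal(self, rng):
        E = rng.uniform(size=(4, 4))
        part = {f"n{k}": f"g{k}" for k in range(4)}
        down, subs = nc.subsystem_downsample(E, part)
        assert np.allclose(down - np.diag(np.diag(down)),
                           E - np.diag(np.diag(E)))

    def test_commutes_with_subject_averaging(self, rng):
        values = rng.uniform(size=(6, 6, 4))
        part = {f"n{k}": f"g{k % 3}" for k in range(6)}
        tensor = CohortTensor(values, subject_ids=list("abcd"), measure="synthetic")
        down_tensor = nc.subsystem_downsample(tensor, part)
        down_mean, _ = nc.subsystem_downsample(values.mean(axis=2), part)
        assert np.allclose(down_tensor.values.mean(axis=2), down_mean)


class TestSingleNetworkIndex:
    def test_formula_values(self):
        E = np.array([[0.0, 2.0], [1.0, 0.0]])
        a = nc.single_network_asymmetry(E)
        assert a[0, 1] == pytest.approx(1 / 3)
        assert a[1, 0] == pytest.approx(-1 / 3)
        E_eq = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert nc.single_network_asymmetry(E_eq)[0, 1] == 0.0
        E_one = np.array([[0.0, 3.0], [0.0, 0.0]])
        assert nc.single_network_asymmetry(E_one)[0, 1] == 1.0

    def test_exclude_connected_masks_pairs(self):
        E = np.array([[0.0, 2.0, 3.0], [1.0, 0.0, 4.0], [1.0, 1.0, 0.0]])
        w = np.zeros((3, 3))
        w[0, 1] = 1.0  # 0 and 1 directly connected
        net = nc.WeightedNetwork(w, directed=True)
        a = nc.single_network_asymmetry(E, exclude_connected=True, net=net)
        assert np.isnan(a[0, 1]) and np.isnan(a[1, 0])
        assert np.isfinite(a[0, 2])

    def test_regional_index_star_hub_positive(self):
        # directed star, all edges outward from the hub; E = reachability
        n = 4
        E = np.zeros((n, n))
        E[0, 1:] = 1.0
        ri = nc.regional_index(E)
        assert ri[0] == 1.0
        assert (ri[1:] == -1.0).all()

    def test_regional_index_symmetric_zero_and_bounded(self, rng):
        E = rng.uniform(size=(6, 6))
        sym = E + E.T
        np.fill_diagonal(sym, 0)
        assert np.allclose(nc.regional_index(sym), 0.0)
        ri = nc.regional_index(rng.uniform(size=(6, 6)))
        ok = np.isfinite(ri)
        assert ((ri[ok] >= -1) & (ri[ok] <= 1)).all()


class TestCorrelationRegression:
    def test_perfect_correlations(self, rng):
        a = rng.normal(size=(5, 5))
        a = a - a.T
        r, p, n = nc.asymmetry_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert n == 10
        r_neg, _, _ = nc.asymmetry_correlation(a, -a)
        assert r_neg == pytest.approx(-1.0)

    def test_linear_scaling_perfect(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[np.triu_indices(3, 1)] = [1, 2, 3]
        b[np.triu_indices(3, 1)] = [2, 4, 6]
        r, _, _ = nc.asymmetry_correlation(a, b)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="3"):
            nc.asymmetry_correlation(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_regress_out_exact_fit_and_properties(self, rng):
        x = rng.uniform(size=20)
        resid = nc.regress_out_covariate(2 * x + 5, x)
        assert np.allclose(resid, 0.0, atol=1e-10)
        y = rng.normal(size=20)
        r = nc.regress_out_covariate(y, x)
        assert abs(np.corrcoef(r, x)[0, 1]) < 1e-10
        assert abs(r.sum()) < 1e-9

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            nc.regress_out_covariate(np.arange(5.0), np.ones(5))


class TestRankSum:
    def test_exact_small_sample_p(self):
        stat, p = nc.group_comparison_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = nc.group_comparison_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_monotone_transform(self, rng):
        a = rng.uniform(1, 2, size=8)
        b = rng.uniform(1.5, 3, size=9)
        s1, p1 = nc.group_comparison_ranksum(a, b)
        s2, p2 = nc.group_comparison_ranksum(np.exp(a), np.exp(b))
        assert s1 == s2 and p1 == pytest.approx(p2, abs=1e-12)


class TestDirectedTensor:
    def test_absolute_value_and_diagonal(self):
        mats = [np.array([[1.0, -2.0], [1.0, 3.0]])]
        tensor = nc.prepare_directed_tensor(mats)
        assert tensor.values[0, 1, 0] == 2.0
        assert tensor.values[0, 0, 0] == 0.0
        raw = nc.prepare_directed_tensor(mats, take_abs=False)
        assert raw.values[0, 1, 0] == -2.0

    def test_stack_order_and_size_mismatch(self):
        a, b = np.zeros((2, 2)), np.ones((2, 2))
        tensor = nc.prepare_directed_tensor([a, b])
        assert tensor.values[0, 1, 1] == 1.0
        with pytest.raises(ValidationError):
            nc.prepare_directed_tensor([a, np.zeros((3, 3))])


class TestCohortTypeIandRecovery:
    def test_null_tensor_type_one_error_near_alpha(self):
        hits = total = 0
        for rep in range(60):
            tensor = nc.generate_null_tensor(12, 15, seed=rep)
            res = nc.pairwise_asymmetry_test(tensor, correction="none")
            iu, ju = np.triu_indices(12, 1)
            hits += int((res.p_raw[iu, ju] < 0.05).sum())
            total += iu.size
        frac = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(frac - 0.05) < 4.5 * se

    def test_cohort_t_tracks_noiseless_index(self):
        spec = nc.CohortSpec(n_nodes=24, n_subjects=16, target_density=0.25,
                             noise_sd=0.05, seed=11)
        subjects, group = nc.generate_geometric_cohort(spec)
        tensor = nc.cohort_communication(subjects, "dif")
        A = nc.pairwise_asymmetry_test(tensor).A
        idx = nc.single_network_asymmetry(nc.diffusion_efficiency(group)[0].eff)
        iu, ju = np.triu_indices(24, 1)
        rho = stats.spearmanr(A[iu, ju], idx[iu, ju]).statistic
        assert rho > 0.9
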