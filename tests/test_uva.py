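import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psychnet import (
    Network,
    SyntheticSpec,
    adaptive_alpha,
    build_merge_sets,
    generate_factor_data,
    merge_items,
    run_uva,
    wto,
)
from psychnet.data import ResponseMatrix
from psychnet.uva import UvaConfig, UvaError, one_factor_fit, redundancy_pvalues


def net_from(w):
    w = np.asarray(w, dtype=float)
    return Network(weights=w, node_ids=tuple(str(i) for i in range(w.shape[0])))


class TestWto:
    def test_empty_network_has_zero_overlap(self):
        assert np.all(wto(net_from(np.zeros((4, 4)))) == 0)

    def test_two_node_single_edge_hand_case(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        # omega = (0 + 0.5) / (0.5 + 1 - 0.5) = 0.5
        assert wto(net_from(w))[0, 1] == pytest.approx(0.5)

    def test_unit_triangle_hand_case(self):
        w = np.ones((3, 3)) - np.eye(3)
        omega = wto(net_from(w))
        # omega = (1 + 1) / (2 + 1 - 1) = 1 for every pair
        iu = np.triu_indices(3, 1)
        assert np.allclose(omega[iu], 1.0)

    def test_symmetric_and_sign_flip_invariant(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(-0.5, 0.5, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        omega = wto(net_from(w))
        assert np.allclose(omega, omega.T)
        assert np.allclose(omega, wto(net_from(-w)))

    def test_asymmetric_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        with pytest.raises(UvaError, match="symmetric"):
            wto(w)


class TestRedundancyPvalues:
    def make_omega(self, values):
        p = 6
        omega = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        omega[iu] = values
        return omega + omega.T

    def test_monotone_max_omega_gets_min_p(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2.0, 0.1, 15)
        omega = self.make_omega(vals)
        pvals = redundancy_pvalues(omega)
        argmax = max(pvals, key=lambda k: omega[k])
        assert pvals[argmax] == min(pvals.values())

    def test_equal_overlaps_get_equal_pvalues_empirically(self):
        omega = self.make_omega(np.full(15, 0.2))
        pvals = redundancy_pvalues(omega, null_family="empirical")
        assert len(set(pvals.values())) == 1

    def test_zero_variance_degenerates_for_gamma_fit(self):
        omega = self.make_omega(np.full(15, 0.2))
        with pytest.raises(UvaError, match="degenerate"):
            redundancy_pvalues(omega, null_family="gamma")

    def test_gamma_tail_matches_closed_form(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 0.1, size=4950)
        vals[0] = 0.9
        p = 100
        omega = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        omega[iu] = vals
        omega = omega + omega.T
        pvals = redundancy_pvalues(omega)
        target = pvals[(0, 1)]  # the 0.9 entry sits at pair (0, 1)
        assert target == pytest.approx(stats.gamma.sf(0.9, a=2.0, scale=0.1), abs=1e-3)

    def test_too_few_pairs_rejected(self):
        omega = self.make_omega(np.r_[np.full(5, 0.2), np.zeros(10)])
        with pytest.raises(UvaError, match="nonzero"):
            redundancy_pvalues(omega)


class TestAdaptiveAlpha:
    def test_reference_size_returns_base_alpha(self):
        assert adaptive_alpha(10, base_alpha=0.05, n_ref=10) == pytest.approx(0.05)

    def test_shrinks_with_test_count(self):
        assert adaptive_alpha(1000) < adaptive_alpha(100) < adaptive_alpha(10)

    def test_matches_direct_formula_evaluation(self):
        q = stats.chi2.ppf(0.95, df=1)
        expected = 0.05 * np.sqrt(10 * (np.log(10) + q)) / np.sqrt(
            1000 * (np.log(1000) + q)
        )
        assert adaptive_alpha(1000, 0.05, 10) == pytest.approx(expected, rel=1e-12)

    def test_invalid_count_rejected(self):
        with pytest.raises(UvaError):
            adaptive_alpha(0)


class TestBuildMergeSets:
    def test_single_pair_merges_both(self):
        chains, sets = build_merge_sets([("a", "b")], {("a", "b"): 0.5})
        assert chains == [["a", "b"]]
        assert sets == [["a", "b"]]

    def test_path_with_central_target_takes_neighbors(self):
        omega = {("a", "b"): 0.4, ("b", "c"): 0.4}
        chains, sets = build_merge_sets([("a", "b"), ("b", "c")], omega)
        assert sets == [["a", "b", "c"]]  # b is the hub, a and c adjacent

    def test_four_node_path_defers_far_member(self):
        omega = {("a", "b"): 0.5, ("b", "c"): 0.4, ("c", "d"): 0.2}
        chains, sets = build_merge_sets(
            [("a", "b"), ("b", "c"), ("c", "d")], omega
        )
        # summed omega: b=0.9 is the target; d is not adjacent to b
        assert sets == [["a", "b", "c"]]
        assert chains == [["a", "b", "c", "d"]]


class TestMergeItems:
    def test_sum_method_averages_rows(self):
        data = ResponseMatrix(values=pd.DataFrame({"a": [0, 0], "b": [4, 4], "c": [1, 2]}))
        merged, mm = merge_items(data, [["a", "b"]], method="sum")
        assert list(merged.values["a_b"]) == [2.0, 2.0]
        assert mm == {"a_b": ["a", "b"]}
        assert "a_b" in merged.continuous_items

    def test_latent_score_tracks_perfectly_correlated_sources(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 500)
        data = ResponseMatrix(values=pd.DataFrame({"a": x, "b": x, "c": rng.integers(0, 5, 500)}))
        merged, _ = merge_items(data, [["a", "b"]], method="latent")
        r = np.corrcoef(merged.values["a_b"], x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_one_factor_loadings_recovered_from_simulation(self):
        rng = np.random.default_rng(4)
        lam = np.array([0.9, 0.8, 0.7])
        n = 20000
        f = rng.standard_normal(n)
        x = f[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(1 - lam**2)
        est, _ = one_factor_fit(np.corrcoef(x, rowvar=False))
        assert np.abs(est - lam).max() < 0.05

    def test_two_item_fit_uses_equal_loadings(self):
        S = np.array([[1.0, 0.64], [0.64, 1.0]])
        lam, psi = one_factor_fit(S)
        assert lam == pytest.approx([0.8, 0.8])
        assert psi == pytest.approx([0.36, 0.36])

    def test_overlapping_sets_rejected(self):
        data = ResponseMatrix(values=pd.DataFrame({"a": [0, 1], "b": [1, 2], "c": [2, 3]}))
        with pytest.raises(UvaError, match="disjoint"):
            merge_items(data, [["a", "b"], ["b", "c"]])


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(
        n_respondents=600, n_factors=3, items_per_factor=5,
        loading=0.7, factor_corr=0.2, seed=21, redundancy_pairs=(("3", 0.15),),
    )
    return generate_factor_data(spec)


class TestRunUva:

    def test_planted_duplicate_is_merged(self, planted):
        data, _ = planted
        reduced, report = run_uva(data)
        assert "3_3r" in report.merge_map
        assert report.merge_map["3_3r"] == ["3", "3r"]
        assert reduced.n_items < data.n_items

    def test_second_pass_is_idempotent(self, planted):
        data, _ = planted
        reduced, _ = run_uva(data)
        again, report2 = run_uva(reduced)
        assert report2.merge_map == {}
        assert again.item_ids == reduced.item_ids

    def test_independence_data_merges_nothing(self):
        spec = SyntheticSpec(
            n_respondents=500, n_factors=2, items_per_factor=6,
            loading=0.0, factor_corr=0.0, seed=22,
        )
        data, _ = generate_factor_data(spec)
        reduced, report = run_uva(data, UvaConfig(correlation="pearson"))
        assert report.merge_map == {}
        assert reduced.values.equals(data.values)
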