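import numpy as np
import pytest

from psychnet import (
    EgaSettings,
    Network,
    Partition,
    align_labels,
    bootstrap_ega,
    case_drop_stability,
    item_stability,
    median_network,
    ncomm_distribution,
    structural_consistency,
)
from psychnet.bootstrap import BootstrapEnsemble
from psychnet.simulate import SyntheticSpec, generate_factor_data

FAST = EgaSettings(correlation="pearson", restarts=2, bootstrap_restarts=1,
                   n_lambda=40)


@pytest.fixture(scope="module")
def small_data():
    spec = SyntheticSpec(
        n_respondents=400, n_factors=3, items_per_factor=4,
        loading=0.75, factor_corr=0.1, seed=31,
    )
    return generate_factor_data(spec)[0]


@pytest.fixture(scope="module")
def small_ensemble(small_data):
    return bootstrap_ega(small_data, B=12, seed=7, settings=FAST)


def make_ensemble(weight_list, partitions, node_ids):
    nets = [Network(weights=w, node_ids=node_ids) for w in weight_list]
    reps = [(n, p, p.n_communities) for n, p in zip(nets, partitions)]
    return BootstrapEnsemble(
        replicates=reps,
        empirical_network=nets[0],
        empirical_partition=partitions[0],
        seed=0,
    )


class TestBootstrapEga:
    def test_identity_resample_reproduces_empirical_network(self, small_data):
        ens = bootstrap_ega(
            small_data, B=1, seed=3, settings=FAST,
            resampler=lambda rng, n: np.arange(n),
        )
        net, part, k = ens.replicates[0]
        assert np.allclose(net.weights, ens.empirical_network.weights)

    def test_same_seed_gives_identical_ensembles(self, small_data):
        e1 = bootstrap_ega(small_data, B=3, seed=5, settings=FAST)
        e2 = bootstrap_ega(small_data, B=3, seed=5, settings=FAST)
        for (n1, p1, k1), (n2, p2, k2) in zip(e1.replicates, e2.replicates):
            assert np.array_equal(n1.weights, n2.weights)
            assert p1.as_dict() == p2.as_dict()

    def test_planted_dimension_count_is_modal(self, small_ensemble):
        summary = ncomm_distribution(small_ensemble)
        assert summary["mode"] == 3
        assert summary["ci95_low"] <= summary["median"] <= summary["ci95_high"]

    def test_item_stability_near_one_in_easy_regime(self, small_ensemble):
        stab, table = item_stability(small_ensemble)
        assert min(stab.values()) >= 0.9
        assert np.allclose(table.sum(axis=1), 1.0)


class TestMedianNetwork:
    def test_identical_replicates_return_themselves(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        part = Partition.from_dict({"0": 0, "1": 0, "2": 1})
        ens = make_ensemble([w, w, w], [part, part, part], ("0", "1", "2"))
        assert np.allclose(median_network(ens).weights, w)

    def test_elementwise_median_of_three(self):
        mats = []
        for v in (0.1, 0.2, 0.6):
            w = np.zeros((2, 2))
            w[0, 1] = w[1, 0] = v
            mats.append(w)
        part = Partition.from_dict({"0": 0, "1": 0})
        ens = make_ensemble(mats, [part] * 3, ("0", "1"))
        assert median_network(ens).weights[0, 1] == pytest.approx(0.2)

    def test_median_is_symmetric_with_zero_diagonal(self, small_ensemble):
        med = median_network(small_ensemble)
        assert np.allclose(med.weights, med.weights.T)
        assert np.all(np.diag(med.weights) == 0)


class TestAlignLabels:
    def test_swapped_labels_realign_to_reference(self):
        ref = Partition.from_dict({"a": 0, "b": 0, "c": 1, "d": 1})
        rep = Partition.from_dict({"a": 1, "b": 1, "c": 0, "d": 0})
        out = align_labels(rep, ref)
        assert out.as_dict() == ref.as_dict()

    def test_split_community_keeps_label_on_larger_half(self):
        ref = Partition.from_dict({c: 0 for c in "abcd"} | {"e": 1, "f": 1})
        rep = Partition.from_dict(
            {"a": 0, "b": 0, "c": 0, "d": 2, "e": 1, "f": 1}
        )
        out = align_labels(rep, ref)
        d = out.as_dict()
        assert d["a"] == d["b"] == d["c"] == 0  # larger fragment takes label 0
        assert d["e"] == d["f"] == 1
        assert d["d"] not in (0, 1)  # surplus community gets a fresh label

    def test_alignment_never_changes_comembership(self):
        rng = np.random.default_rng(2)
        nodes = tuple(f"n{i}" for i in range(30))
        ref = Partition.from_dict(dict(zip(nodes, rng.integers(0, 4, 30))))
        rep = Partition.from_dict(dict(zip(nodes, rng.integers(0, 4, 30))))
        out = align_labels(rep, ref)
        before = rep.reordered(nodes)
        after = out.reordered(nodes)
        same_before = before[:, None] == before[None, :]
        same_after = after[:, None] == after[None, :]
        assert np.array_equal(same_before, same_after)


class TestStabilityMetrics:
    def two_state_ensemble(self):
        """Half the replicates split the second dimension in two."""
        nodes = tuple("abcdef")
        w = np.zeros((6, 6))
        whole = Partition.from_dict(dict(zip(nodes, [0, 0, 0, 1, 1, 1])))
        split = Partition.from_dict(dict(zip(nodes, [0, 0, 0, 1, 2, 2])))
        parts = [whole, whole, split, split]
        ens = make_ensemble([w] * 4, parts, nodes)
        ens.empirical_partition = whole
        return ens

    def test_half_split_dimension_scores_half(self):
        cons = structural_consistency(self.two_state_ensemble())
        assert cons[0] == pytest.approx(1.0)
        assert cons[1] == pytest.approx(0.5)

    def test_consistency_bounded_by_member_item_stability(self):
        ens = self.two_state_ensemble()
        stab, _ = item_stability(ens)
        cons = structural_consistency(ens)
        emp = ens.empirical_partition
        for label, value in cons.items():
            member_floor = min(stab[n] for n in emp.members(label))
            assert value <= member_floor + 1e-12

    def test_fully_stable_item_scores_one(self):
        ens = self.two_state_ensemble()
        stab, _ = item_stability(ens)
        assert stab["a"] == pytest.approx(1.0)

    def test_ncomm_summary_arithmetic(self):
        nodes = ("a", "b")
        w = np.zeros((2, 2))
        counts = [1, 2, 2, 2, 3]
        parts = []
        for k in counts:
            labels = [0, 0] if k == 1 else ([0, 1] if k == 2 else [0, 1])
            parts.append(Partition.from_dict(dict(zip(nodes, labels))))
        ens = make_ensemble([w] * 5, parts, nodes)
        ens.replicates = [(n, p, k) for (n, p, _), k in zip(ens.replicates, counts)]
        summary = ncomm_distribution(ens)
        assert summary["mode"] == 2
        assert summary["median"] == 2
        assert summary["mean"] == pytest.approx(2.0)

    def test_degenerate_all_equal_counts_collapse_ci(self):
        nodes = ("a", "b")
        part = Partition.from_dict({"a": 0, "b": 1})
        ens = make_ensemble([np.zeros((2, 2))] * 3, [part] * 3, nodes)
        summary = ncomm_distribution(ens)
        assert summary["ci95_low"] == summary["ci95_high"] == 2.0


class TestCaseDropStability:
    def test_strong_structure_keeps_strength_stable(self, small_data):
        cs, table = case_drop_stability(
            small_data, metric="strength", drop_fractions=(0.0, 0.25, 0.5),
            B=8, seed=4, settings=FAST,
        )
        assert table.loc[0, "mean_corr"] == pytest.approx(1.0)
        assert cs >= 0.25

    def test_invalid_drop_fraction_rejected(self, small_data):
        with pytest.raises(ValueError):
            case_drop_stability(small_data, drop_fractions=(1.0,), B=2)

    def test_stricter_threshold_never_raises_cs(self, small_data):
        kwargs = dict(
            metric="strength", drop_fractions=(0.0, 0.3, 0.6), B=6, seed=9,
            settings=FAST,
        )
        cs_loose, _ = case_drop_stability(small_data, corr_threshold=0.5, **kwargs)
        cs_strict, _ = case_drop_stability(small_data, corr_threshold=0.9, **kwargs)
        assert cs_strict <= cs_loose
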