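import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psychnet import (
    ItemKey,
    Network,
    Partition,
    centrality_table,
    expected_influence,
    network_loadings,
    strength,
    subscale_agreement,
    top_bottom_nodes,
)
from psychnet.metrics import MetricsError


def net_from(w, ids=None):
    w = np.asarray(w, dtype=float)
    ids = ids or tuple(str(i) for i in range(w.shape[0]))
    return Network(weights=w, node_ids=ids)


def random_network(seed, p=8):
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.5, 0.5, (p, p))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return net_from(w)


class TestStrengthAndInfluence:
    def test_hand_sums(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        w[0, 2] = w[2, 0] = -0.2
        net = net_from(w)
        assert strength(net)["0"] == pytest.approx(0.5)
        assert expected_influence(net, 1)["0"] == pytest.approx(0.1)

    def test_isolated_node_scores_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        net = net_from(w)
        assert strength(net)["2"] == 0.0
        assert expected_influence(net, 2)["2"] == 0.0

    def test_strength_invariant_to_global_sign_flip(self):
        net = random_network(1)
        flipped = net_from(-net.weights)
        assert strength(net) == strength(flipped)

    def test_ei1_equals_strength_on_positive_network(self):
        net = net_from(np.abs(random_network(2).weights))
        s, e = strength(net), expected_influence(net, 1)
        assert all(s[k] == pytest.approx(e[k]) for k in s)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_ei1_bounded_by_strength(self, seed):
        net = random_network(seed)
        s, e = strength(net), expected_influence(net, 1)
        assert all(abs(e[k]) <= s[k] + 1e-12 for k in s)

    def test_star_two_step_influence_hand_case(self):
        w = np.zeros((5, 5))
        for leaf in range(1, 5):
            w[0, leaf] = w[leaf, 0] = 0.5
        net = net_from(w)
        # center EI1 = 2.0; leaf EI2 = 0.5 + 0.5 * 2.0 = 1.5
        assert expected_influence(net, 2)["1"] == pytest.approx(1.5)


class TestNetworkLoadings:
    def test_single_edge_loads_on_its_community(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        net = net_from(w)
        part = Partition.from_dict({"0": 0, "1": 1, "2": 1})
        df = network_loadings(net, part)
        raw = df.attrs["raw"]
        assert raw[0, 1] == pytest.approx(0.4)  # node 0 into community of 1
        assert raw[0, 0] == pytest.approx(0.0)

    def test_isolated_node_has_zero_row(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.4
        part = Partition.from_dict({"0": 0, "1": 0, "2": 1, "3": 1})
        df = network_loadings(net_from(w), part)
        assert np.allclose(df.loc["3"], 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_raw_loadings_decompose_strength(self, seed):
        net = random_network(seed)
        rng = np.random.default_rng(seed + 1)
        part = Partition.from_dict(
            dict(zip(net.node_ids, rng.integers(0, 3, net.n_nodes)))
        )
        raw = network_loadings(net, part).attrs["raw"]
        s = strength(net)
        for i, node in enumerate(net.node_ids):
            assert raw[i].sum() == pytest.approx(s[node], abs=1e-12)

    def test_cross_loadings_small_on_separated_structure(self, easy_network, easy_data):
        _, planted = easy_data
        df = network_loadings(easy_network, planted)
        labels = planted.reordered(easy_network.node_ids)
        main = np.array([df.iloc[i, labels[i]] for i in range(len(labels))])
        cross = np.array(
            [max(abs(df.iloc[i, c]) for c in range(df.shape[1]) if c != labels[i])
             for i in range(len(labels))]
        )
        assert np.median(cross / main) < 0.25


class TestRankings:
    def test_strict_order_gives_unambiguous_top(self):
        w = np.zeros((6, 6))
        for i, v in enumerate((0.6, 0.5, 0.4, 0.3, 0.2), start=1):
            w[0, i] = w[i, 0] = v
        net = net_from(w)
        table = centrality_table(net)
        ranks = top_bottom_nodes(table, k=2)
        assert ranks["strength"]["top"][0] == "0"

    def test_ties_break_by_node_id(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        table = centrality_table(net_from(w))
        ranks = top_bottom_nodes(table, k=2)
        assert ranks["strength"]["top"] == ["0", "1"]

    def test_oversized_k_rejected(self):
        table = centrality_table(random_network(3))
        with pytest.raises(MetricsError, match="exceeds"):
            top_bottom_nodes(table, k=99)


KEY = ItemKey(
    subscales={"DT": ["1", "2"], "B": ["3", "4"], "MF": ["5", "6"]},
    composites={"EDR": ["DT", "B"], "MFC": ["MF"]},
)


class TestSubscaleAgreement:
    def test_perfect_partition_has_no_misfits(self):
        part = Partition.from_dict(
            {"1": 0, "2": 0, "3": 0, "4": 0, "5": 1, "6": 1}
        )
        table = subscale_agreement(part, KEY)
        assert (table["missing_items"] == "").all()
        assert (table["foreign_items"] == "").all()
        assert set(table["composite"]) == {"EDR", "MFC"}

    def test_foreign_and_missing_items_reported(self):
        part = Partition.from_dict(
            {"1": 0, "2": 0, "3": 0, "4": 0, "5": 1, "6": 0}
        )
        table = subscale_agreement(part, KEY)
        row = table[table["subscales"].str.contains("MF")].iloc[0]
        assert "6" in row["missing_items"]
        foreign_row = table[table["foreign_items"].str.contains("6")].iloc[0]
        assert "(MF)" in foreign_row["foreign_items"]

    def test_unscored_items_listed_separately(self):
        part = Partition.from_dict(
            {"1": 0, "2": 0, "3": 0, "4": 0, "5": 1, "6": 1, "71": 1}
        )
        table = subscale_agreement(part, KEY)
        row = table[table["unscored_items"] != ""].iloc[0]
        assert row["unscored_items"] == "71"

    def test_invariant_to_label_permutation(self):
        p1 = Partition.from_dict({"1": 0, "2": 0, "3": 1, "4": 1, "5": 2, "6": 2})
        p2 = Partition.from_dict({"1": 2, "2": 2, "3": 0, "4": 0, "5": 1, "6": 1})
        t1 = subscale_agreement(p1, KEY).sort_values("subscales").reset_index(drop=True)
        t2 = subscale_agreement(p2, KEY).sort_values("subscales").reset_index(drop=True)
        cols = ["subscales", "missing_items", "foreign_items", "composite"]
        assert t1[cols].equals(t2[cols])

    def test_merge_map_expansion_inline(self):
        part = Partition.from_dict({"1_2": 0, "3": 1, "4": 1, "5": 2, "6": 2})
        table = subscale_agreement(part, KEY, merge_map={"1_2": ["1", "2"]})
        assert "DT" in " ".join(table["subscales"])
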