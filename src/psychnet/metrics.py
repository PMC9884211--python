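"""Node importance and dimension-level loading metrics.

Strength is the summed absolute edge weight of a node; the one-step expected
influence keeps the signs (so it is bounded by strength, with equality on
all-positive networks), and the two-step variant adds the weight-propagated
influence of the neighbors.  Network loadings decompose a node's strength
over the communities of a partition — the network analogue of a factor
loading matrix — and the subscale-agreement table compares a community
solution with the questionnaire's theoretical subscale/composite structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .communities import Partition
from .data import ItemKey
from .glasso import Network

__all__ = [
    "strength",
    "expected_influence",
    "network_loadings",
    "centrality_table",
    "top_bottom_nodes",
    "subscale_agreement",
]


class MetricsError(ValueError):
    pass


def strength(network: Network) -> dict[str, float]:
    """``s_i = sum_j |w_ij|``."""
    s = np.abs(network.weights).sum(axis=1)
    return {node: float(v) for node, v in zip(network.node_ids, s)}


def expected_influence(network: Network, steps: int = 1) -> dict[str, float]:
    """Signed influence: ``EI1_i = sum_j w_ij``; ``EI2_i = EI1_i + sum_j w_ij EI1_j``."""
    if steps not in (1, 2):
        raise MetricsError("steps must be 1 or 2")
    w = network.weights
    ei1 = w.sum(axis=1)
    if steps == 1:
        out = ei1
    else:
        out = ei1 + w @ ei1
    return {node: float(v) for node, v in zip(network.node_ids, out)}


def network_loadings(
    network: Network, partition: Partition, signed: bool = False
) -> pd.DataFrame:
    """Node x community matrix of (standardized) within-community strengths.

    Raw loading ``NL_ic = sum_{j in c} |w_ij|`` (signed sums if
    ``signed=True``); each column c is standardized by the square root of the
    summed raw loadings of c's own members.  Off-community columns hold the
    cross-loadings.
    """
    nodes = network.node_ids
    labels = partition.reordered(nodes)
    n_comm = int(labels.max()) + 1
    for c in range(n_comm):
        if not np.any(labels == c):
            raise MetricsError(f"community {c} has no members")
    w = network.weights if signed else np.abs(network.weights)
    raw = np.zeros((len(nodes), n_comm))
    for c in range(n_comm):
        raw[:, c] = w[:, labels == c].sum(axis=1)
    std = raw.copy()
    for c in range(n_comm):
        denom = np.sqrt(np.abs(raw[labels == c, c]).sum())
        if denom > 0:
            std[:, c] = raw[:, c] / denom
    df = pd.DataFrame(std, index=list(nodes), columns=[f"C{c+1}" for c in range(n_comm)])
    df.attrs["standardization"] = "column / sqrt(sum of own-member raw loadings)"
    df.attrs["signed"] = signed
    df.attrs["raw"] = raw
    return df


def centrality_table(network: Network) -> pd.DataFrame:
    """Per-node strength, EI1 and EI2 plus dense rankings (1 = highest)."""
    s = strength(network)
    e1 = expected_influence(network, steps=1)
    e2 = expected_influence(network, steps=2)
    df = pd.DataFrame(
        {
            "strength": pd.Series(s),
            "ei1": pd.Series(e1),
            "ei2": pd.Series(e2),
        }
    )
    for col in ("strength", "ei1", "ei2"):
        df[f"{col}_rank"] = (
            df[col].rank(ascending=False, method="first").astype(int)
        )
    return df


def top_bottom_nodes(table: pd.DataFrame, k: int = 5) -> dict[str, dict[str, list[str]]]:
    """The k strongest and k weakest nodes per metric; ties break by node id."""
    if k > len(table):
        raise MetricsError(f"k={k} exceeds node count {len(table)}")
    out: dict[str, dict[str, list[str]]] = {}
    for col in ("strength", "ei1", "ei2"):
        ordered = table.assign(_node=table.index.astype(str)).sort_values(
            by=[col, "_node"], ascending=[False, True], kind="mergesort"
        )
        out[col] = {
            "top": list(ordered.index[:k].astype(str)),
            "bottom": list(ordered.index[-k:].astype(str)[::-1]),
        }
    return out


def subscale_agreement(
    partition: Partition,
    item_key: ItemKey,
    merge_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Compare a community solution with the theoretical subscale structure.

    The partition must already be expanded to original items (pass
    ``merge_map`` to expand here).  Each community is matched to the set of
    subscales for which it holds the majority of items, and to the composite
    score with maximal item overlap (Jaccard tie-break).  The table reports,
    per community: matched subscales, missing items of those subscales,
    foreign items annotated with their true subscale, the matched composite,
    and unscored items.
    """
    from .communities import expand_partition

    if merge_map:
        partition = expand_partition(partition, merge_map)
    items = set(partition.node_ids)
    unknown = [
        i
        for i in items
        if item_key.subscale_of(i) is None and i not in item_key.unscored_items(items)
    ]
    # unscored_items covers every keyless item, so `unknown` is empty unless
    # the key itself is inconsistent; keep the check for safety
    if unknown:
        raise MetricsError(f"items missing from key: {sorted(unknown)}")
    # each subscale is claimed by the community holding the plurality of its
    # items; ties break towards the community with higher Jaccard overlap
    claimed_by: dict[str, int] = {}
    community_members = [
        set(partition.members(label)) for label in range(partition.n_communities)
    ]
    for sub, sub_items in item_key.subscales.items():
        sub_set = {i for i in sub_items if i in items}
        if not sub_set:
            continue
        best, best_score = None, (0, -1.0)
        for label, members in enumerate(community_members):
            inter = len(sub_set & members)
            if inter == 0:
                continue
            score = (inter, inter / len(sub_set | members))
            if score > best_score:
                best, best_score = label, score
        if best is not None:
            claimed_by[sub] = best
    rows = []
    for label in range(partition.n_communities):
        members = community_members[label]
        scored = {i for i in members if item_key.subscale_of(i) is not None}
        unscored = sorted(members - scored, key=_item_sort_key)
        matched = [s for s, lab in claimed_by.items() if lab == label]
        matched_items = {i for s in matched for i in item_key.items_of_subscale(s)}
        missing = sorted(matched_items - members, key=_item_sort_key)
        foreign = sorted(
            (i for i in scored if item_key.subscale_of(i) not in matched),
            key=_item_sort_key,
        )
        composite = _best_composite(scored, item_key)
        rows.append(
            {
                "community": f"C{label + 1}",
                "subscales": " + ".join(sorted(matched)),
                "missing_items": ", ".join(missing),
                "foreign_items": ", ".join(
                    f"{i} ({item_key.subscale_of(i)})" for i in foreign
                ),
                "composite": composite or "",
                "unscored_items": ", ".join(unscored),
                "n_items": len(members),
            }
        )
    return pd.DataFrame(rows)


def _item_sort_key(item: str):
    return (0, int(item)) if str(item).isdigit() else (1, str(item))


def _best_composite(members: set[str], item_key: ItemKey) -> str | None:
    best, best_score = None, (-1.0, -1.0)
    for comp in item_key.composites:
        comp_items = set(item_key.items_of_composite(comp))
        inter = len(members & comp_items)
        union = len(members | comp_items)
        score = (float(inter), inter / union if union else 0.0)
        if score > best_score:
            best, best_score = comp, score
    if best_score[0] <= 0:
        return None
    return best
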