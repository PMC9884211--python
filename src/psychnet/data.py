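"""Data containers and file IO for questionnaire network analysis.

The two core containers are :class:`ResponseMatrix` (respondents x ordinal
items) and :class:`ItemKey` (item -> subscale -> composite bookkeeping for a
multidimensional questionnaire such as the EDI-3).  Networks are exchanged as
GraphML plus a weighted edge-list CSV so they can be inspected with standard
graph tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResponseMatrix",
    "ItemKey",
    "EDI3_SUBSCALES",
    "load_responses",
    "save_responses",
    "load_item_key",
    "export_network",
    "read_network",
    "save_partition",
    "load_partition",
]

#: The 12 primary subscale codes of the EDI-3 questionnaire.
EDI3_SUBSCALES = frozenset(
    {"DT", "B", "BD", "LSE", "PA", "II", "IA", "ID", "ED", "P", "A", "MF"}
)

#: Name of the optional per-respondent grouping column in response CSVs.
GROUP_COLUMN = "diagnosis"


class DataError(ValueError):
    """Invalid questionnaire data or key configuration."""


@dataclass
class ResponseMatrix:
    """Respondents x items table of questionnaire responses.

    Parameters
    ----------
    values
        DataFrame with one column per item (item ids as column names) and one
        row per respondent.  Ordinal items hold integers in
        ``[0, likert_max]``; items listed in ``continuous_items`` (e.g.
        composites produced by redundancy merging) may hold arbitrary floats.
    likert_max
        Largest admissible ordinal category (categories are ``0..likert_max``).
    group
        Optional per-respondent label (e.g. a diagnosis such as AN or BN).
    continuous_items
        Items exempt from the ordinal range check.
    latent
        Optional latent (pre-discretization) values, kept by the synthetic
        generator so near-duplicate items can be cloned at the latent level.
    """

    values: pd.DataFrame
    likert_max: int = 4
    group: pd.Series | None = None
    continuous_items: frozenset[str] = frozenset()
    latent: pd.DataFrame | None = None
    redundant_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.columns = [str(c) for c in self.values.columns]
        self.continuous_items = frozenset(str(c) for c in self.continuous_items)
        self.validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def item_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_respondents(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.values.shape[1])

    def is_ordinal(self, item: str) -> bool:
        return item not in self.continuous_items

    def validate(self) -> None:
        if self.values.shape[0] < 1:
            raise DataError("response matrix needs at least one respondent")
        ids = self.item_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate item id(s): {dupes}")
        if self.values.isna().any().any():
            col = self.values.columns[self.values.isna().any()][0]
            row = int(self.values.index[self.values[col].isna()][0])
            raise DataError(f"missing value at row {row}, item {col!r}")
        for item in ids:
            if item in self.continuous_items:
                continue
            col = self.values[item].to_numpy()
            if not np.all((col >= 0) & (col <= self.likert_max)):
                bad = col[(col < 0) | (col > self.likert_max)][0]
                raise DataError(
                    f"item {item!r} has value {bad} outside 0..{self.likert_max}"
                )
            if not np.all(col == np.round(col)):
                raise DataError(f"ordinal item {item!r} has non-integer values")
        if self.group is not None and len(self.group) != self.n_respondents:
            raise DataError("group labels do not match respondent count")

    def subset(self, labels: Sequence[str]) -> "ResponseMatrix":
        """Rows whose group label is in ``labels`` (cohort selection)."""
        if self.group is None:
            raise DataError("no group labels present")
        mask = self.group.isin(labels).to_numpy()
        if not mask.any():
            raise DataError(f"no respondents with group in {list(labels)}")
        return ResponseMatrix(
            values=self.values.loc[mask].reset_index(drop=True),
            likert_max=self.likert_max,
            group=self.group.loc[mask].reset_index(drop=True),
            continuous_items=self.continuous_items,
            latent=None
            if self.latent is None
            else self.latent.loc[mask].reset_index(drop=True),
            redundant_pairs=self.redundant_pairs,
        )

    def with_columns(
        self, values: pd.DataFrame, continuous_items: Iterable[str] = ()
    ) -> "ResponseMatrix":
        """Same respondents, new item columns (used by merging steps)."""
        return ResponseMatrix(
            values=values,
            likert_max=self.likert_max,
            group=self.group,
            continuous_items=frozenset(continuous_items),
            latent=None,
            redundant_pairs=self.redundant_pairs,
        )


@dataclass
class ItemKey:
    """Item -> subscale and subscale -> composite mapping of a questionnaire.

    ``subscales`` maps each subscale code to its ordered item ids;
    ``composites`` maps each composite score to the subscales it combines.
    Items absent from every subscale are unscored (the EDI-3 has one such
    item, number 71).
    """

    subscales: dict[str, list[str]]
    composites: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subscales = {
            str(s): [str(i) for i in items] for s, items in self.subscales.items()
        }
        self.composites = {
            str(c): [str(s) for s in subs] for c, subs in self.composites.items()
        }
        seen: dict[str, str] = {}
        for sub, items in self.subscales.items():
            for item in items:
                if item in seen:
                    raise DataError(
                        f"item {item!r} mapped to both {seen[item]!r} and {sub!r}"
                    )
                seen[item] = sub
        for comp, subs in self.composites.items():
            for s in subs:
                if s not in self.subscales:
                    raise DataError(
                        f"composite {comp!r} references unknown subscale {s!r}"
                    )
        if self.composites:
            uncovered = set(self.subscales) - {
                s for subs in self.composites.values() for s in subs
            }
            if uncovered:
                raise DataError(
                    f"subscale(s) {sorted(uncovered)} belong to no composite"
                )

    def subscale_of(self, item: str) -> str | None:
        for sub, items in self.subscales.items():
            if item in items:
                return sub
        return None

    def items_of_subscale(self, subscale: str) -> list[str]:
        return list(self.subscales[subscale])

    def items_of_composite(self, composite: str) -> list[str]:
        return [i for s in self.composites[composite] for i in self.subscales[s]]

    def unscored_items(self, item_ids: Iterable[str]) -> list[str]:
        return [i for i in item_ids if self.subscale_of(i) is None]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_responses(
    path: str | Path, likert_max: int = 4, group_column: str = GROUP_COLUMN
) -> ResponseMatrix:
    """Read a respondents x items CSV (header of item ids; optional group column)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if len(set(header)) != len(header):  # pandas would silently mangle these
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicate item id(s) in header: {dupes}")
    df = pd.read_csv(path, dtype={group_column: str}, na_values=[""])
    group = None
    if group_column in df.columns:
        group = df.pop(group_column).reset_index(drop=True)
        if group.isna().any():
            row = int(group.index[group.isna()][0])
            raise DataError(f"missing group label at row {row}")
    return ResponseMatrix(values=df, likert_max=likert_max, group=group)


def save_responses(data: ResponseMatrix, path: str | Path) -> None:
    df = data.values.copy()
    if data.group is not None:
        df.insert(0, GROUP_COLUMN, data.group.to_numpy())
    df.to_csv(path, index=False)


def load_item_key(path: str | Path) -> ItemKey:
    """Read an item key from YAML.

    Expected layout::

        scale: EDI-3          # optional; enforces the canonical 12 codes
        subscales:
          DT: [1, 7, 11]
          ...
        composites:
          EDR: [DT, B, BD]
          ...
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "subscales" not in cfg:
        raise DataError("item key must define a 'subscales' mapping")
    key = ItemKey(
        subscales=cfg["subscales"], composites=cfg.get("composites", {}) or {}
    )
    if str(cfg.get("scale", "")).upper().replace("-", "") == "EDI3":
        unknown = set(key.subscales) - EDI3_SUBSCALES
        if unknown:
            raise DataError(f"unknown EDI-3 subscale code(s): {sorted(unknown)}")
    return key


def _require_symmetric(weights: np.ndarray) -> None:
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise DataError("weight matrix must be square")
    if not np.allclose(weights, weights.T, atol=1e-12):
        raise DataError("weight matrix must be symmetric")


def export_network(network, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a network as ``<prefix>.graphml`` and ``<prefix>_edges.csv``.

    The edge list has columns ``node_i,node_j,weight`` and omits zero-weight
    pairs; every node is declared in the GraphML even if isolated.
    """
    weights = np.asarray(network.weights, dtype=float)
    _require_symmetric(weights)
    node_ids = [str(n) for n in network.node_ids]
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    rows = []
    p = len(node_ids)
    for i in range(p):
        for j in range(i + 1, p):
            w = weights[i, j]
            if w != 0.0:
                g.add_edge(node_ids[i], node_ids[j], weight=float(w))
                rows.append((node_ids[i], node_ids[j], w))
    prefix = Path(path_prefix)
    graphml = prefix.with_suffix(".graphml")
    edges = prefix.parent / f"{prefix.name}_edges.csv"
    nx.write_graphml(g, graphml)
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        edges, index=False, float_format="%.17g"
    )
    return graphml, edges


def read_network(graphml_path: str | Path):
    """Read a GraphML file written by :func:`export_network` back to a Network."""
    from .glasso import Network  # local import to avoid a cycle

    g = nx.read_graphml(graphml_path)
    node_ids = list(g.nodes())
    idx = {n: i for i, n in enumerate(node_ids)}
    weights = np.zeros((len(node_ids), len(node_ids)))
    for u, v, attrs in g.edges(data=True):
        weights[idx[u], idx[v]] = weights[idx[v], idx[u]] = float(attrs["weight"])
    return Network(weights=weights, node_ids=tuple(node_ids))


def save_partition(partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {str(n): int(l) for n, l in partition.as_dict().items()},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def load_partition(path: str | Path):
    from .communities import Partition

    with open(path) as fh:
        mapping: Mapping[str, int] = json.load(fh)
    return Partition.from_dict({str(k): int(v) for k, v in mapping.items()})
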