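"""Community detection on signed psychometric networks and partition agreement.

Dimensions of a questionnaire network are identified with the spinglass
algorithm, which minimizes a signed Potts Hamiltonian: within-community
positive weight is rewarded and within-community negative weight penalized,
each against a configuration null model computed on the corresponding signed
subgraph.  The annealing itself is delegated to igraph's
``community_spinglass(implementation="neg")`` — the standard implementation
for signed graphs — while the Hamiltonian is evaluated here so multi-restart
runs can keep the lowest-energy solution and small cases can be checked
against exhaustive enumeration.

Partition agreement uses normalized and adjusted mutual information with the
arithmetic normalization convention.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph
import numpy as np
from sklearn.metrics import adjusted_mutual_info_score, normalized_mutual_info_score

__all__ = [
    "Partition",
    "signed_hamiltonian",
    "spinglass_partition",
    "nmi",
    "ami",
    "expand_partition",
]


class CommunityError(RuntimeError):
    pass


@dataclass
class Partition:
    """Node -> community assignment with the energy of the solution."""

    node_ids: tuple[str, ...]
    labels: np.ndarray
    energy: float = float("nan")
    seed: int | None = None

    def __post_init__(self) -> None:
        self.node_ids = tuple(str(n) for n in self.node_ids)
        labels = np.asarray(self.labels, dtype=int)
        if len(labels) != len(self.node_ids):
            raise ValueError("labels must match node_ids")
        # relabel to dense integers from 0, preserving numeric label order so
        # that aligned partitions keep their correspondence to the reference
        _, dense = np.unique(labels, return_inverse=True)
        self.labels = dense.astype(int)

    @classmethod
    def from_dict(cls, assignment: dict[str, int], **kw) -> "Partition":
        nodes = tuple(assignment)
        return cls(node_ids=nodes, labels=np.array([assignment[n] for n in nodes]), **kw)

    def as_dict(self) -> dict[str, int]:
        return {n: int(l) for n, l in zip(self.node_ids, self.labels)}

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, label: int) -> frozenset[str]:
        return frozenset(n for n, l in zip(self.node_ids, self.labels) if l == label)

    def reordered(self, node_ids: tuple[str, ...]) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[str(n)] for n in node_ids], dtype=int)


def signed_hamiltonian(
    weights: np.ndarray,
    labels: np.ndarray,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
) -> float:
    """Potts energy of a labeling on a signed weighted network.

    ``H = - sum_{i<j in same community} (w+_ij - g+ p+_ij)
        + sum_{i<j in same community} (w-_ij - g- p-_ij)``
    with null expectations ``p+-_ij = k+-_i k+-_j / (2 m+-)`` from the
    positive/negative subgraph degrees.
    """
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)

    def half(mat: np.ndarray, gamma: float) -> float:
        k = mat.sum(axis=1)
        two_m = k.sum()
        if two_m <= 0:
            null = np.zeros_like(mat)
        else:
            null = np.outer(k, k) / two_m
        return float(np.sum((mat - gamma * null)[same]) / 2.0)

    return -half(wp, gamma_pos) + half(wn, gamma_neg)


def _components(weights: np.ndarray) -> list[list[int]]:
    p = weights.shape[0]
    adj = np.abs(weights) > 0
    seen = np.zeros(p, dtype=bool)
    comps = []
    for start in range(p):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
        comps.append(sorted(comp))
    return comps


def spinglass_partition(
    network,
    gamma_pos: float = 1.0,
    gamma_neg: float = 1.0,
    max_spins: int = 25,
    t_start: float = 1.0,
    t_stop: float = 0.01,
    cooling: float = 0.99,
    seed: int = 0,
    restarts: int = 1,
) -> Partition:
    """Signed spinglass communities, deterministic given ``seed``.

    Each connected component of the nonzero graph is annealed separately
    (the configuration null is undefined across components); isolated nodes
    become singleton communities.  With ``restarts > 1`` the lowest-energy
    labeling over restarts is returned.
    """
    w = np.asarray(network.weights, dtype=float)
    if not np.any(w):
        raise CommunityError("no structure: network has no nonzero edges")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: tuple[float, np.ndarray] | None = None
    for r in range(restarts):
        labels = _spinglass_once(
            w, gamma_pos, gamma_neg, max_spins, t_start, t_stop, cooling,
            seed=int(seed) + r,
        )
        energy = signed_hamiltonian(w, labels, gamma_pos, gamma_neg)
        if best is None or energy < best[0]:
            best = (energy, labels)
    assert best is not None
    return Partition(
        node_ids=tuple(network.node_ids), labels=best[1], energy=best[0], seed=int(seed)
    )


def _spinglass_once(w, gamma_pos, gamma_neg, max_spins, t_start, t_stop, cooling,
                    seed) -> np.ndarray:
    p = w.shape[0]
    labels = np.full(p, -1, dtype=int)
    next_label = 0
    random.seed(seed)  # python-igraph draws from Python's random module
    for comp in _components(w):
        if len(comp) == 1:
            labels[comp[0]] = next_label
            next_label += 1
            continue
        sub = w[np.ix_(comp, comp)]
        iu = np.triu_indices(len(comp), k=1)
        src, dst = iu[0][sub[iu] != 0], iu[1][sub[iu] != 0]
        g = igraph.Graph(n=len(comp), edges=list(zip(src.tolist(), dst.tolist())))
        ew = sub[src, dst].tolist()
        cl = g.community_spinglass(
            weights=ew,
            spins=min(max_spins, len(comp)),
            start_temp=t_start,
            stop_temp=t_stop,
            cool_fact=cooling,
            update_rule="config",
            gamma=gamma_pos,
            implementation="negative",
            lambda_=gamma_neg,
        )
        membership = np.asarray(cl.membership, dtype=int)
        for local, node in enumerate(comp):
            labels[node] = next_label + membership[local]
        next_label = int(labels.max()) + 1
    return labels


def _aligned_label_arrays(p1: Partition, p2: Partition) -> tuple[np.ndarray, np.ndarray]:
    if set(p1.node_ids) != set(p2.node_ids):
        raise CommunityError("partitions are over different node sets")
    return p1.labels, p2.reordered(p1.node_ids)


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information, arithmetic normalization, in [0, 1]."""
    a, b = _aligned_label_arrays(p1, p2)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ami(p1: Partition, p2: Partition) -> float:
    """Chance-adjusted mutual information (hypergeometric permutation model)."""
    a, b = _aligned_label_arrays(p1, p2)
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def expand_partition(p: Partition, merge_map: dict[str, list[str]]) -> Partition:
    """Push a partition over merged composites back onto the original items.

    Every source item inherits its composite's community label; items that
    were never merged keep their own label.
    """
    assignment: dict[str, int] = {}
    for node, label in p.as_dict().items():
        if node in merge_map:
            for src in merge_map[node]:
                assignment[str(src)] = label
        elif "_" in node and node not in merge_map:
            raise CommunityError(f"composite node {node!r} missing from merge map")
        else:
            assignment[node] = label
    return Partition.from_dict(assignment, energy=p.energy, seed=p.seed)
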