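"""Bootstrap exploratory graph analysis: stability of the dimensional solution.

The estimate-and-partition pipeline (correlate -> GLASSO/EBIC -> spinglass)
is replicated over row resamples of the data.  The ensemble yields

* the median network (elementwise median of the replicate partial
  correlations),
* item stability — how often each item lands in its empirical community
  after aligning replicate labels to the empirical partition,
* structural consistency — how often each empirical dimension recurs as an
  identical community, and
* the distribution of the number of detected communities.

A case-dropping subsample bootstrap for centrality indices (the
correlation-stability coefficient) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .communities import Partition, spinglass_partition
from .correlation import CorrelationError, corr_matrix
from .data import ResponseMatrix
from .glasso import GlassoError, Network, estimate_network
from .metrics import expected_influence, strength

__all__ = [
    "EgaSettings",
    "BootstrapEnsemble",
    "StabilityReport",
    "ega",
    "bootstrap_ega",
    "median_network",
    "align_labels",
    "item_stability",
    "structural_consistency",
    "ncomm_distribution",
    "stability_report",
    "case_drop_stability",
]


class BootstrapError(RuntimeError):
    pass


@dataclass
class EgaSettings:
    """Shared configuration of one estimate-and-partition pass."""

    correlation: str = "polychoric"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    spinglass_gamma_pos: float = 1.0
    spinglass_gamma_neg: float = 1.0
    max_spins: int = 25
    restarts: int = 10
    bootstrap_restarts: int = 1


@dataclass
class BootstrapEnsemble:
    replicates: list[tuple[Network, Partition, int]]
    empirical_network: Network
    empirical_partition: Partition
    seed: int
    n_redraws: int = 0

    @property
    def B(self) -> int:
        return len(self.replicates)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.empirical_network.node_ids


@dataclass
class StabilityReport:
    item_stability: dict[str, float]
    structural_consistency: dict[int, float]
    ncomm: dict[str, float]
    item_dimension_table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "item_stability": self.item_stability,
            "structural_consistency": {
                str(k): v for k, v in self.structural_consistency.items()
            },
            "ncomm": self.ncomm,
        }


def ega(
    data: ResponseMatrix, settings: EgaSettings | None = None, seed: int = 0,
    restarts: int | None = None,
) -> tuple[Network, Partition]:
    """One estimate-and-partition pass on the full data."""
    s = settings or EgaSettings()
    S = corr_matrix(data, method=s.correlation)
    network = estimate_network(
        S, gamma=s.gamma, n_lambda=s.n_lambda, lambda_min_ratio=s.lambda_min_ratio
    )
    partition = spinglass_partition(
        network,
        gamma_pos=s.spinglass_gamma_pos,
        gamma_neg=s.spinglass_gamma_neg,
        max_spins=s.max_spins,
        seed=seed,
        restarts=restarts if restarts is not None else s.restarts,
    )
    return network, partition


def bootstrap_ega(
    data: ResponseMatrix,
    B: int = 500,
    seed: int = 0,
    settings: EgaSettings | None = None,
    resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> BootstrapEnsemble:
    """Row-resampling bootstrap of the estimate-and-partition pipeline.

    Each replicate b uses the child seed ``seed + b``.  Degenerate resamples
    (an item collapsing to one category, or an unestimable network) are
    logged and redrawn; more than 10% redraws aborts.

    ``resampler`` is a test seam: given (rng, n) it returns row indices;
    the default draws n rows with replacement.
    """
    if data.n_respondents < 50:
        import warnings

        warnings.warn("fewer than 50 respondents; bootstrap may be unstable")
    s = settings or EgaSettings()
    emp_net, emp_part = ega(data, settings=s, seed=seed)
    draw = resampler or (lambda rng, n: rng.integers(0, n, size=n))
    replicates: list[tuple[Network, Partition, int]] = []
    n_redraws = 0
    max_redraws = max(1, int(0.1 * B))
    b = 1
    attempt_offset = 0
    while len(replicates) < B:
        child_seed = seed + b + attempt_offset
        rng = np.random.default_rng(child_seed)
        idx = draw(rng, data.n_respondents)
        boot = ResponseMatrix(
            values=data.values.iloc[idx].reset_index(drop=True),
            likert_max=data.likert_max,
            continuous_items=data.continuous_items,
        )
        try:
            net, part = ega(
                boot, settings=s, seed=child_seed, restarts=s.bootstrap_restarts
            )
        except (CorrelationError, GlassoError) as exc:
            n_redraws += 1
            if n_redraws > max_redraws:
                raise BootstrapError(
                    f"unstable resampling: {n_redraws} degenerate replicates ({exc})"
                ) from exc
            attempt_offset += B  # fresh seed stream for the redraw
            continue
        replicates.append((net, part, part.n_communities))
        b += 1
    return BootstrapEnsemble(
        replicates=replicates,
        empirical_network=emp_net,
        empirical_partition=emp_part,
        seed=seed,
        n_redraws=n_redraws,
    )


def median_network(ensemble: BootstrapEnsemble) -> Network:
    """Elementwise median of the replicate partial-correlation matrices."""
    if ensemble.B < 1:
        raise BootstrapError("need at least one replicate")
    stack = np.stack([net.weights for net, _, _ in ensemble.replicates])
    med = np.median(stack, axis=0)
    med = (med + med.T) / 2.0
    np.fill_diagonal(med, 0.0)
    return Network(
        weights=med,
        node_ids=ensemble.node_ids,
        n=ensemble.empirical_network.n,
        correlation_method=ensemble.empirical_network.correlation_method,
        metadata={"kind": "median", "B": ensemble.B},
    )


def align_labels(replicate: Partition, reference: Partition) -> Partition:
    """Map replicate labels onto reference labels by maximum total overlap.

    Solves the assignment problem on the label contingency table; replicate
    communities beyond the reference's count keep fresh labels.  Only labels
    change — co-membership is untouched.
    """
    if set(replicate.node_ids) != set(reference.node_ids):
        raise BootstrapError("partitions are over different node sets")
    rep = replicate.labels
    ref = reference.reordered(replicate.node_ids)
    n_rep = rep.max() + 1
    n_ref = ref.max() + 1
    contingency = np.zeros((n_rep, n_ref))
    np.add.at(contingency, (rep, ref), 1.0)
    rows, cols = optimize.linear_sum_assignment(-contingency)
    mapping = dict(zip(rows.tolist(), cols.tolist()))
    fresh = int(n_ref)
    out = np.empty_like(rep)
    for lab in range(n_rep):
        if lab not in mapping:
            mapping[lab] = fresh
            fresh += 1
    for i, lab in enumerate(rep):
        out[i] = mapping[lab]
    aligned = Partition(
        node_ids=replicate.node_ids, labels=out, energy=replicate.energy,
        seed=replicate.seed,
    )
    # keep the reference's numbering verbatim: re-densification would shift
    # labels whenever a reference community has no counterpart here
    aligned.labels = out
    return aligned


def _aligned_label_matrix(ensemble: BootstrapEnsemble) -> np.ndarray:
    """B x p matrix of replicate labels aligned to the empirical partition."""
    nodes = ensemble.node_ids
    ref = ensemble.empirical_partition
    rows = []
    for _, part, _ in ensemble.replicates:
        aligned = align_labels(part, ref)
        rows.append(aligned.reordered(nodes))
    return np.asarray(rows)


def item_stability(
    ensemble: BootstrapEnsemble,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Proportion of replicates placing each item in its empirical community.

    Also returns the full item x dimension replication-frequency table
    (columns are empirical dimension labels plus ``other`` for fresh
    replicate communities).
    """
    nodes = ensemble.node_ids
    emp = ensemble.empirical_partition.reordered(nodes)
    aligned = _aligned_label_matrix(ensemble)
    n_dims = int(emp.max()) + 1
    freq = np.zeros((len(nodes), n_dims + 1))
    for b in range(aligned.shape[0]):
        for i, lab in enumerate(aligned[b]):
            freq[i, min(lab, n_dims)] += 1
    freq /= ensemble.B
    table = pd.DataFrame(
        freq, index=list(nodes), columns=[*map(str, range(n_dims)), "other"]
    )
    stab = {node: float(freq[i, emp[i]]) for i, node in enumerate(nodes)}
    return stab, table


def structural_consistency(
    ensemble: BootstrapEnsemble, min_member_fraction: float = 1.0
) -> dict[int, float]:
    """Proportion of replicates reproducing each empirical dimension.

    With the default ``min_member_fraction=1`` a dimension counts as
    reproduced only when its exact item set appears as one replicate
    community (no missing members, no extras); lower values relax the
    membership requirement while still forbidding extras.
    """
    emp = ensemble.empirical_partition
    nodes = ensemble.node_ids
    out: dict[int, float] = {}
    replicate_sets = []
    for _, part, _ in ensemble.replicates:
        d = part.as_dict()
        sets: dict[int, set[str]] = {}
        for node in nodes:
            sets.setdefault(d[node], set()).add(node)
        replicate_sets.append(list(sets.values()))
    for label in range(emp.n_communities):
        members = set(emp.members(label))
        hits = 0
        for sets in replicate_sets:
            for s in sets:
                if s <= members and len(s) >= min_member_fraction * len(members):
                    hits += 1
                    break
        out[label] = hits / ensemble.B
    return out


def ncomm_distribution(ensemble: BootstrapEnsemble) -> dict[str, float]:
    """Mode/median/mean/sd and normal-approximation 95% CI of community counts."""
    if ensemble.B < 2:
        raise BootstrapError("need at least two replicates")
    counts = np.array([k for _, _, k in ensemble.replicates], dtype=float)
    mode = int(stats.mode(counts, keepdims=False).mode)
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1))
    return {
        "mode": mode,
        "median": float(np.median(counts)),
        "mean": mean,
        "sd": sd,
        "ci95_low": mean - 1.96 * sd,
        "ci95_high": mean + 1.96 * sd,
    }


def stability_report(ensemble: BootstrapEnsemble) -> StabilityReport:
    stab, table = item_stability(ensemble)
    return StabilityReport(
        item_stability=stab,
        structural_consistency=structural_consistency(ensemble),
        ncomm=ncomm_distribution(ensemble),
        item_dimension_table=table,
    )


# ---------------------------------------------------------------------------
# Case-dropping centrality stability
# ---------------------------------------------------------------------------

_METRICS = {
    "strength": lambda net: strength(net),
    "ei1": lambda net: expected_influence(net, steps=1),
    "ei2": lambda net: expected_influence(net, steps=2),
}


def case_drop_stability(
    data: ResponseMatrix,
    metric: str = "strength",
    drop_fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
    B: int = 50,
    seed: int = 0,
    settings: EgaSettings | None = None,
    corr_threshold: float = 0.7,
    coverage: float = 0.95,
) -> tuple[float, pd.DataFrame]:
    """Correlation-stability (CS) coefficient of a centrality index.

    For each drop fraction, B subsamples (without replacement) are re-
    estimated and the subsample metric is Spearman-correlated with the
    full-sample metric.  The CS coefficient is the largest drop fraction up
    to which at least ``coverage`` of the correlations stay >=
    ``corr_threshold``.
    """
    if any(f >= 1 or f < 0 for f in drop_fractions):
        raise ValueError("drop fractions must lie in [0, 1)")
    s = settings or EgaSettings()
    metric_fn = _METRICS[metric]
    S = corr_matrix(data, method=s.correlation)
    full_net = estimate_network(
        S, gamma=s.gamma, n_lambda=s.n_lambda, lambda_min_ratio=s.lambda_min_ratio
    )
    full_vals = np.array([metric_fn(full_net)[n] for n in full_net.node_ids])
    rows = []
    cs = 0.0
    passing = True
    for frac in sorted(drop_fractions):
        if frac == 0:
            rows.append({"drop_fraction": 0.0, "prop_above": 1.0, "mean_corr": 1.0})
            cs = max(cs, 0.0)
            continue
        keep = int(round((1 - frac) * data.n_respondents))
        corrs = []
        for b in range(B):
            rng = np.random.default_rng(seed + 1000 * b + int(frac * 100))
            idx = rng.choice(data.n_respondents, size=keep, replace=False)
            sub = ResponseMatrix(
                values=data.values.iloc[idx].reset_index(drop=True),
                likert_max=data.likert_max,
                continuous_items=data.continuous_items,
            )
            try:
                sub_net = estimate_network(
                    corr_matrix(sub, method=s.correlation),
                    gamma=s.gamma, n_lambda=s.n_lambda,
                    lambda_min_ratio=s.lambda_min_ratio,
                )
            except (CorrelationError, GlassoError):
                corrs.append(0.0)
                continue
            sub_vals = np.array([metric_fn(sub_net)[n] for n in full_net.node_ids])
            rho = stats.spearmanr(full_vals, sub_vals).statistic
            corrs.append(0.0 if np.isnan(rho) else float(rho))
        prop = float(np.mean(np.asarray(corrs) >= corr_threshold))
        rows.append(
            {"drop_fraction": frac, "prop_above": prop,
             "mean_corr": float(np.mean(corrs))}
        )
        if passing and prop >= coverage:
            cs = frac
        else:
            passing = False
    return cs, pd.DataFrame(rows)
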