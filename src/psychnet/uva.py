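"""Unique Variable Analysis: detect and merge locally dependent items.

Redundancy between items is measured by the weighted topological overlap
(wTO) of the estimated partial-correlation network: two items overlap when
they are directly connected and share neighbors with similar weights.  A
null distribution (gamma by default) is fitted to the nonzero overlaps, each
pair gets an upper-tail p-value, and the significance cutoff shrinks with the
number of tests (adaptive alpha).  Significant pairs form redundancy chains;
within each chain a hub target is picked and merged with its direct
neighbors and clique partners into a single composite variable (one-factor
confirmatory model score by default, mean score as fallback/option).  The
whole cycle repeats until no pair is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .correlation import corr_matrix
from .data import ResponseMatrix
from .glasso import Network, estimate_network

__all__ = [
    "RedundancyReport",
    "wto",
    "redundancy_pvalues",
    "adaptive_alpha",
    "build_merge_sets",
    "merge_items",
    "one_factor_fit",
    "run_uva",
    "UvaConfig",
]

MIN_NONZERO_PAIRS = 10


class UvaError(RuntimeError):
    pass


@dataclass
class UvaConfig:
    """Knobs of the redundancy loop (defaults follow common UVA practice)."""

    correlation: str = "polychoric"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    null_family: str = "gamma"  # or "lognormal", "empirical"
    base_alpha: float = 0.05
    n_ref: int = 10
    merge_method: str = "latent"  # or "sum"
    max_rounds: int = 10


@dataclass
class RedundancyReport:
    """Everything the redundancy loop found, aggregated over rounds."""

    wto: np.ndarray | None = None
    item_ids: tuple[str, ...] = ()
    pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha_corrected: float = float("nan")
    chains: list[list[str]] = field(default_factory=list)
    merge_map: dict[str, list[str]] = field(default_factory=dict)
    rounds: int = 0
    round_details: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "pvalues": {f"{a}|{b}": p for (a, b), p in self.pvalues.items()},
            "alpha_corrected": self.alpha_corrected,
            "chains": self.chains,
            "merge_map": self.merge_map,
            "rounds": self.rounds,
            "round_details": self.round_details,
        }

    def merged_items_table(self) -> pd.DataFrame:
        rows = [
            {"composite": comp, "sources": ", ".join(srcs), "n_sources": len(srcs)}
            for comp, srcs in sorted(self.merge_map.items())
        ]
        return pd.DataFrame(rows, columns=["composite", "sources", "n_sources"])


# ---------------------------------------------------------------------------
# Overlap and significance
# ---------------------------------------------------------------------------


def wto(network: Network | np.ndarray) -> np.ndarray:
    """Weighted topological overlap of a signed network.

    ``omega_ij = (sum_u |w_iu||w_ju| + |w_ij|) / (min(k_i, k_j) + 1 - |w_ij|)``
    with ``k_i = sum_u |w_iu|``; symmetric with zero diagonal by convention.
    """
    w = network.weights if isinstance(network, Network) else np.asarray(network, float)
    if not np.allclose(w, w.T, atol=1e-10):
        raise UvaError("weight matrix must be symmetric")
    a = np.abs(w)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # with zero diagonal, excludes u = i and u = j automatically
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(den > 0, num / den, 0.0)
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 0.0)
    return omega


def redundancy_pvalues(
    omega: np.ndarray, null_family: str = "gamma"
) -> dict[tuple[int, int], float]:
    """Upper-tail p-value of every nonzero overlap pair under a fitted null."""
    omega = np.asarray(omega, dtype=float)
    iu = np.triu_indices(omega.shape[0], k=1)
    vals = omega[iu]
    nz = vals > 0
    if int(nz.sum()) < MIN_NONZERO_PAIRS:
        raise UvaError(
            f"need >= {MIN_NONZERO_PAIRS} nonzero overlap pairs, got {int(nz.sum())}"
        )
    x = vals[nz]
    degenerate = np.ptp(x) == 0  # a parametric null cannot be fitted then
    if null_family == "gamma":
        if degenerate:
            raise UvaError("degenerate overlap distribution (zero variance)")
        mean, var = float(np.mean(x)), float(np.var(x))
        shape = mean**2 / var
        scale = var / mean
        p = stats.gamma.sf(x, a=shape, scale=scale)
    elif null_family == "lognormal":
        if degenerate:
            raise UvaError("degenerate overlap distribution (zero variance)")
        mu, sd = float(np.mean(np.log(x))), float(np.std(np.log(x)))
        p = stats.lognorm.sf(x, s=sd, scale=np.exp(mu))
    elif null_family == "empirical":
        p = np.array([np.mean(x >= v) for v in x])
    else:
        raise ValueError(f"unknown null family {null_family!r}")
    return {
        (int(i), int(j)): float(pv)
        for i, j, pv in zip(iu[0][nz], iu[1][nz], p)
    }


def adaptive_alpha(n_tests: int, base_alpha: float = 0.05, n_ref: int = 10) -> float:
    """Significance level that shrinks with the number of overlap tests.

    ``alpha * sqrt(n_ref (log n_ref + q)) / sqrt(n_tests (log n_tests + q))``
    with q the upper ``base_alpha`` quantile of chi-square(1); equals
    ``base_alpha`` at ``n_tests == n_ref`` and decreases thereafter.
    """
    if n_tests < 1:
        raise UvaError("n_tests must be >= 1")
    q = float(stats.chi2.ppf(1.0 - base_alpha, df=1))
    ref = np.sqrt(n_ref * (np.log(n_ref) + q))
    cur = np.sqrt(n_tests * (np.log(n_tests) + q))
    return float(base_alpha * ref / cur)


# ---------------------------------------------------------------------------
# Chains and merging
# ---------------------------------------------------------------------------


def build_merge_sets(
    significant_pairs: list[tuple[str, str]], omega_of: dict[tuple[str, str], float]
) -> tuple[list[list[str]], list[list[str]]]:
    """Redundancy chains and the per-chain merge sets.

    A chain is a connected component of the significant-pair graph.  Its
    target is the member with the largest summed overlap to the rest of the
    chain; the merge set is the target plus its direct neighbors plus any
    clique of the chain containing the target.  Remaining chain members are
    left for the next round.
    """
    g = nx.Graph()
    g.add_edges_from((str(a), str(b)) for a, b in significant_pairs)
    chains: list[list[str]] = []
    merge_sets: list[list[str]] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        chain = sorted(comp)
        chains.append(chain)

        def summed_omega(node: str) -> float:
            return sum(
                omega_of.get((node, other), omega_of.get((other, node), 0.0))
                for other in comp
                if other != node
            )

        target = max(chain, key=lambda v: (summed_omega(v), v))
        members = {target} | set(sub.neighbors(target))
        for clique in nx.find_cliques(sub):
            if target in clique:
                members |= set(clique)
        merge_sets.append(sorted(members))
    return chains, merge_sets


def one_factor_fit(S: np.ndarray, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """ML one-factor model of a correlation matrix -> (loadings, uniquenesses).

    Two-indicator sets use the equal-loading identification constraint.
    Raises on a Heywood case (uniqueness driven to the boundary).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if p < 2:
        raise UvaError("one-factor model needs >= 2 items")
    if p == 2:
        r = S[0, 1]
        if r <= 0:
            raise UvaError("two-item set with non-positive correlation")
        lam = np.sqrt(r)
        return np.array([lam, lam]), np.array([1 - r, 1 - r])

    def unpack(x):
        return x[:p], x[p:]

    def discrepancy(x):
        lam, psi = unpack(x)
        sigma = np.outer(lam, lam) + np.diag(psi)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        return logdet + float(np.trace(np.linalg.solve(sigma, S)))

    start_lam = np.full(p, np.sqrt(max(np.mean(S[np.triu_indices(p, 1)]), 0.1)))
    x0 = np.concatenate([start_lam, 1 - start_lam**2])
    res = optimize.minimize(
        discrepancy, x0, method="L-BFGS-B",
        bounds=[(-0.999, 0.999)] * p + [(1e-6, 1.0)] * p,
        options={"maxiter": max_iter},
    )
    lam, psi = unpack(res.x)
    if lam.sum() < 0:  # sign indeterminacy: orient positively
        lam = -lam
    if np.any(psi < 5e-3):
        raise UvaError("Heywood case: uniqueness at boundary")
    return lam, psi


def _composite_name(sources: list[str]) -> str:
    def sort_key(s: str):
        return (0, int(s)) if s.isdigit() else (1, s)

    flat: list[str] = []
    for s in sources:
        flat.extend(s.split("_"))
    return "_".join(sorted(set(flat), key=sort_key))


def merge_items(
    data: ResponseMatrix, merge_sets: list[list[str]], method: str = "latent"
) -> tuple[ResponseMatrix, dict[str, list[str]]]:
    """Collapse each merge set into one composite column.

    ``latent``: one-factor ML fit on the set's correlation matrix, composite
    = regression-method factor score (standardized); falls back to the mean
    score on a Heywood case or non-positive two-item correlation.  ``sum``:
    mean of the source responses.  Composites are named by the underscore-
    joined sorted source ids (e.g. ``"72_81"``).
    """
    flat = [i for s in merge_sets for i in s]
    if len(flat) != len(set(flat)):
        raise UvaError("merge sets must be disjoint")
    for item in flat:
        if item not in data.item_ids:
            raise UvaError(f"unknown item {item!r}")
    values = data.values.copy()
    continuous = set(data.continuous_items)
    merge_map: dict[str, list[str]] = {}
    for sources in merge_sets:
        name = _composite_name(sources)
        x = values[sources].to_numpy(dtype=float)
        score = None
        if method == "latent" and np.all(x.std(axis=0) > 0):
            z = (x - x.mean(axis=0)) / x.std(axis=0)
            S = np.corrcoef(z, rowvar=False)
            try:
                lam, psi = one_factor_fit(S)
                sigma = np.outer(lam, lam) + np.diag(psi)
                weights = np.linalg.solve(sigma, lam)  # regression factor scores
                score = z @ weights
                score = score / score.std()
            except UvaError:
                score = None  # Heywood or degenerate: fall back to the mean
        if score is None:
            if method not in ("latent", "sum"):
                raise ValueError(f"unknown merge method {method!r}")
            score = x.mean(axis=1)
        values = values.drop(columns=sources)
        values[name] = score
        continuous -= set(sources)
        continuous.add(name)
        merge_map[name] = sorted(
            {s for src in sources for s in src.split("_")},
            key=lambda s: (0, int(s)) if s.isdigit() else (1, s),
        )
    return data.with_columns(values, continuous_items=continuous), merge_map


# ---------------------------------------------------------------------------
# Full loop
# ---------------------------------------------------------------------------


def run_uva(
    data: ResponseMatrix, config: UvaConfig | None = None
) -> tuple[ResponseMatrix, RedundancyReport]:
    """Iterate correlate -> network -> wTO -> test -> merge to convergence."""
    cfg = config or UvaConfig()
    report = RedundancyReport()
    current = data
    for round_no in range(1, cfg.max_rounds + 1):
        S = corr_matrix(current, method=cfg.correlation)
        network = estimate_network(
            S, gamma=cfg.gamma, n_lambda=cfg.n_lambda,
            lambda_min_ratio=cfg.lambda_min_ratio,
        )
        omega = wto(network)
        ids = network.node_ids
        if report.wto is None:
            report.wto = omega
            report.item_ids = ids
        iu = np.triu_indices(omega.shape[0], k=1)
        n_nonzero = int(np.sum(omega[iu] > 0))
        if n_nonzero < MIN_NONZERO_PAIRS:
            break
        pvals = redundancy_pvalues(omega, null_family=cfg.null_family)
        alpha = adaptive_alpha(len(pvals), cfg.base_alpha, cfg.n_ref)
        named_pvals = {(ids[i], ids[j]): p for (i, j), p in pvals.items()}
        if round_no == 1:
            report.pvalues = named_pvals
            report.alpha_corrected = alpha
        significant = [pair for pair, p in named_pvals.items() if p < alpha]
        if not significant:
            break
        omega_of = {(ids[i], ids[j]): float(omega[i, j]) for (i, j) in pvals}
        chains, merge_sets = build_merge_sets(significant, omega_of)
        report.chains.extend(chains)
        current, round_map = merge_items(current, merge_sets, method=cfg.merge_method)
        # flatten: a composite of composites keeps original sources only
        for comp, sources in round_map.items():
            for prior in list(report.merge_map):
                if set(prior.split("_")) <= set(comp.split("_")):
                    del report.merge_map[prior]
            report.merge_map[comp] = sources
        report.round_details.append(
            {
                "round": round_no,
                "lambda": network.lambda_,
                "alpha_corrected": alpha,
                "n_tests": len(pvals),
                "n_significant": len(significant),
                "merged": {c: s for c, s in round_map.items()},
            }
        )
        report.rounds = round_no
    return current, report
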