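"""Synthetic ordinal questionnaire data with planted structure.

Responses are generated from a standard multi-factor model: latent item
scores follow a multivariate normal with covariance ``L @ Phi @ L.T + Theta``
(unit total variance per item), and each latent value is discretized through
ordered thresholds into Likert categories 0..likert_max.  The generator plants

* a community structure (the item -> factor map), used as ground truth for
  dimension-recovery tests;
* optional near-duplicate items (a clone equals its source's latent value
  plus Gaussian noise, re-discretized), ground truth for redundancy tests;
* optional cohort perturbations (an item re-assigned to a different factor in
  one subgroup), emulating diagnosis-specific item migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .communities import Partition
from .data import ResponseMatrix

__all__ = [
    "SyntheticSpec",
    "generate_factor_data",
    "inject_redundancy",
    "with_item_moved",
    "generate_cohorts",
]

DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted multi-factor ordinal generator.

    ``loading`` is the standardized main loading of each item on its factor;
    ``cross_loading`` (default 0) the loading on every other factor;
    ``factor_corr`` the common inter-factor correlation; ``thresholds`` the
    ordered cut-points on the latent N(0,1) scale; ``redundancy_pairs`` lists
    ``(source item id, noise sd)`` clones to append.
    """

    n_respondents: int = 1000
    n_factors: int = 4
    items_per_factor: int = 5
    loading: float = 0.7
    cross_loading: float = 0.0
    factor_corr: float = 0.2
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    redundancy_pairs: tuple[tuple[str, float], ...] = ()
    moved_items: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not (0 <= self.loading < 1):
            raise ValueError("loading must be in [0, 1)")
        if not (-1 < self.factor_corr < 1):
            raise ValueError("factor_corr must be in (-1, 1)")

    @property
    def item_ids(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_factors * self.items_per_factor)]


def _implied_model(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Loading matrix L, factor correlation Phi and implied item covariance."""
    p = spec.n_factors * spec.items_per_factor
    lam = np.full((p, spec.n_factors), spec.cross_loading)
    factor_of = np.repeat(np.arange(spec.n_factors), spec.items_per_factor)
    for item, fac in spec.moved_items.items():
        idx = spec.item_ids.index(str(item))
        factor_of[idx] = fac
    lam[np.arange(p), factor_of] = spec.loading
    phi = np.full((spec.n_factors, spec.n_factors), spec.factor_corr)
    np.fill_diagonal(phi, 1.0)
    common = lam @ phi @ lam.T
    uniq = 1.0 - np.diag(common)
    if np.any(uniq <= 0):
        bad = int(np.argmin(uniq))
        raise ValueError(
            f"item {spec.item_ids[bad]} has non-positive uniqueness "
            f"{uniq[bad]:.4f}; reduce loadings"
        )
    sigma = common + np.diag(uniq)
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin <= 0:
        raise ValueError(f"implied covariance not positive definite (min eig {eigmin:.3e})")
    return lam, phi, sigma


def _discretize(latent: np.ndarray, thresholds: tuple[float, ...]) -> np.ndarray:
    return np.searchsorted(np.asarray(thresholds), latent, side="right").astype(np.int64)


def generate_factor_data(spec: SyntheticSpec) -> tuple[ResponseMatrix, Partition]:
    """Draw ordinal responses plus the planted item -> factor partition.

    Fully reproducible from ``spec.seed``; clones listed in
    ``spec.redundancy_pairs`` are appended (they inherit their source's factor
    in the planted partition).
    """
    _, _, sigma = _implied_model(spec)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(sigma)
    latent = rng.standard_normal((spec.n_respondents, sigma.shape[0])) @ chol.T
    values = pd.DataFrame(_discretize(latent, spec.thresholds), columns=spec.item_ids)
    data = ResponseMatrix(
        values=values,
        likert_max=len(spec.thresholds),
        latent=pd.DataFrame(latent, columns=spec.item_ids),
    )
    factor_of = np.repeat(np.arange(spec.n_factors), spec.items_per_factor)
    labels = {i: int(f) for i, f in zip(spec.item_ids, factor_of)}
    for item, fac in spec.moved_items.items():
        labels[str(item)] = int(fac)
    if spec.redundancy_pairs:
        data = inject_redundancy(
            data, spec.redundancy_pairs, seed=rng.integers(2**31)
        )
        for src, _ in spec.redundancy_pairs:
            labels[f"{src}r"] = labels[str(src)]
    return data, Partition.from_dict(labels)


def inject_redundancy(
    data: ResponseMatrix,
    pairs: list[tuple[str, float]] | tuple[tuple[str, float], ...],
    seed: int = 0,
) -> ResponseMatrix:
    """Append a near-duplicate of each named item.

    The clone (id ``<source>r``) equals the source's latent value plus
    N(0, sd^2) noise, rescaled to unit variance and re-discretized through the
    generator's thresholds; the planted pairs are recorded on the result.
    """
    if not pairs:
        return data
    if data.latent is None:
        raise ValueError("data has no latent values; generate with generate_factor_data")
    rng = np.random.default_rng(seed)
    values = data.values.copy()
    latent = data.latent.copy()
    thresholds = DEFAULT_THRESHOLDS if data.likert_max == 4 else tuple(
        np.linspace(-1.5, 1.5, data.likert_max)
    )
    planted = list(data.redundant_pairs)
    for src, sd in pairs:
        src = str(src)
        if src not in values.columns:
            raise ValueError(f"unknown item {src!r}")
        clone_latent = latent[src].to_numpy() + rng.normal(0.0, sd, len(values))
        clone_latent = clone_latent / np.sqrt(1.0 + sd**2)
        clone_id = f"{src}r"
        values[clone_id] = _discretize(clone_latent, thresholds)
        latent[clone_id] = clone_latent
        planted.append((src, clone_id))
    return ResponseMatrix(
        values=values,
        likert_max=data.likert_max,
        group=data.group,
        latent=latent,
        redundant_pairs=tuple(planted),
    )


def with_item_moved(spec: SyntheticSpec, item: str, new_factor: int) -> SyntheticSpec:
    """Cohort perturbation: re-assign one item's main loading to another factor."""
    if str(item) not in spec.item_ids:
        raise ValueError(f"unknown item {item!r}")
    if not (0 <= new_factor < spec.n_factors):
        raise ValueError("new_factor out of range")
    moved = dict(spec.moved_items)
    moved[str(item)] = int(new_factor)
    return replace(spec, moved_items=moved)


def generate_cohorts(
    specs: dict[str, SyntheticSpec],
) -> tuple[ResponseMatrix, dict[str, Partition]]:
    """Stack cohort-specific draws into one matrix with group labels.

    Each cohort is generated from its own spec (same item set required);
    returns the combined data plus each cohort's planted partition.
    """
    frames, groups, partitions = [], [], {}
    item_sets = {tuple(s.item_ids) for s in specs.values()}
    if len(item_sets) != 1:
        raise ValueError("cohort specs must share the same item set")
    for label, spec in specs.items():
        data, part = generate_factor_data(spec)
        frames.append(data.values)
        groups.extend([label] * data.n_respondents)
        partitions[label] = part
    combined = ResponseMatrix(
        values=pd.concat(frames, ignore_index=True),
        likert_max=len(next(iter(specs.values())).thresholds),
        group=pd.Series(groups),
    )
    return combined, partitions
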