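"""End-to-end cohort validation and cross-cohort comparison.

``run_validation`` executes, per cohort (the full sample plus each selected
group label): redundancy reduction (UVA) -> bootstrap EGA -> median network
-> spinglass partition of the median network -> stability metrics ->
loadings/centralities -> subscale agreement, writing every report as plain
CSV/JSON.  ``run_comparison`` expands each cohort's partition back onto the
original item set via its merge map and tabulates pairwise NMI/AMI plus
per-item label migration.

All randomness derives from the config seed; artifact files contain no
timestamps, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bootstrap as bs
from .communities import Partition, ami, expand_partition, nmi, spinglass_partition
from .data import (
    ItemKey,
    ResponseMatrix,
    export_network,
    load_item_key,
    load_responses,
    save_partition,
    save_responses,
)
from .metrics import centrality_table, network_loadings, subscale_agreement
from .uva import UvaConfig, run_uva

__all__ = ["PipelineConfig", "CohortBundle", "run_validation", "run_comparison"]

log = logging.getLogger("psychnet")


@dataclass
class PipelineConfig:
    """Configuration of a full validation run."""

    responses: str
    item_key: str | None = None
    likert_max: int = 4
    cohort_labels: list[str] = field(default_factory=list)
    correlation: str = "polychoric"
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    uva: UvaConfig = field(default_factory=UvaConfig)
    spinglass_restarts: int = 10
    bootstrap_B: int = 500
    seed: int = 0
    output_dir: str = "psychnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        uva_section = cfg.pop("uva", {}) or {}
        # the UVA loop inherits the pipeline correlation unless overridden
        if "correlation" not in uva_section and "correlation" in cfg:
            uva_section["correlation"] = cfg["correlation"]
        return cls(uva=UvaConfig(**uva_section), **cfg)

    def ega_settings(self) -> bs.EgaSettings:
        return bs.EgaSettings(
            correlation=self.correlation,
            gamma=self.ebic_gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            restarts=self.spinglass_restarts,
        )


@dataclass
class CohortBundle:
    """In-memory results for one cohort (also written to disk)."""

    name: str
    reduced_data: ResponseMatrix
    report: "object"
    ensemble: bs.BootstrapEnsemble
    median_net: "object"
    median_partition: Partition
    stability: bs.StabilityReport
    original_items: tuple[str, ...]

    @property
    def merge_map(self) -> dict[str, list[str]]:
        return self.report.merge_map

    def expanded_partition(self) -> Partition:
        return expand_partition(self.median_partition, self.merge_map)


def _validate_cohort(
    name: str,
    data: ResponseMatrix,
    key: ItemKey | None,
    config: PipelineConfig,
    outdir: Path,
) -> CohortBundle:
    outdir.mkdir(parents=True, exist_ok=True)
    settings = config.ega_settings()
    stage = "uva"
    try:
        log.info("[%s] redundancy analysis (UVA) on %d items", name, data.n_items)
        reduced, report = run_uva(data, config.uva)
        save_responses(reduced, outdir / "reduced_responses.csv")
        with open(outdir / "redundancy_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        report.merged_items_table().to_csv(outdir / "merged_items.csv", index=False)

        stage = "bootstrap_ega"
        log.info("[%s] bootstrap EGA, B=%d", name, config.bootstrap_B)
        ensemble = bs.bootstrap_ega(
            reduced, B=config.bootstrap_B, seed=config.seed, settings=settings
        )
        export_network(ensemble.empirical_network, outdir / "empirical_network")

        stage = "median_network"
        med = bs.median_network(ensemble)
        export_network(med, outdir / "median_network")

        stage = "spinglass"
        partition = spinglass_partition(
            med,
            gamma_pos=settings.spinglass_gamma_pos,
            gamma_neg=settings.spinglass_gamma_neg,
            max_spins=settings.max_spins,
            seed=config.seed,
            restarts=config.spinglass_restarts,
        )
        save_partition(partition, outdir / "median_partition.json")
        save_partition(ensemble.empirical_partition, outdir / "empirical_partition.json")

        stage = "stability"
        stability = bs.stability_report(ensemble)
        with open(outdir / "stability.json", "w") as fh:
            json.dump(stability.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        stability.item_dimension_table.to_csv(outdir / "item_stability.csv")

        stage = "metrics"
        loadings = network_loadings(med, partition)
        loadings.to_csv(outdir / "loadings.csv")
        centrality = centrality_table(med)
        centrality.to_csv(outdir / "centrality.csv")
        if key is not None:
            agreement = subscale_agreement(partition, key, report.merge_map)
            agreement.to_csv(outdir / "agreement.csv", index=False)

        run_log = {
            "cohort": name,
            "seed": config.seed,
            "n_respondents": data.n_respondents,
            "n_items_original": data.n_items,
            "n_items_reduced": reduced.n_items,
            "uva_rounds": report.rounds,
            "empirical_lambda": ensemble.empirical_network.lambda_,
            "bootstrap_B": config.bootstrap_B,
            "bootstrap_redraws": ensemble.n_redraws,
            "replicate_seeds": f"{config.seed}+b for b in 1..{config.bootstrap_B}",
            "spinglass_seed": config.seed,
            "spinglass_restarts": config.spinglass_restarts,
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"[{name}] stage {stage!r} failed: {exc}") from exc
    return CohortBundle(
        name=name,
        reduced_data=reduced,
        report=report,
        ensemble=ensemble,
        median_net=med,
        median_partition=partition,
        stability=stability,
        original_items=tuple(data.item_ids),
    )


def run_validation(config: PipelineConfig) -> dict[str, CohortBundle]:
    """Full validation of every cohort; returns the in-memory bundles."""
    data = load_responses(config.responses, likert_max=config.likert_max)
    key = load_item_key(config.item_key) if config.item_key else None
    out = Path(config.output_dir)
    bundles: dict[str, CohortBundle] = {}
    bundles["cross-sample"] = _validate_cohort(
        "cross-sample", data, key, config, out / "cross-sample"
    )
    for label in config.cohort_labels:
        cohort = data.subset([label])
        bundles[label] = _validate_cohort(label, cohort, key, config, out / label)
    return bundles


def run_comparison(
    bundles: dict[str, CohortBundle], output_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise NMI/AMI of cohort partitions expanded to the original items.

    Returns (agreement table, per-item label table flagging migrating items).
    """
    if len(bundles) < 2:
        raise ValueError("need at least two cohorts to compare")
    item_sets = {b.original_items for b in bundles.values()}
    if len(item_sets) != 1:
        raise ValueError("cohorts do not share the original item set")
    expanded = {name: b.expanded_partition() for name, b in bundles.items()}
    names = list(expanded)
    # align labels to the first cohort so the per-item table is comparable
    reference = expanded[names[0]]
    aligned = {names[0]: reference}
    for name in names[1:]:
        aligned[name] = bs.align_labels(expanded[name], reference)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append(
                {
                    "network_1": a,
                    "network_2": b,
                    "nmi": nmi(expanded[a], expanded[b]),
                    "ami": ami(expanded[a], expanded[b]),
                }
            )
    agreement = pd.DataFrame(rows)
    items = sorted(next(iter(item_sets)), key=lambda s: (0, int(s)) if s.isdigit() else (1, s))
    label_table = pd.DataFrame(
        {name: [aligned[name].as_dict()[i] for i in items] for name in names},
        index=items,
    )
    label_table["migrating"] = label_table.nunique(axis=1) > 1
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        agreement.to_csv(outdir / "partition_agreement.csv", index=False)
        label_table.to_csv(outdir / "item_labels.csv")
    return agreement, label_table
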