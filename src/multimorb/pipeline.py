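"""End-to-end survey pipeline: simulate/read -> classify -> estimate -> model -> network.

Deterministic given the configured seed; every stage appends a run-log
entry (stage, parameters, records in/out) and all tables are written as
UTF-8 delimited text with ``NA`` for missing values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditions import CONDITIONS, ConditionThresholds, classify_cohort
from .network import build_network, louvain, network_metrics, sensitivity_sweep
from .prevalence import StandardPopulation, age_standardize, prevalence_table, stratified_counts
from .regression import forest_table
from .synthetic import CohortSpec, generate_cohort_frame, read_cohort, write_cohort

logger = logging.getLogger("multimorb")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "multimorb_out"
    cohort_path: str | None = None  # read this cohort instead of simulating
    n_participants: int = 2333
    seed: int = 20240701
    deff: float = 1.5
    confidence: float = 0.95
    weight_scheme: str = "joint_prevalence"
    min_node_prevalence: float = 0.05
    edge_threshold: float = 0.0
    sweep_thresholds: tuple[float, ...] = (0.0, 0.01, 0.02)
    age_band: float = 10.0
    thresholds: ConditionThresholds = field(default_factory=ConditionThresholds)
    warn_missing_above: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected, thresholds nested."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    thr = raw.pop("thresholds", {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if thr:
        cfg.thresholds = dataclasses.replace(ConditionThresholds(), **thr)
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns a dict of in-memory results (cohort, panel, tables, network,
    partition, metrics, log).
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, n_in: int, n_out: int, **params):
        entry = {"stage": name, "records_in": n_in, "records_out": n_out, **params}
        log.append(entry)
        logger.info("%s: %d -> %d %s", name, n_in, n_out, params)

    # 1. cohort -----------------------------------------------------------
    if config.cohort_path is None:
        spec = CohortSpec(n_participants=config.n_participants, seed=config.seed)
        cohort = generate_cohort_frame(spec)
        write_cohort(cohort, out / "cohort.csv")
        stage("simulate", 0, len(cohort), seed=config.seed)
    else:
        cohort = read_cohort(config.cohort_path)
        n_raw = len(cohort)
        bad = cohort["age"].isna() | cohort["sex"].isna()
        if bad.any():
            logger.warning("skipping %d malformed row(s): %s", bad.sum(), list(cohort.index[bad]))
            cohort = cohort.loc[~bad]
        stage("read_cohort", n_raw, len(cohort), path=str(config.cohort_path))
    for col in ("fbs", "hb", "serum_creatinine"):
        if col in cohort:
            frac = float(cohort[col].isna().mean())
            if frac > config.warn_missing_above:
                logger.warning("missingness for %s is %.1f%%", col, 100 * frac)

    # 2. classify ---------------------------------------------------------
    panel = classify_cohort(cohort, config.thresholds)
    panel.to_csv(out / "panel.csv", index=False, na_rep="NA", encoding="utf-8")
    stage("classify", len(cohort), len(panel))

    # 3. prevalence -------------------------------------------------------
    prev = prevalence_table(panel, deff=config.deff, confidence=config.confidence)
    std = StandardPopulation.from_ages(cohort["age"], band=config.age_band)
    strata = stratified_counts(panel, cohort["age"], "multimorbid", std)
    std_est = age_standardize(strata, std, deff=config.deff, confidence=config.confidence)
    prev = pd.concat(
        [
            prev,
            pd.DataFrame(
                [
                    {
                        "condition": "multimorbid_age_standardized",
                        "cases": std_est.cases,
                        "denominator": std_est.denominator,
                        "prevalence_pct": std_est.percent,
                        "ci_low_pct": round(100 * std_est.ci_low, 1),
                        "ci_high_pct": round(100 * std_est.ci_high, 1),
                        "deff": config.deff,
                    }
                ]
            ),
        ],
        ignore_index=True,
    )
    prev.to_csv(out / "prevalence.csv", index=False, na_rep="NA", encoding="utf-8")
    stage("prevalence", len(panel), len(prev), deff=config.deff)

    # 4. regression -------------------------------------------------------
    try:
        forest = forest_table(cohort, panel, config.thresholds, config.confidence)
    except Exception as exc:  # degenerate cohorts (tiny n, constant covariates)
        logger.warning("regression stage skipped: %s", exc)
        forest = pd.DataFrame()
    forest.to_csv(out / "regression.csv", index=False, na_rep="NA", encoding="utf-8")
    stage("regress", len(panel), len(forest), n_used=int(forest["n_used"].iloc[0]) if len(forest) else 0)

    # 5. network ----------------------------------------------------------
    net = part = met = None
    try:
        net = build_network(
            panel,
            weight_scheme=config.weight_scheme,
            min_node_prevalence=config.min_node_prevalence,
            edge_threshold=config.edge_threshold,
        )
        part = louvain(net, seed=config.seed) if net.edges else None
        met = network_metrics(net)
    except Exception as exc:
        logger.warning("network stage skipped: %s", exc)
    if net is not None:
        net.edge_frame().to_csv(out / "network_edges.csv", index=False, encoding="utf-8")
        import networkx as nx

        nx.write_graphml(net.to_networkx(), out / "network.graphml")
        with open(out / "partition.csv", "w", encoding="utf-8") as fh:
            if part is not None:
                fh.write(
                    f"# modularity={part.modularity:.6f} resolution={part.resolution} seed={part.seed}\n"
                )
                fh.write("node,community\n")
                for v in net.nodes:
                    fh.write(f"{v},{part.assignment[v]}\n")
            else:
                fh.write("node,community\n")
        (out / "network_metrics.json").write_text(
            json.dumps(dataclasses.asdict(met), indent=2), encoding="utf-8"
        )
        stage("network", len(panel), len(net.nodes), edges=len(net.edges), scheme=config.weight_scheme)

    # 6. sensitivity sweep ------------------------------------------------
    try:
        sweep = sensitivity_sweep(
            panel,
            thresholds=config.sweep_thresholds,
            include_rare=True,
            min_node_prevalence=config.min_node_prevalence,
            seed=config.seed,
        )
    except Exception as exc:
        logger.warning("sensitivity sweep skipped: %s", exc)
        sweep = pd.DataFrame()
    sweep.to_csv(out / "sensitivity.csv", index=False, na_rep="NA", encoding="utf-8")
    stage("sweep", len(panel), len(sweep))

    # 7. run metadata -----------------------------------------------------
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
        "stages": log,
    }
    (out / "run_log.json").write_text(json.dumps(meta, indent=2, default=str), encoding="utf-8")
    return {
        "cohort": cohort,
        "panel": panel,
        "prevalence": prev,
        "regression": forest,
        "network": net,
        "partition": part,
        "metrics": met,
        "sweep": sweep,
        "log": meta,
    }
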