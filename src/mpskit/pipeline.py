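"""End-to-end pipeline: simulate cohorts, quantify every axon, compare conditions.

A run is fully described by a configuration (seed, per-condition lattice
parameters, analysis settings) and is deterministic: the same configuration
and seed reproduce every output file.  Unquantifiable axons are logged,
counted and excluded from the summaries, mirroring per-condition axon counts
in reported group statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import List, Optional

import yaml

from . import __version__
from .exceptions import ConfigError
from .group_stats import summarize
from .locio import write_locs
from .occupancy import OccupancyConfig
from .periodicity import AnalysisConfig, quantify_axon
from .synthetic import ConditionSpec, LatticeParams, simulate_cohort

logger = logging.getLogger("mpskit")

__all__ = ["RunConfig", "validate_config", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    conditions: List[ConditionSpec]
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    occupancy: OccupancyConfig = field(default_factory=OccupancyConfig)
    corridor_nm: float = 500.0
    log_level: str = "INFO"

    def __post_init__(self):
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigError("condition labels must be unique")


def _build_config(raw: dict) -> RunConfig:
    """Turn a parsed mapping into a RunConfig, collecting all violations."""
    violations = []
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        violations.append("seed: must be an integer")
        seed = 0

    try:
        analysis = AnalysisConfig(**raw.get("analysis", {}))
    except (ConfigError, TypeError) as exc:
        violations.append(f"analysis: {exc}")
        analysis = AnalysisConfig()

    try:
        occ = OccupancyConfig(**raw.get("occupancy", {}))
    except TypeError as exc:
        violations.append(f"occupancy: {exc}")
        occ = OccupancyConfig()

    conditions = []
    seen = set()
    raw_conditions = raw.get("conditions", [])
    if not raw_conditions:
        violations.append("conditions: at least one condition is required")
    for i, cond in enumerate(raw_conditions):
        prefix = f"conditions[{i}]"
        label = cond.get("label")
        if not label:
            violations.append(f"{prefix}.label: missing")
            continue
        if label in seen:
            violations.append(f"{prefix}.label: duplicate label {label!r}")
            continue
        seen.add(label)
        try:
            params = LatticeParams(**cond.get("params", {}))
            conditions.append(
                ConditionSpec(
                    label=str(label),
                    n_axons=int(cond.get("n_axons", 20)),
                    params=params,
                    seed=int(cond.get("seed", seed + i)),
                )
            )
        except (ConfigError, TypeError, ValueError) as exc:
            violations.append(f"{prefix}: {exc}")

    if violations:
        raise ConfigError(
            "invalid configuration:\n" + "\n".join(violations), violations=violations
        )
    return RunConfig(
        seed=seed,
        conditions=conditions,
        analysis=analysis,
        occupancy=occ,
        corridor_nm=float(raw.get("corridor_nm", 500.0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def validate_config(path) -> RunConfig:
    """Parse and invariant-check a YAML run configuration.

    Raises :class:`ConfigError` whose ``violations`` attribute lists every
    problem with its field path.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: cannot parse configuration: {exc}") from exc
    return _build_config(raw)


load_config = validate_config


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["conditions"] = [dataclasses.asdict(c) for c in cfg.conditions]
    return d


def run_pipeline(cfg: RunConfig, out_dir, write_tables: bool = True) -> dict:
    """Execute simulate → quantify → compare and write all artifacts.

    Writes per-axon localization tables (optional) and autocorrelation
    results, a per-condition summary table, a pairwise comparison table and a
    manifest capturing the seed, the fully-expanded configuration and its
    hash.  Returns the manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    locs_dir = os.path.join(out_dir, "locs")
    results_dir = os.path.join(out_dir, "results")
    os.makedirs(results_dir, exist_ok=True)

    config_echo = _config_dict(cfg)
    config_json = json.dumps(config_echo, sort_keys=True, default=str)
    config_hash = hashlib.sha256(config_json.encode()).hexdigest()

    groups = {}
    axon_records = []
    unquantifiable = {}
    for cond in cfg.conditions:
        tables, _truth = simulate_cohort(cond)
        amplitudes = []
        unquantifiable[cond.label] = 0
        if write_tables:
            os.makedirs(os.path.join(locs_dir, cond.label), exist_ok=True)
        for table in tables:
            if write_tables:
                write_locs(
                    table, os.path.join(locs_dir, cond.label, f"{table.axon_id}.csv")
                )
            result = quantify_axon(
                table, cfg=cfg.analysis, corridor_nm=cfg.corridor_nm
            )
            with open(os.path.join(results_dir, f"{table.axon_id}.json"), "w") as fh:
                json.dump(result.to_dict(), fh, indent=1)
            axon_records.append(
                {"axon_id": table.axon_id, "condition": cond.label,
                 "status": result.status}
            )
            if result.status == "ok":
                amplitudes.append(result.amplitude)
            else:
                unquantifiable[cond.label] += 1
                logger.warning("axon %s is unquantifiable", table.axon_id)
        if amplitudes:
            groups[cond.label] = amplitudes

    summaries, comparisons = summarize(groups)
    summary_path = os.path.join(out_dir, "summary.csv")
    with open(summary_path, "w") as fh:
        fh.write("label,mean,sem,n,n_unquantifiable\n")
        for s in summaries:
            fh.write(
                f"{s.label},{s.mean!r},{s.sem!r},{s.n},{unquantifiable[s.label]}\n"
            )
    comparisons_path = os.path.join(out_dir, "comparisons.csv")
    comparisons.to_csv(comparisons_path, index=False, lineterminator="\n")

    manifest = {
        "mpskit_version": __version__,
        "seed": cfg.seed,
        "config": config_echo,
        "config_sha256": config_hash,
        "n_axons": {c.label: c.n_axons for c in cfg.conditions},
        "n_unquantifiable": unquantifiable,
        "axons": axon_records,
        "outputs": {
            "summary": os.path.basename(summary_path),
            "comparisons": os.path.basename(comparisons_path),
            "results_dir": "results",
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
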