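"""End-to-end orchestration: load or simulate data, build layers, describe,
fit the model suite, run post hoc tests, and emit a report bundle.

All randomness flows from one global seed through a deterministic hierarchy
of per-stage seeds, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    DIRECTED_LAYERS,
    LayerNetwork,
    PersonRecord,
    build_household_network,
    build_layer,
    read_edge_list,
    read_node_table,
    write_edge_list,
    write_node_table,
)
from .descriptives import (
    acceptance_prevalence,
    centrality_by_group,
    centrality_profile,
    composition_summary,
    ego_alter_crosstab,
    jaccard_overlap,
    perception_summary,
    summary_table,
)
from .suite import (
    FitConfig,
    edge_directionality_test,
    higher_order_suite,
    run_model_suite,
)
from .synthetic import generate_scenario_data, get_preset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    def __init__(self, errors: Sequence[str]):
        super().__init__("; ".join(errors))
        self.errors = list(errors)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``preset`` (synthetic scenario name) or ``inputs``
    (paths: node_table, chatting_edges, respect_edges) is set; the seed is
    mandatory.
    """

    seed: int
    outdir: str
    preset: str | None = None
    inputs: Mapping[str, str] | None = None
    layers: Sequence[str] = ("chatting", "respect", "household")
    draws: int = 2000
    burn: int = 1000
    thin: int = 1
    aux_sweeps: int = 30
    prior_sd: float = 10.0
    covariates: Sequence[str] = ("gender", "education", "wealth_rank", "village")
    run_directionality: bool = True
    run_higher_order: bool = False
    log_level: str = "INFO"

    def fit_config(self, seed: int) -> FitConfig:
        return FitConfig(seed=seed, covariates=self.covariates,
                         prior_sd=self.prior_sd, draws=self.draws,
                         burn=self.burn, thin=self.thin,
                         aux_sweeps=self.aux_sweeps)


def validate_config_dict(raw: Mapping) -> RunConfig:
    errors = []
    if "seed" not in raw:
        errors.append("seed is mandatory")
    preset, inputs = raw.get("preset"), raw.get("inputs")
    if (preset is None) == (inputs is None):
        errors.append("exactly one of 'preset' or 'inputs' must be set")
    if inputs is not None:
        for key in ("node_table",):
            if key not in inputs:
                errors.append(f"inputs missing {key!r}")
    if "outdir" not in raw:
        errors.append("outdir is mandatory")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(**{k: raw[k] for k in raw})


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(["config file must contain a mapping"])
    return validate_config_dict(raw)


def load_input_data(inputs: Mapping[str, str]
                    ) -> tuple[list[PersonRecord], dict[str, LayerNetwork]]:
    records, report = read_node_table(inputs["node_table"])
    if report.errors:
        logger.warning("node table: %d rows rejected", report.n_rejected)
    layers: dict[str, LayerNetwork] = {}
    for layer in DIRECTED_LAYERS:
        key = f"{layer}_edges"
        if key in inputs:
            ties, tie_report = read_edge_list(inputs[key], layer, records)
            if tie_report.errors:
                logger.warning("%s edges: %d rows rejected", layer,
                               tie_report.n_rejected)
            layers[layer] = build_layer(ties, records, layer)
    layers["household"] = build_household_network(records)
    return records, layers


@dataclass
class PipelineReport:
    outdir: str
    stages: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def ok(self, stage: str) -> bool:
        return self.stages.get(stage) == "ok"


def _describe_stage(records, layers, outdir, outputs):
    nets = [layers[k] for k in layers]
    tab = summary_table(nets)
    path = os.path.join(outdir, "structural_characteristics.csv")
    tab.to_csv(path)
    outputs.append(path)
    overlaps = {}
    names = list(layers)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            try:
                overlaps[f"{names[i]}-{names[j]}"] = jaccard_overlap(
                    layers[names[i]], layers[names[j]])
            except ValueError:
                overlaps[f"{names[i]}-{names[j]}"] = float("nan")
    path = os.path.join(outdir, "jaccard_overlap.csv")
    pd.Series(overlaps, name="jaccard").to_csv(path)
    outputs.append(path)
    outcome = {r.person_id: r.ipvaw_accept for r in records
               if r.ipvaw_accept is not None}
    for name, net in layers.items():
        prof = centrality_profile(net, records)
        path = os.path.join(outdir, f"centrality_{name}.csv")
        prof.to_csv(path)
        outputs.append(path)
        for group in ("community_role", "ipvaw_accept"):
            path = os.path.join(outdir, f"centrality_{name}_by_{group}.csv")
            centrality_by_group(prof, group).to_csv(path)
            outputs.append(path)
        path = os.path.join(outdir, f"crosstab_{name}.csv")
        ego_alter_crosstab(net, outcome).to_csv(path)
        outputs.append(path)
    ties_meta = [t for name in DIRECTED_LAYERS if name in layers
                 for t in _layer_ties(layers[name])]
    if ties_meta:
        path = os.path.join(outdir, "composition.csv")
        composition_summary(ties_meta, records).to_csv(path)
        outputs.append(path)
    path = os.path.join(outdir, "perceptions.csv")
    perception_summary(records).to_csv(path)
    outputs.append(path)
    path = os.path.join(outdir, "acceptance_prevalence.csv")
    acceptance_prevalence(records).to_csv(path)
    outputs.append(path)


def _layer_ties(net: LayerNetwork):
    from .data import TieRecord

    return [TieRecord(ego_id=e, alter_id=a, layer=net.name,
                      kin=m.get("kin"), ego_gender=m.get("ego_gender"),
                      alter_gender=m.get("alter_gender"))
            for e, a, m in net.iter_ties()]


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis: data, descriptives, model suite, post hoc
    tests, manifest. Idempotent for a fixed seed; any stage failure is
    logged and independent stages continue."""
    os.makedirs(config.outdir, exist_ok=True)
    report = PipelineReport(outdir=config.outdir)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2 ** 31))
                   for s in ("data", "suite", "directionality", "higher_order")}

    records: list[PersonRecord] | None = None
    layers: dict[str, LayerNetwork] | None = None
    try:
        if config.preset is not None:
            scenario = get_preset(config.preset, seed=stage_seeds["data"])
            records, layers, _ = generate_scenario_data(scenario)
            write_node_table(records, os.path.join(config.outdir, "node_table.csv"))
        else:
            records, layers = load_input_data(config.inputs)
        layers = {k: v for k, v in layers.items() if k in config.layers}
        report.stages["data"] = "ok"
    except Exception as exc:
        logger.error("data stage failed: %s", exc)
        report.stages["data"] = f"failed: {exc}"

    if report.ok("data"):
        try:
            _describe_stage(records, layers, config.outdir, report.outputs)
            report.stages["describe"] = "ok"
        except Exception as exc:
            logger.error("describe stage failed: %s", exc)
            report.stages["describe"] = f"failed: {exc}"

        try:
            suite = run_model_suite(layers, records,
                                    config.fit_config(stage_seeds["suite"]))
            report.outputs += suite.save(config.outdir)
            report.stages["fit"] = "ok" if not suite.failures() else (
                "partial: " + "; ".join(f"{k}: {v}" for k, v in
                                        suite.failures().items()))
        except Exception as exc:
            logger.error("fit stage failed: %s", exc)
            report.stages["fit"] = f"failed: {exc}"

        if config.run_directionality:
            try:
                rows = []
                for layer in config.layers:
                    if layer in layers and layers[layer].directed:
                        res = edge_directionality_test(
                            layers[layer], records,
                            config.fit_config(stage_seeds["directionality"]))
                        path = os.path.join(config.outdir,
                                            f"directionality_{layer}.csv")
                        res.summary_frame().to_csv(path, index=False)
                        report.outputs.append(path)
                        if res.comparison is not None:
                            row = res.comparison.copy()
                            row["layer"] = layer
                            rows.append(row)
                if rows:
                    path = os.path.join(config.outdir,
                                        "directionality_comparison.csv")
                    pd.DataFrame(rows).to_csv(path, index=False)
                    report.outputs.append(path)
                report.stages["directionality"] = "ok"
            except Exception as exc:
                logger.error("directionality stage failed: %s", exc)
                report.stages["directionality"] = f"failed: {exc}"

        if config.run_higher_order:
            try:
                for layer in config.layers:
                    if layer in layers and layers[layer].directed:
                        res = higher_order_suite(
                            layers[layer], records,
                            config.fit_config(stage_seeds["higher_order"]))
                        report.outputs += res.save(config.outdir)
                report.stages["higher_order"] = "ok"
            except Exception as exc:
                logger.error("higher-order stage failed: %s", exc)
                report.stages["higher_order"] = f"failed: {exc}"

    manifest = {
        "package": "alaamnet",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "preset": config.preset,
        "layers": list(config.layers),
        "stages": report.stages,
        "outputs": sorted(os.path.basename(p) for p in report.outputs),
    }
    path = os.path.join(config.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report.outputs.append(path)
    _write_text_report(report, config)
    return report


def _write_text_report(report: PipelineReport, config: RunConfig) -> None:
    lines = [f"alaamnet pipeline report (seed={config.seed})", ""]
    for stage, status in report.stages.items():
        lines.append(f"  {stage}: {status}")
    lines += ["", f"{len(report.outputs)} output files in {config.outdir}"]
    path = os.path.join(config.outdir, "report.txt")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    report.outputs.append(path)


def simulate_to_directory(preset: str, seed: int, outdir: str) -> dict[str, str]:
    """Write a synthetic scenario as node table + per-layer edge lists in the
    package CSV dialect; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    scenario = get_preset(preset, seed=seed)
    records, layers, ties = generate_scenario_data(scenario)
    paths = {"node_table": os.path.join(outdir, "node_table.csv")}
    write_node_table(records, paths["node_table"])
    for layer in DIRECTED_LAYERS:
        layer_ties = [t for t in ties if t.layer == layer]
        if layer_ties:
            path = os.path.join(outdir, f"{layer}_edges.csv")
            write_edge_list(layer_ties, path)
            paths[f"{layer}_edges"] = path
    return paths
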