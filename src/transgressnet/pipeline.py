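"""One-command orchestration of the full analysis.

``run_all`` wires the stages end to end — (optional) simulate ->
normalize -> classify -> trace -> select -> network -> mirna — and
writes a JSON run report embedding every parameter and the checksum of
every input and output, so a run is reproducible from the report alone.
Stages are idempotent; a stage failure aborts the run, names the stage,
and leaves a ``RUN.partial`` marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as tio
from . import mirna as tmirna
from .classify import classify_all, set_intersections, summarize_calls
from .inheritance import trace_all
from .modules import refine_by_early_contrast, select_constitutive, select_steady_upregulated
from .network import build_network, compare_networks, fragmentation_metrics, temporal_profiles
from .normalization import fold_change_tensor, normalize, tmm_factors
from .simulate import GeneratorConfig, SyntheticTruth, generate, truth_report, write_dataset
from .types import PipelineError, Thresholds, UsageError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

STAGES = ("simulate", "normalize", "classify", "trace", "select", "network", "mirna")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    out_dir: str = "run"
    seed: int = 42
    simulate: bool = True
    mrna_counts: str | None = None
    mirna_counts: str | None = None
    sample_sheet: str | None = None
    family_map: str | None = None
    pair_list: str | None = None
    parent_a: str = "IR29"
    parent_b: str = "Pokkali"
    focal: str = "FL510"
    inferior: tuple[str, ...] = ("FL454", "FL499")
    rils: tuple[str, ...] = ("FL478", "FL454", "FL510", "FL499")
    thresholds: Thresholds = field(default_factory=Thresholds)
    pseudocount: float = 1.0
    cpm_cutoff: float = 1.0
    min_samples: int = 2
    down_rule: str = "lenient"
    include_control_zero: bool = True
    repression_rho: float = 0.8
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        if self.focal in (self.parent_a, self.parent_b):
            raise UsageError("focal genotype cannot be a parent")
        if self.focal in self.inferior:
            raise UsageError("focal genotype also listed as inferior")
        if {self.parent_a, self.parent_b} & set(self.rils):
            raise UsageError("parents cannot be listed as RILs")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise UsageError(f"unknown stages: {sorted(unknown)}")
        if not self.simulate:
            for name in ("mrna_counts", "sample_sheet"):
                if getattr(self, name) is None:
                    raise UsageError(f"{name} required when not simulating")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if "thresholds" in payload:
            payload["thresholds"] = Thresholds(**payload["thresholds"])
        for key in ("inferior", "rils", "stages"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict[str, Any]:
        out = asdict(self)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g",
                 lineterminator="\n")


def run_all(config: RunConfig, generator: GeneratorConfig | None = None) -> dict:
    """Execute the configured stages; returns the run report (also
    written to ``<out_dir>/run_report.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "RUN.partial"
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "stages": [],
        "inputs": {},
        "outputs": {},
        "summary": {},
    }
    outputs: dict[str, Path] = {}
    current_stage = "setup"
    try:
        marker.write_text("setup\n")
        # ---- inputs -------------------------------------------------------
        current_stage = "simulate"
        truth: SyntheticTruth | None = None
        if config.simulate and "simulate" in config.stages:
            gen = generator or GeneratorConfig(seed=config.seed)
            dataset = generate(gen)
            sim_paths = write_dataset(dataset, out / "sim")
            outputs.update({f"sim_{k}": v for k, v in sim_paths.items()})
            truth = dataset.truth
            mrna, mirna_counts = dataset.mrna, dataset.mirna
            family_map, pairs = dataset.family_map, dataset.pairs
            report["stages"].append("simulate")
        else:
            mrna = tio.read_count_matrix(config.mrna_counts, config.sample_sheet)
            report["inputs"]["mrna_counts"] = _sha256(Path(config.mrna_counts))
            report["inputs"]["sample_sheet"] = _sha256(Path(config.sample_sheet))
            mirna_counts = None
            family_map = pairs = None
            if config.mirna_counts:
                mirna_counts = tio.read_count_matrix(
                    config.mirna_counts, config.sample_sheet
                )
                report["inputs"]["mirna_counts"] = _sha256(Path(config.mirna_counts))
            if config.family_map:
                family_map = tmirna.read_family_map(config.family_map)
            if config.pair_list:
                pairs = tmirna.read_pair_list(config.pair_list)

        th = config.thresholds

        # ---- normalize ----------------------------------------------------
        current_stage = "normalize"
        marker.write_text("normalize\n")
        factors = tmm_factors(mrna)
        norm = normalize(mrna, factors)
        tensor = fold_change_tensor(norm, pseudocount=config.pseudocount)
        design = tio.validate_design(mrna)
        norm_path = out / "normalized_cpm.tsv"
        norm_table = norm.values.copy()
        norm_table.index.name = "gene_id"
        norm_table.to_csv(norm_path, sep="\t", float_format="%.10g", lineterminator="\n")
        fc_path = out / "fold_change.tsv"
        tio.write_fold_change(tensor, fc_path)
        _write_tsv(design.cells, out / "design_report.tsv")
        outputs.update({
            "normalized_cpm": norm_path,
            "fold_change": fc_path,
            "design_report": out / "design_report.tsv",
        })
        report["summary"]["n_genes"] = len(mrna.gene_ids)
        report["summary"]["n_samples"] = len(mrna.samples)
        report["summary"]["design_flags"] = design.flags
        report["stages"].append("normalize")

        # ---- classify -----------------------------------------------------
        if "classify" in config.stages:
            current_stage = "classify"
            marker.write_text("classify\n")
            calls = classify_all(tensor, threshold=th.fc_threshold)
            _write_tsv(calls, out / "response_calls.tsv")
            _write_tsv(summarize_calls(calls), out / "response_summary.tsv")
            outputs["response_calls"] = out / "response_calls.tsv"
            outputs["response_summary"] = out / "response_summary.tsv"
            for which in ("up", "down", "constant"):
                table = set_intersections(calls, which)
                _write_tsv(table.to_frame(), out / f"upset_{which}.tsv")
                outputs[f"upset_{which}"] = out / f"upset_{which}.tsv"
                report["summary"][f"{which}_union"] = table.union_size
            report["stages"].append("classify")

        # ---- trace --------------------------------------------------------
        trace = None
        if "trace" in config.stages:
            current_stage = "trace"
            marker.write_text("trace\n")
            trace = trace_all(
                tensor, norm, config.parent_a, config.parent_b, list(config.rils),
                thresholds=th, min_samples=config.min_samples,
            )
            _write_tsv(trace.calls, out / "inheritance.tsv")
            counts = trace.category_counts.reset_index().rename(columns={"index": "ril"})
            _write_tsv(counts, out / "inheritance_counts.tsv")
            _write_tsv(trace.shared_counts, out / "inheritance_shared.tsv")
            outputs["inheritance"] = out / "inheritance.tsv"
            outputs["inheritance_counts"] = out / "inheritance_counts.tsv"
            outputs["inheritance_shared"] = out / "inheritance_shared.tsv"
            report["stages"].append("trace")

        # ---- select -------------------------------------------------------
        steady = refined = constitutive = None
        if "select" in config.stages:
            current_stage = "select"
            marker.write_text("select\n")
            steady = select_steady_upregulated(tensor, config.focal, th.fc_threshold)
            refined = refine_by_early_contrast(
                steady, tensor, list(config.inferior),
                down_rule=config.down_rule, threshold=th.fc_threshold,
            )
            constitutive = select_constitutive(
                tensor, config.focal, (config.parent_a, config.parent_b),
                base_threshold=th.fc_threshold,
                stability_threshold=th.fc_threshold,
                pseudocount=config.pseudocount,
            )
            for module, name in (
                (steady, "module_steady_up"),
                (refined, "module_steady_up_refined"),
                (constitutive, "module_constitutive"),
            ):
                tio.write_gene_list(module.members, out / f"{name}.txt")
                with open(out / f"{name}.rule.json", "w", encoding="utf-8") as fh:
                    json.dump(module.rule, fh, indent=1, sort_keys=True)
                    fh.write("\n")
                outputs[name] = out / f"{name}.txt"
                outputs[f"{name}_rule"] = out / f"{name}.rule.json"
                report["summary"][name] = len(module)
            report["stages"].append("select")

        # ---- network ------------------------------------------------------
        ranking = None
        if "network" in config.stages and steady is not None:
            current_stage = "network"
            marker.write_text("network\n")
            net_summaries = []
            for module, pos, neg, tag in (
                (steady, th.pcc_responsive, -th.pcc_responsive, "steady"),
                (constitutive, th.pcc_constitutive, -th.pcc_constitutive, "constitutive"),
            ):
                if not module.members:
                    continue
                reports = []
                for g in tensor.genotypes:
                    profiles = temporal_profiles(
                        tensor, module.members, g,
                        include_control_zero=config.include_control_zero,
                    )
                    net = build_network(profiles, pos, neg, genotype=g)
                    tio.write_network(net, out / f"net_{tag}_{g}")
                    outputs[f"net_{tag}_{g}_edges"] = out / f"net_{tag}_{g}.edges.tsv"
                    outputs[f"net_{tag}_{g}_graphml"] = out / f"net_{tag}_{g}.graphml"
                    reports.append(fragmentation_metrics(net))
                table = compare_networks(reports)
                table.insert(0, "module", tag)
                net_summaries.append(table)
                if tag == "steady":
                    ranking = table
            if net_summaries:
                _write_tsv(pd.concat(net_summaries, ignore_index=True),
                           out / "fragmentation_report.tsv")
                outputs["fragmentation_report"] = out / "fragmentation_report.tsv"
            report["stages"].append("network")

        # ---- mirna --------------------------------------------------------
        pair_table = None
        if "mirna" in config.stages and mirna_counts is not None and family_map:
            current_stage = "mirna"
            marker.write_text("mirna\n")
            fam_counts = tmirna.collapse_families(mirna_counts, family_map, mode="sum")
            fam_norm = normalize(fam_counts)
            fam_fc = fold_change_tensor(fam_norm, pseudocount=config.pseudocount)
            ranges = tmirna.family_range_stats(fam_fc)
            _write_tsv(ranges, out / "mirna_family_ranges.tsv")
            outputs["mirna_family_ranges"] = out / "mirna_family_ranges.tsv"
            if pairs:
                pair_table, problems = tmirna.pair_correlation(
                    fam_fc, tensor, pairs, rho=config.repression_rho,
                    include_control_zero=config.include_control_zero,
                )
                _write_tsv(pair_table, out / "mirna_target_pairs.tsv")
                outputs["mirna_target_pairs"] = out / "mirna_target_pairs.tsv"
                if problems:
                    report["summary"]["mirna_pair_problems"] = problems
            report["stages"].append("mirna")

        # ---- recovery against planted truth -------------------------------
        if truth is not None:
            module_ranking = None
            if truth.module_genes and "network" in config.stages:
                module_reports = []
                for g in tensor.genotypes:
                    profiles = temporal_profiles(
                        tensor, truth.module_genes, g,
                        include_control_zero=config.include_control_zero,
                    )
                    net = build_network(
                        profiles, th.pcc_responsive, -th.pcc_responsive, genotype=g
                    )
                    module_reports.append(fragmentation_metrics(net))
                module_ranking = compare_networks(module_reports)
            recovery = truth_report(
                truth,
                trace_calls=trace.calls if trace is not None else None,
                steady_module=steady,
                constitutive_module=constitutive,
                network_ranking=module_ranking,
                pair_table=pair_table,
            )
            report["summary"]["recovery"] = {
                k: (None if pd.isna(v) else v) for k, v in recovery.metrics.items()
            }

        report["outputs"] = {k: _sha256(p) for k, p in sorted(outputs.items())}
        report["output_files"] = {k: str(p) for k, p in sorted(outputs.items())}
        report_path = out / "run_report.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        marker.unlink(missing_ok=True)
        return report
    except Exception as exc:
        marker.write_text(f"failed at stage: {current_stage}\n")
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc
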