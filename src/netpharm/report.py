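"""End-to-end pipeline orchestration and report assembly.

Stage order: validate -> MEI -> threshold/MTI -> DSWMP -> report. The
report is self-describing: it echoes every analysis parameter, and all of
its numbers are recomputable from the bundled inputs plus that echo.

Reports are deterministic by default (no wall-clock timestamp) so that the
same inputs and seed produce byte-identical output; pass ``timestamp`` to
stamp one in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .dswmp import DswmpConfig, cross_system_overlap, score_all_pathways, top_k
from .io import validate_study, write_study_bundle
from .mei import build_mei_network, enzyme_function_tally, node_degrees, select_hubs
from .model import SYSTEMS, BipartiteNetwork, StudyBundle, StudyConfig, round_half_up
from .mti import (
    ThresholdRule,
    build_mti_network,
    shared_targets,
    summarize_network,
    system_membership_classes,
    threshold_edges,
)

__all__ = ["PipelineError", "PipelineReport", "run_pipeline", "export_network"]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and the cause."""

    def __init__(self, stage: str, cause: str) -> None:
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(slots=True)
class PipelineReport:
    """Everything the pipeline computed, JSON-serializable."""

    config: dict[str, Any]
    validation: dict[str, Any]
    mei: dict[str, Any]
    mti: dict[str, Any]
    dswmp: dict[str, Any]
    version: str = __version__
    timestamp: str | None = None
    networks: dict[str, BipartiteNetwork] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict[str, Any]:
        out = {
            "version": self.version,
            "config": self.config,
            "validation": self.validation,
            "mei": self.mei,
            "mti": self.mti,
            "dswmp": self.dswmp,
        }
        if self.timestamp is not None:
            out["timestamp"] = self.timestamp
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _summary_dict(net: BipartiteNetwork) -> dict[str, Any]:
    s = summarize_network(net)
    mrl, mlr = s.rounded()
    return {
        "n_left": s.n_left,
        "n_right": s.n_right,
        "n_edges": s.n_edges,
        "mean_right_per_left": mrl,
        "mean_left_per_right": mlr,
        "empty": s.is_empty,
    }


def run_pipeline(bundle: StudyBundle, config: StudyConfig | None = None,
                 *, timestamp: str | None = None) -> PipelineReport:
    """Run every analysis stage on a validated bundle."""
    config = config or StudyConfig()

    issues = validate_study(bundle)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise PipelineError(
            "validate", f"{len(errors)} error(s); first: {errors[0].message}")
    validation = {
        "n_errors": 0,
        "n_warnings": sum(1 for i in issues if i.severity == "warning"),
    }

    # --- MEI ---
    mei_section: dict[str, Any] = {}
    networks: dict[str, BipartiteNetwork] = {}
    if bundle.relations:
        try:
            mei_net = build_mei_network(bundle.relations, bundle.biomarkers,
                                        bundle.enzymes)
        except ValueError as e:
            raise PipelineError("mei", str(e)) from e
        networks["mei"] = mei_net
        bm_deg = node_degrees(mei_net, "biomarker")
        en_deg = node_degrees(mei_net, "enzyme")
        mei_section = {
            "summary": _summary_dict(mei_net),
            "biomarker_degrees": [[r.node_id, r.degree] for r in bm_deg],
            "enzyme_degrees": [[r.node_id, r.degree] for r in en_deg],
            "hub_biomarkers": select_hubs(bm_deg, config.hub_min_degree),
            "hub_min_degree": config.hub_min_degree,
            "function_tally": enzyme_function_tally(mei_net, bundle.enzymes),
        }

    # --- threshold + MTI ---
    mti_section: dict[str, Any] = {}
    edges_by_system: dict[str, list] = {}
    if bundle.scores is not None and bundle.targets:
        rule = ThresholdRule(threshold=config.threshold_pkd,
                             comparator=config.comparator)
        try:
            edges = threshold_edges(bundle.scores, rule)
        except Exception as e:  # pragma: no cover - defensive
            raise PipelineError("threshold", str(e)) from e
        per_system: dict[str, Any] = {}
        for system in SYSTEMS:
            net = build_mti_network(edges, system, bundle.targets)
            networks[f"mti_{system}"] = net
            edges_by_system[system] = net.edges()
            per_system[system] = _summary_dict(net)
        classes = system_membership_classes(bundle.targets)
        mti_section = {
            "threshold_pkd": rule.threshold,
            "comparator": rule.comparator,
            "n_passing_edges": len(edges),
            "per_system": per_system,
            "membership_class_sizes": classes.class_sizes(),
            "shared_targets": shared_targets(
                {s: networks[f"mti_{s}"] for s in SYSTEMS}),
        }

    # --- DSWMP ---
    dswmp_section: dict[str, Any] = {}
    if edges_by_system and bundle.pathways:
        dcfg = DswmpConfig(count_mode=config.count_mode, top_k=config.top_k)
        try:
            scored = score_all_pathways(
                edges_by_system, bundle.pathways, dcfg,
                n_biomarkers=len(bundle.scores.biomarker_ids))
        except ValueError as e:
            raise PipelineError("dswmp", str(e)) from e
        tops = {s: top_k(scored[s], dcfg.top_k) for s in scored}
        alluvial = cross_system_overlap(tops)
        dswmp_section = {
            "count_mode": dcfg.count_mode,
            "top_k": dcfg.top_k,
            "top_pathways": {
                s: [[p.pathway_id, p.pathway_name, round_half_up(p.score)]
                    for p in tops[s]]
                for s in sorted(tops)
            },
            "alluvial": [list(r) for r in alluvial.rows],
            "overlap_classes": alluvial.overlap_classes(),
        }

    return PipelineReport(
        config={
            "threshold_pkd": config.threshold_pkd,
            "comparator": config.comparator,
            "count_mode": config.count_mode,
            "top_k": config.top_k,
            "hub_min_degree": config.hub_min_degree,
            "seed": config.seed,
        },
        validation=validation,
        mei=mei_section,
        mti=mti_section,
        dswmp=dswmp_section,
        timestamp=timestamp,
        networks=networks,
    )


def export_network(net: BipartiteNetwork, stem: Path,
                   *, interaction: str = "interacts",
                   node_attrs: dict[str, dict[str, Any]] | None = None) -> list[Path]:
    """Write a network as SIF and GraphML next to ``stem``.

    SIF rows are ``left <interaction> right``; GraphML carries edge weights
    and any per-node attributes supplied (trend, functions, system class).
    """
    paths = []
    sif = stem.with_suffix(".sif")
    with open(sif, "w", encoding="utf-8") as fh:
        for l, r, _ in net.edges():
            fh.write(f"{l}\t{interaction}\t{r}\n")
    paths.append(sif)

    import networkx as nx

    g = net.to_networkx()
    for node, attrs in (node_attrs or {}).items():
        if node in g:
            g.nodes[node].update(attrs)
    gml = stem.with_suffix(".graphml")
    nx.write_graphml(g, gml)
    paths.append(gml)
    return paths


def write_report_artifacts(report: PipelineReport, bundle: StudyBundle,
                           out_dir: Path) -> None:
    """Write report.json plus TSV/SIF/GraphML artifacts for each stage."""
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json(), encoding="utf-8")

    def tsv(name: str, header: list[str], rows: list[list[Any]]) -> None:
        with open(out_dir / name, "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(c) for c in row) + "\n")

    if report.mei:
        tsv("mei_biomarker_degrees.tsv", ["id", "degree"],
            report.mei["biomarker_degrees"])
        tsv("mei_enzyme_degrees.tsv", ["id", "degree"],
            report.mei["enzyme_degrees"])
        tsv("mei_function_tally.tsv", ["function", "n_enzymes"],
            [list(r) for r in report.mei["function_tally"]])
        trends = {b.id: {"trend": b.trend} for b in bundle.biomarkers.values()}
        funs = {e.id: {"functions": ";".join(sorted(e.functions))}
                for e in bundle.enzymes.values()}
        export_network(report.networks["mei"], out_dir / "mei_network",
                       node_attrs={**trends, **funs})
    if report.mti:
        tsv("mti_summaries.tsv",
            ["system", "n_biomarkers", "n_targets", "n_edges",
             "mean_targets_per_biomarker", "mean_biomarkers_per_target"],
            [[s, d["n_left"], d["n_right"], d["n_edges"],
              d["mean_right_per_left"], d["mean_left_per_right"]]
             for s, d in report.mti["per_system"].items()])
        tsv("shared_targets.tsv", ["target_id"],
            [[t] for t in report.mti["shared_targets"]])
        n_sys = {t.id: {"n_systems": len(t.systems)}
                 for t in bundle.targets.values()}
        for system in SYSTEMS:
            net = report.networks.get(f"mti_{system}")
            if net is not None and net.n_edges:
                export_network(net, out_dir / f"mti_{system}",
                               node_attrs=n_sys)
    if report.dswmp:
        for system, rows in report.dswmp["top_pathways"].items():
            tsv(f"dswmp_top_{system}.tsv",
                ["pathway_id", "pathway_name", "DSWMP"], rows)
        tsv("dswmp_alluvial.tsv", ["system", "pathway_id", "score"],
            report.dswmp["alluvial"])
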