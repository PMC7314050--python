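"""Run orchestration: configuration, the end-to-end pipeline, and exports.

``run_pipeline`` executes load -> QC -> similarity -> soft-threshold scan ->
TOM -> clustering -> dynamic cut -> eigengenes -> merge -> colors ->
stability -> hubs -> associations -> TF ranking -> hub annotation, writing
every intermediate table as TSV plus a JSON run summary.  All randomness
flows from one master seed recorded in the summary, and every output is
stamped with a hash of the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import downstream, modules, network, stability
from .correlation import similarity_matrix
from .downstream import GeneList, load_annotation_map, load_gene_list
from .expression import ExpressionMatrix, batch_diagnostics, load_expression, qc_filter
from .modules import ModulePartition
from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "export_cytoscape_edges", "export_module_graphml",
           "save_matrix", "load_matrix"]


@dataclass
class RunConfig:
    """Fully resolved settings for one pipeline run."""

    expression_path: str = ""
    manifest_path: str | None = None
    gene_list_paths: tuple[str, ...] = ()
    tf_list_path: str | None = None
    annotation_path: str | None = None
    output_dir: str = "coexnet_run"

    correlation: str = "bicor"
    max_missing_frac: float = 0.5
    impute: bool = True
    beta: int | None = None
    beta_grid_max: int = 20
    r2_target: float = 0.9
    min_module_size: int = 20
    deep_split: int = 2
    pam_stage: bool = True
    merge_height: float = 0.2
    stability_fraction: float = 0.5
    stability_resamples: int = 1000
    stability_threshold: float = 0.7
    kme_min: float = 0.8
    tom_neighbor_min: float = 0.01
    alpha: float = 0.05
    edge_weight_min: float = 0.01
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, default=str), encoding="utf-8"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in fields}
        for key in ("gene_list_paths",):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def save_matrix(path: str | Path, mat: np.ndarray, gene_ids: list[str], meta: dict | None = None) -> None:
    """Persist a gene x gene matrix as .npy with a JSON sidecar (gene order
    plus free-form metadata)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), mat)
    sidecar = {"gene_ids": gene_ids, **(meta or {})}
    path.with_suffix(".json").write_text(json.dumps(sidecar), encoding="utf-8")


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    mat = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    return mat, meta


def export_cytoscape_edges(
    net: GeneNetwork,
    partition: ModulePartition,
    weight_min: float = 0.01,
    annotation_map: dict[str, set[str]] | None = None,
    edge_path: str | Path = "edges.tsv",
    node_path: str | Path = "nodes.tsv",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write Cytoscape-style edge and node files thresholded on TOM.

    The edge file has one row per unordered gene pair with TOM >= weight_min
    (columns fromNode, toNode, weight, direction, fromAltName, toAltName);
    the node file carries each gene's alt name and module color.
    """
    if not 0 <= weight_min < 1:
        raise ValueError("weight_min must be in [0, 1)")
    def alt(g: str) -> str:
        if annotation_map and annotation_map.get(g):
            return sorted(annotation_map[g])[0]
        return "NA"

    genes = net.gene_ids
    tom = net.tom
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if tom[i, j] >= weight_min:
                rows.append(
                    {
                        "fromNode": genes[i],
                        "toNode": genes[j],
                        "weight": repr(float(tom[i, j])),
                        "direction": "undirected",
                        "fromAltName": alt(genes[i]),
                        "toAltName": alt(genes[j]),
                    }
                )
    edges = pd.DataFrame(
        rows, columns=["fromNode", "toNode", "weight", "direction", "fromAltName", "toAltName"]
    )
    colors = {g: partition.color_of(l) for g, l in zip(partition.gene_ids, partition.labels)}
    nodes = pd.DataFrame(
        {
            "nodeName": genes,
            "altName": [alt(g) for g in genes],
            "moduleColor": [colors.get(g, "grey") for g in genes],
        }
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)
    return edges, nodes


def export_module_graphml(graph, path: str | Path) -> None:
    """Write the inter-module graph (eigengene correlations) as GraphML."""
    import networkx as nx

    g = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    nx.write_graphml(g, path)


def run_pipeline(config: RunConfig, expression: ExpressionMatrix | None = None) -> dict:
    """Execute the full analysis and write all artifacts to the output dir.

    ``expression`` may be passed directly (e.g. a synthetic matrix); else it
    is loaded from ``config.expression_path``.  Returns the run summary
    (also written as run_summary.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("coexnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    cfg_hash = config.config_hash()
    config.to_file(out / "resolved_config.json")
    summary: dict = {"config_hash": cfg_hash, "seed": config.seed, "warnings": []}
    stage = "load"
    try:
        if expression is None:
            expression = load_expression(config.expression_path, config.manifest_path)
        logger.info("loaded %d genes x %d samples", expression.n_genes, expression.n_samples)

        stage = "qc"
        filtered, report = qc_filter(expression, config.max_missing_frac, config.impute)
        report.to_csv(out / "qc_removals.tsv", sep="\t", index=False)
        diag = batch_diagnostics(filtered)
        diag.write(out / "batch_summaries.tsv", out / "mds_coordinates.tsv")
        summary["n_genes"] = filtered.n_genes
        summary["n_samples"] = filtered.n_samples
        summary["n_genes_removed"] = len(report)

        stage = "similarity"
        sim = similarity_matrix(filtered, method=config.correlation)

        stage = "soft_threshold"
        net = network.build_network(
            sim,
            beta=config.beta,
            beta_grid=range(1, config.beta_grid_max + 1),
            r2_target=config.r2_target,
        )
        net.scan.to_tsv(out / "soft_threshold_scan.tsv")
        save_matrix(out / "tom", net.tom, net.gene_ids,
                    {"beta": net.beta, "method": config.correlation})
        summary["beta"] = net.beta
        summary["r2_target_reached"] = bool(net.scan.target_reached)
        if not net.scan.target_reached:
            summary["warnings"].append("soft-threshold target not reached; argmax-R2 beta used")

        stage = "clustering"
        dend = modules.cluster_genes(net.dissimilarity, gene_ids=net.gene_ids)
        part_pre = modules.cut_dynamic(
            dend,
            net.dissimilarity,
            min_cluster_size=config.min_module_size,
            deep_split=config.deep_split,
            pam_stage=config.pam_stage,
        )
        summary["n_modules_premerge"] = part_pre.n_modules

        stage = "eigengenes"
        me_pre = modules.module_eigengenes(filtered, part_pre)
        part, me = modules.merge_modules(filtered, part_pre, me_pre, cut_height=config.merge_height)
        part = modules.assign_colors(part)
        part.to_frame().to_csv(out / "module_partition.tsv", sep="\t", index=False)
        me.to_tsv(out / "module_eigengenes.tsv")
        summary["n_modules"] = part.n_modules
        summary["module_sizes"] = {part.color_of(l): s for l, s in part.module_sizes.items()}

        if part.n_modules >= 2:
            graph = modules.module_graph(me, edge_threshold=0.0, sizes=part.module_sizes)
            export_module_graphml(graph, out / "module_graph.graphml")
            pd.DataFrame(
                [
                    {"module1": part.color_of(u), "module2": part.color_of(v), "weight": d["weight"]}
                    for u, v, d in graph.edges(data=True)
                ]
            ).to_csv(out / "module_graph_edges.tsv", sep="\t", index=False)

        stage = "stability"
        stab = stability.resample_connectivity_stability(
            filtered,
            part,
            beta=net.beta,
            n_resamples=config.stability_resamples,
            fraction=config.stability_fraction,
            threshold=config.stability_threshold,
            seed=config.seed,
            method=config.correlation,
        )
        stab.to_tsv(out / "module_stability.tsv")
        summary["stable_modules"] = {
            r["color"]: bool(r["stable"]) for _, r in stab.table.iterrows()
        }

        stage = "hubs"
        conn = downstream.intramodular_connectivity(net, part, filtered, me)
        conn.to_csv(out / "connectivity.tsv", sep="\t")
        hubs = downstream.select_hubs(conn, part, kme_min=config.kme_min)
        hubs.to_csv(out / "hubs.tsv", sep="\t")
        summary["hubs"] = {row["color"]: row["hub"] for _, row in hubs.reset_index().iterrows()}

        stage = "associations"
        universe = list(filtered.gene_ids)
        assoc_frames = []
        for glp in config.gene_list_paths:
            gl = load_gene_list(glp)
            assoc_frames.append(
                downstream.module_set_association(part, gl, universe, alpha=config.alpha)
            )
        if assoc_frames:
            assoc = pd.concat(assoc_frames, ignore_index=True)
            assoc.to_csv(out / "module_associations.tsv", sep="\t", index=False)
            summary["significant_associations"] = int(assoc["significant"].sum())

        stage = "tfs"
        if config.tf_list_path:
            tfs = load_gene_list(config.tf_list_path).members
            ranking, unmapped = downstream.rank_tfs(filtered, tfs, part, hubs)
            ranking.to_csv(out / "tf_ranking.tsv", sep="\t", index=False)
            summary["n_tfs_ranked"] = len(ranking)
            summary["n_tfs_unmapped"] = len(unmapped)

        stage = "annotations"
        if config.annotation_path:
            ann = load_annotation_map(config.annotation_path)
            records = []
            for _, row in hubs.reset_index().iterrows():
                ha = downstream.annotate_hypothetical_hub(
                    row["hub"], net, ann, universe,
                    tom_min=config.tom_neighbor_min, alpha=config.alpha,
                )
                records.append(
                    {
                        "module": row["module"],
                        "color": row["color"],
                        "hub": ha.hub,
                        "n_neighbors": len(ha.neighbors),
                        "top_term": ha.top_term,
                    }
                )
            pd.DataFrame(records).to_csv(out / "hub_annotations.tsv", sep="\t", index=False)

        stage = "export"
        export_cytoscape_edges(
            net, part, weight_min=config.edge_weight_min,
            edge_path=out / "cytoscape_edges.tsv", node_path=out / "cytoscape_nodes.tsv",
        )
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} (config hash {cfg_hash}): {err}"
        ) from err
    finally:
        root.removeHandler(handler)
        handler.close()

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
    )
    return summary
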