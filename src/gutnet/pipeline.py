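"""End-to-end orchestration: simulate -> profile -> networks -> bootstrap ->
differential features -> multi-omics -> community comparison.

:func:`run_pipeline` executes the stages in order, writes every artifact as
TSV/GraphML under the output directory, and finishes with a ``manifest.json``
listing each artifact with its SHA-256 content hash.  All randomness derives
from a single seed split per stage, so rerunning with the same configuration
reproduces identical hashes.  Stage failures abort with the stage name and a
machine-readable error code.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import community, differential, multiomics, profiles
from .containers import CountTable, GutnetError, OmicsBlock
from .corrnet import graph_to_edge_frame
from .model import MicrobiomeNetworkModel
from .simulate import SyntheticConfig, generate_counts, generate_pathways, generate_phenotypes

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(GutnetError):
    """A stage failed; carries the stage name and a short error code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    Either ``synthetic`` (a :class:`SyntheticConfig`) or the three input
    paths must be given.  ``k_clusters=None`` means the eigengap heuristic.
    """

    outdir: str | Path = "gutnet_out"
    synthetic: SyntheticConfig | None = None
    counts_path: str | Path | None = None
    metadata_path: str | Path | None = None
    block_paths: dict[str, str] = field(default_factory=dict)  # tag -> TSV path
    alpha_edge: float = 0.05
    alpha_by: float = 0.05
    diff_alpha: float = 0.05
    B: int = 1000
    n_perm: int = 999
    k_clusters: int | None = None
    top_k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_edge", "alpha_by", "diff_alpha"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise GutnetError(f"{name} must be in (0, 1), got {a}")
        if self.B < 1 or self.n_perm < 1:
            raise GutnetError("B and n_perm must be >= 1")
        if self.synthetic is None and (self.counts_path is None or self.metadata_path is None):
            raise GutnetError("provide either a synthetic config or counts+metadata paths")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    artifacts: list[Path] = []

    def emit(frame: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        path = outdir / name
        if index_label is None and isinstance(frame.index, pd.RangeIndex):
            frame.to_csv(path, sep="\t", index=False)
        else:
            frame.to_csv(path, sep="\t", index_label=index_label)
        artifacts.append(path)

    def record(stage: str, message: str) -> None:
        log.append(f"{stage}: {message}")
        logger.info("%s: %s", stage, message)

    # -- stage 1: inputs -----------------------------------------------------
    stage = "input"
    try:
        if config.synthetic is not None:
            table = generate_counts(config.synthetic)
            phenotypes = (
                generate_phenotypes(config.synthetic, table)
                if config.synthetic.phenotype_spec
                else None
            )
            pathways = (
                generate_pathways(config.synthetic, table)
                if config.synthetic.n_pathways > 0
                else None
            )
            table.to_tsv(outdir / "counts.tsv", outdir / "metadata.tsv")
            artifacts += [outdir / "counts.tsv", outdir / "metadata.tsv"]
            for block, name in ((phenotypes, "phenotypes.tsv"), (pathways, "pathways.tsv")):
                if block is not None:
                    block.to_tsv(outdir / name)
                    artifacts.append(outdir / name)
            record(stage, f"simulated {table.n_samples} samples x {table.n_taxa} taxa "
                          f"(seed={config.synthetic.seed})")
        else:
            table = CountTable.read_tsv(config.counts_path, config.metadata_path)
            phenotypes = pathways = None
            record(stage, f"loaded {table.n_samples} samples x {table.n_taxa} taxa")
        blocks: dict[str, OmicsBlock] = {}
        for tag, path in config.block_paths.items():
            blocks[tag] = OmicsBlock.read_tsv(path, tag)
        if phenotypes is not None:
            # blood pressure is its own modality in the integration network
            values = phenotypes.values
            if "blood_pressure" in values.columns:
                blocks["blood_pressure"] = OmicsBlock(values[["blood_pressure"]], "blood_pressure")
                values = values.drop(columns="blood_pressure")
            if values.shape[1]:
                blocks["phenotype"] = OmicsBlock(values, "phenotype")
        if pathways is not None:
            blocks["pathway"] = pathways
    except GutnetError as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, "bad_input", str(exc)) from exc

    n_groups = len(table.group_names)

    # -- stage 2: abundance profiles ----------------------------------------
    stage = "profile"
    try:
        div = profiles.diversity(table)
        emit(div.to_frame(), "diversity.tsv", index_label="sample_id")
        emit(profiles.top_k_taxa(table, config.top_k), "top_taxa.tsv", index_label="group")
        record(stage, f"diversity + top-{config.top_k} summary written")
    except GutnetError as exc:
        raise PipelineError(stage, "profile_failed", str(exc)) from exc

    # -- stage 3: per-group networks + bootstrap + comparison ---------------
    stage = "network"
    try:
        model = MicrobiomeNetworkModel(table, alpha=config.alpha_edge)
        fit = model.fit(n_boot=config.B, seed=config.seed, k_clusters=config.k_clusters)
        emit(pd.concat({p: fit.bootstrap_frame(p) for p in fit.summaries.columns}, axis=1),
             "bootstrap_replicates.tsv")
        for group in fit.group_names:
            emit(graph_to_edge_frame(fit.graphs[group]), f"network_{group}_edges.tsv")
            emit(fit.clusters[group].to_frame(), f"network_{group}_clusters.tsv",
                 index_label="node")
        emit(fit.summaries, "network_summaries.tsv", index_label="group")
        if fit.comparisons:
            emit(fit.comparison_table(), "network_comparisons.tsv")
            record(stage, f"networks + B={config.B} bootstrap + ANOVA/Tukey written")
        else:
            record(stage, "single group: between-group network comparison skipped")
    except GutnetError as exc:
        raise PipelineError(stage, "network_failed", str(exc)) from exc

    # -- stage 4: differential features --------------------------------------
    stage = "differential"
    selected: list[str] = []
    try:
        if n_groups >= 2:
            diff = differential.select_differential(table, alpha=config.diff_alpha)
            emit(diff, "differential_features.tsv", index_label="feature")
            selected = list(diff.index[diff["selected"]])
            record(stage, f"{len(selected)} feature(s) selected at "
                          f"adjusted p < {config.diff_alpha}")
            if len(selected) >= 2:
                rel = profiles.relative_abundance(table)
                scores, explained = differential.pc_projection(rel[selected])
                scores["group"] = table.groups
                emit(scores, "pc_scores.tsv", index_label="sample_id")
                record(stage, "PC projection explained variance: "
                              f"{explained[0]:.3f}, {explained[1]:.3f}")
        else:
            record(stage, "single group: differential selection skipped")
    except GutnetError as exc:
        raise PipelineError(stage, "differential_failed", str(exc)) from exc

    # -- stage 5: multi-omics network ----------------------------------------
    stage = "multiomics"
    try:
        if blocks:
            rel = profiles.relative_abundance(table)
            genus_features = selected if len(selected) >= 2 else list(
                rel.var(axis=0).sort_values(ascending=False).index[:10]
            )
            genus_block = OmicsBlock(rel[genus_features], "genus")
            graph = multiomics.multiomic_graph(
                [genus_block, *blocks.values()], alpha=config.alpha_by
            )
            frame = graph_to_edge_frame(graph)
            adj = nx.get_edge_attributes(graph, "p_adjusted")
            frame["p_adjusted"] = [
                adj.get((a, b), adj.get((b, a)))
                for a, b in zip(frame.node_i, frame.node_j)
            ]
            emit(frame, "multiomics_edges.tsv")
            path = outdir / "multiomics.graphml"
            nx.write_graphml(graph, path)
            artifacts.append(path)
            record(stage, f"multi-omic network: {graph.number_of_nodes()} nodes, "
                          f"{graph.number_of_edges()} BY-retained edges")
        else:
            record(stage, "no omics blocks provided: multi-omics network skipped")
    except GutnetError as exc:
        raise PipelineError(stage, "multiomics_failed", str(exc)) from exc

    # -- stage 6: community-level comparison ---------------------------------
    stage = "community"
    try:
        dist = community.bray_curtis(table)
        emit(dist, "bray_curtis.tsv", index_label="sample_id")
        if n_groups >= 2:
            res = community.permanova(dist, table.groups, n_perm=config.n_perm,
                                      seed=config.seed)
            emit(pd.DataFrame([res.to_dict()]), "permanova.tsv")
            pairwise = community.pairwise_adonis(dist, table.groups,
                                                 n_perm=config.n_perm, seed=config.seed)
            emit(pairwise, "pairwise_adonis.tsv")
            record(stage, f"PERMANOVA pseudo-F={res.pseudo_F:.3f} R2={res.R2:.3f} "
                          f"p={res.p:.4f}")
        else:
            record(stage, "single group: PERMANOVA skipped")
    except GutnetError as exc:
        raise PipelineError(stage, "community_failed", str(exc)) from exc

    # -- manifest -------------------------------------------------------------
    unique = sorted(set(artifacts))
    manifest = {
        "artifacts": {p.name: _sha256(p) for p in unique},
        "log": log,
        "parameters": {
            "alpha_edge": config.alpha_edge,
            "alpha_by": config.alpha_by,
            "diff_alpha": config.diff_alpha,
            "B": config.B,
            "n_perm": config.n_perm,
            "k_clusters": config.k_clusters,
            "top_k": config.top_k,
            "seed": config.seed,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return manifest
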