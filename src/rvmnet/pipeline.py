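"""End-to-end orchestration: DE -> enrichment (GO and pathway separately)
-> term networks -> Signal-Net -> centrality ranking, with a JSON manifest
recording the config, input checksums and per-stage counts."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, diffexpr, enrichment, io, networks
from .errors import InvalidConfigError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one reproducible run."""

    expression: str = ""
    design: str = ""
    gene_sets: str = ""
    edges: str = ""
    term_relations: str = ""
    out_dir: str = "results"
    alpha_de: float = 0.05
    alpha_enrich: float = 0.05
    betweenness_mode: str = "directed"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_enrich"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidConfigError(f"{name} must be in (0, 1], got {v}")
        if self.betweenness_mode not in ("directed", "undirected"):
            raise InvalidConfigError(f"bad betweenness_mode {self.betweenness_mode!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class RunManifest:
    """Config snapshot, input checksums, per-stage record counts, version."""

    config: dict
    input_checksums: dict[str, str]
    counts: dict[str, int]
    version: str = __version__

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage, writing one TSV per stage plus manifest.json.

    Any stage failure aborts with :class:`PipelineError` naming the stage;
    files written by the aborted run are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(writer, obj, name: str) -> Path:
        path = out / name
        writer(obj, path)
        written.append(path)
        return path

    stage = "read-inputs"
    try:
        matrix = io.read_expression(config.expression, config.design)
        collection = io.read_gmt(config.gene_sets, universe=matrix.gene_ids)
        edge_list = io.read_edges(config.edges) if config.edges else None
        relations = io.read_term_relations(config.term_relations) if config.term_relations else []

        stage = "diffexpr"
        records, de_list, prior = diffexpr.run_de(matrix, alpha=config.alpha_de)
        emit(io.write_table, records, "de_all.tsv")
        emit(io.write_table, de_list.selected, "de_selected.tsv")

        stage = "enrichment"
        up, down = de_list.genes("up"), de_list.genes("down")
        enr = {}
        for category in enrichment.CATEGORIES:
            sub = collection.of_category(category).restricted(matrix.gene_ids)
            enr[category] = enrichment.run_enrichment(sub, up, down, alpha=config.alpha_enrich)
            emit(io.write_table, enr[category], f"enrichment_{category}.tsv")

        stage = "term-network"
        term_counts = {}
        for category in enrichment.CATEGORIES:
            tg = networks.build_term_network(enr[category], relations)
            emit(io.export_graphml, tg, f"termnet_{category}.graphml")
            emit(io.export_dot, tg, f"termnet_{category}.dot")
            term_counts[category] = tg.graph.number_of_nodes()

        stage = "signal-net"
        if edge_list is None:
            raise PipelineError("no interaction edge file configured")
        net = networks.build_signal_net(edge_list, de_list)
        emit(io.export_graphml, net, "signalnet.graphml")
        emit(io.export_dot, net, "signalnet.dot")

        stage = "centrality"
        core = networks.rank_core_genes(net, mode=config.betweenness_mode)
        emit(io.write_table, core, "core_genes.tsv")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    checksums = {
        name: _sha256(getattr(config, name))
        for name in ("expression", "design", "gene_sets", "edges", "term_relations")
        if getattr(config, name)
    }
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_checksums=checksums,
        counts={
            "genes_tested": len(records),
            "de_up": de_list.n_up,
            "de_down": de_list.n_down,
            "significant_terms_up": int(sum(
                ((df["direction_class"] == "up") & df["significant"]).sum()
                for df in enr.values() if len(df)
            )),
            "significant_terms_down": int(sum(
                ((df["direction_class"] == "down") & df["significant"]).sum()
                for df in enr.values() if len(df)
            )),
            "termnet_nodes_GO": term_counts["GO"],
            "termnet_nodes_pathway": term_counts["pathway"],
            "network_nodes": net.n,
            "network_edges": net.graph.number_of_edges(),
        },
    )
    manifest.to_json(out / "manifest.json")
    return manifest
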