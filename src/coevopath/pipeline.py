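"""End-to-end orchestration: alignment + structures + tables -> ranked pathways.

The stages run in a fixed order — sequence space, co-evolution, structure
dynamics, graph analysis, pathway semantics — and communicate only
through the documented on-disk formats, so each stage can be re-run
standalone on the persisted intermediates.  A JSON manifest records
parameters, input checksums and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignment import (
    DISORDER_THRESHOLD_BITS,
    build_consensus,
    classify_order,
    entropy_report,
    read_alignment,
    sequence_entropy,
)
from .dca import build_dca_network, dca_pipeline
from .graphs import Mutation, betweenness, compare_partitions, extract_stretch, girvan_newman
from .netio import read_edge_list, write_network, write_partition, write_series
from .semantics import (
    PPITable,
    PathwayCatalog,
    build_semantic_graph,
    filter_partners,
    filter_pathways,
    load_go_graph,
    pagerank,
)
from .structure import (
    InteractionParams,
    ensemble_similarity,
    gnm_correlation_network,
    hydropathy_profile,
    interaction_network,
    read_structure,
    rmsf,
)

__all__ = ["RunConfig", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)

STAGES = (
    "sequence_space",
    "coevolution",
    "structure_dynamics",
    "graph_analysis",
    "pathway_semantics",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run.

    The numeric defaults are the frame's canonical settings: disorder
    threshold 2.9 bits, DCA pseudocount 0.5 and identity cutoff 0.8,
    interaction-strength threshold E_c = 4%, GNM correlation threshold
    0.7, PPI cutoff 0.5 with top 11 partners, working stretch 40-95 and
    pathway filter of >= 2 members including the query protein.
    """

    alignment: str = ""
    alignment_format: str = "fasta"
    structure: str = ""
    ppi_table: str = ""
    pathway_table: str = ""
    annotation_table: str = ""
    ontology_table: str = ""
    outdir: str = "results"
    seed: int = 0
    query_protein: str = "SNCA"
    mutations: list[str] = field(default_factory=list)
    entropy_threshold: float = DISORDER_THRESHOLD_BITS
    identity_cutoff: float = 0.8
    pseudocount: float = 0.5
    dca_top_k: int = 100
    e_c: float = 4.0
    contact_distance: float = 4.5
    gnm_cutoff: float = 7.3
    corr_threshold: float = 0.7
    ppi_cutoff: float = 0.5
    ppi_top_n: int = 11
    stretch_start: int = 40
    stretch_end: int = 95
    hydropathy_window: int = 9
    min_members: int = 2
    ontology: str = "BP"
    strong_quantile: float = 0.75
    damping: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("alignment", "structure", "ppi_table", "pathway_table",
                    "annotation_table", "ontology_table"):
            path = getattr(self, key)
            if not path:
                raise ValueError(f"config field {key!r} is required")
            if not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path}")
        if not 0.0 <= self.ppi_cutoff <= 1.0:
            raise ValueError("ppi_cutoff must lie in [0, 1]")
        if self.stretch_start > self.stretch_end:
            raise ValueError("stretch_start must be <= stretch_end")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in order and return (and persist) the run manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {
            key: {"path": getattr(cfg, key), "sha256": _sha256(getattr(cfg, key))}
            for key in ("alignment", "structure", "ppi_table", "pathway_table",
                        "annotation_table", "ontology_table")
        },
        "stages": {},
    }
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            summary = _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise PipelineError(stage, exc) from exc
        summary["status"] = "complete"
        summary["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = summary
        logger.info("stage %s complete in %.2fs", stage, summary["seconds"])
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_sequence_space(cfg: RunConfig, out: Path) -> dict:
    fam = read_alignment(cfg.alignment, cfg.alignment_format)
    report = entropy_report(fam, threshold=cfg.entropy_threshold)
    report.to_csv(out / "entropy.tsv", sep="\t", index=False)
    cons = build_consensus(fam)
    (out / "consensus.txt").write_text(cons.consensus + "\n")
    h = sequence_entropy(cons.consensus)
    return {
        "n_sequences": fam.n_sequences,
        "n_columns": fam.length,
        "consensus_entropy_bits": round(h, 4),
        "consensus_class": classify_order(h, cfg.entropy_threshold),
    }


def _stage_coevolution(cfg: RunConfig, out: Path) -> dict:
    fam = read_alignment(cfg.alignment, cfg.alignment_format)
    model, di = dca_pipeline(
        fam, identity_cutoff=cfg.identity_cutoff, pseudocount=cfg.pseudocount
    )
    di.write_tsv(out / "di.tsv")
    g_dca = build_dca_network(di, top_k=cfg.dca_top_k)
    write_network(g_dca, out / "g_dca")
    partition = girvan_newman(g_dca) if g_dca.number_of_edges() else None
    if partition is not None:
        write_partition(partition, out / "dca_communities.tsv")
    return {
        "m_eff": round(model.m_eff, 3),
        "n_edges": g_dca.number_of_edges(),
        "n_communities": len(partition.communities) if partition else 0,
        "modularity": round(partition.modularity, 4) if partition else None,
    }


def _stage_structure_dynamics(cfg: RunConfig, out: Path) -> dict:
    ens = read_structure(cfg.structure)
    profile = rmsf(ens)
    profile.to_frame().to_csv(out / "rmsf.tsv", sep="\t", index=False)
    params = InteractionParams(e_c=cfg.e_c, contact_distance=cfg.contact_distance)
    g_int = interaction_network(ens, params=params)
    write_network(g_int, out / "g_interaction")
    g_nma = gnm_correlation_network(
        ens, cutoff=cfg.gnm_cutoff, corr_threshold=cfg.corr_threshold
    )
    write_network(g_nma, out / "g_nma")
    summary: dict = {
        "n_models": ens.n_models,
        "n_residues": ens.n_residues,
        "interaction_edges": g_int.number_of_edges(),
        "nma_edges": g_nma.number_of_edges(),
    }
    if ens.n_models >= 2:
        _, representative = ensemble_similarity(ens, cutoff=cfg.gnm_cutoff)
        summary["representative_model"] = representative
    seq = ens.sequence
    end = min(cfg.stretch_end, len(seq))
    if cfg.stretch_start <= end:
        hydro = hydropathy_profile(
            seq, start=cfg.stretch_start, end=end, window=cfg.hydropathy_window
        )
        hydro.to_csv(out / "hydropathy.tsv", sep="\t")
    return summary


def _stage_graph_analysis(cfg: RunConfig, out: Path) -> dict:
    g_dca = read_edge_list(out / "g_dca.tsv", provenance="dca")
    g_nma = read_edge_list(out / "g_nma.tsv", provenance="nma")
    summary: dict = {}
    p_nma = girvan_newman(g_nma) if g_nma.number_of_edges() else None
    if p_nma is not None:
        write_partition(p_nma, out / "nma_communities.tsv")
        summary["nma_communities"] = len(p_nma.communities)
    target = g_nma if g_nma.number_of_edges() else g_dca
    if target.number_of_nodes():
        write_series(betweenness(target), out / "betweenness.tsv", "betweenness")
    else:
        write_series({}, out / "betweenness.tsv", "betweenness")
    ens = read_structure(cfg.structure)
    seq = ens.sequence
    muts = [Mutation.parse(m) for m in cfg.mutations]
    if muts and p_nma is not None and g_dca.number_of_edges():
        p_dca = girvan_newman(g_dca)
        anchor = muts[0].position
        # DCA columns are 0-based alignment columns; map to residue numbering
        dca_nodes = {int(n) + 1 for n in p_dca.node_set}
        if anchor in dca_nodes and anchor in p_nma.node_set:
            relabeled = type(p_dca)(
                communities=tuple(
                    frozenset(int(n) + 1 for n in c) for c in p_dca.communities
                ),
                modularity=p_dca.modularity,
                provenance=p_dca.provenance,
            )
            shared, jaccard = compare_partitions(
                relabeled, p_nma, anchor, (cfg.stretch_start, cfg.stretch_end)
            )
            summary["shared_residues"] = sorted(shared)
            summary["jaccard"] = round(jaccard, 4)
    end = min(cfg.stretch_end, len(seq))
    rec = extract_stretch(
        seq, start=cfg.stretch_start, end=end, mutations=muts, seq_id="stretch"
    )
    with open(out / "stretch.fasta", "w") as fh:
        fh.write(f">{rec.id} {rec.description}\n{rec.seq}\n")
    summary["stretch_length"] = len(rec.seq)
    return summary


def _stage_pathway_semantics(cfg: RunConfig, out: Path) -> dict:
    ppi = PPITable.from_tsv(cfg.ppi_table, query=cfg.query_protein)
    kept = filter_partners(ppi, cutoff=cfg.ppi_cutoff, top_n=cfg.ppi_top_n)
    kept.write_tsv(out / "ppi_filtered.tsv")
    cat = PathwayCatalog.from_tsv(cfg.pathway_table)
    cat_kept = filter_pathways(cat, required=cfg.query_protein, min_members=cfg.min_members)
    cat_kept.write_tsv(out / "pathways_filtered.tsv")
    go = load_go_graph(cfg.ontology_table)
    annotations = pd.read_csv(cfg.annotation_table, sep="\t")
    g_sem = build_semantic_graph(
        cat_kept, annotations, go,
        ontology=cfg.ontology, strong_quantile=cfg.strong_quantile,
    )
    write_network(g_sem, out / "g_semantic")
    ranks = pagerank(g_sem, damping=cfg.damping)
    write_series(ranks, out / "pagerank.tsv", "pagerank")
    return {
        "partners_retained": len(kept.table),
        "pathways_retained": len(cat_kept.members),
        "semantic_edges": g_sem.number_of_edges(),
        "top_pathway": str(ranks.index[0]),
        "top_pagerank": round(float(ranks.iloc[0]), 4),
    }


_STAGE_FUNCS = {
    "sequence_space": _stage_sequence_space,
    "coevolution": _stage_coevolution,
    "structure_dynamics": _stage_structure_dynamics,
    "graph_analysis": _stage_graph_analysis,
    "pathway_semantics": _stage_pathway_semantics,
}
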