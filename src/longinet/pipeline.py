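"""End-to-end pipeline: curation -> network -> inference -> scoring.

Stages run in order with structured per-stage logging and intermediate
artifacts written to the output directory, so a rerun with the same
configuration and seed reproduces every file byte-for-byte. The
``use_predictions`` toggle reproduces the experimental-only condition
(score the experimental network alone) against the full
experimental-plus-computational condition.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as lio
from .catalog import (
    build_catalog,
    filter_by_organism_support,
    map_to_human_orthologs,
    pool_aag_sets,
)
from .inference import InferenceParams, predict_dti_network
from .network import (
    DTINetwork,
    annotate_aap_targets,
    build_network,
    dedup_compounds,
    filter_activity_records,
    merge_networks,
    network_stats,
)
from .scoring import PermutationConfig, prioritize_indications

log = logging.getLogger("longinet.pipeline")


@dataclass
class PipelineConfig:
    """Paths, parameters and stage toggles for a full run."""

    gene_lists: str
    ortholog_table: str
    activity_records: str
    profiles: str
    target_gene_map: str | None = None
    output_dir: str = "longinet_out"
    seed: int = 0
    min_organisms: int = 2
    activity_threshold_um: float = 10.0
    organism: str = "Homo sapiens"
    inference: InferenceParams = field(default_factory=InferenceParams)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    use_predictions: bool = True  # False = experimental-network-only condition

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        inference = InferenceParams(**raw.pop("inference", {}))
        perm = PermutationConfig(**raw.pop("permutation", {}))
        cfg = cls(inference=inference, permutation=perm, **raw)
        return cfg


@dataclass
class RunReport:
    """Per-stage counts and provenance of one pipeline run."""

    config: dict
    counts: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def validate(self) -> None:
        c = self.counts
        if c.get("records_kept", 0) + c.get("records_rejected", 0) != c.get(
            "records_input", 0
        ):
            raise AssertionError("kept + rejected != input records")
        if c.get("drugs_significant", 0) > c.get("drugs_scored", 0):
            raise AssertionError("significant > scored")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "counts": self.counts,
            "wall_clock_s": self.wall_clock_s,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _load_target_gene_map(path: str | None) -> dict[str, str]:
    if path is None:
        return {}
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        acc, gene = line.split("\t")[:2]
        out[acc] = gene
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute curation, filtering, network building, inference and scoring.

    Writes ``catalog.tsv``, ``rejection_log.tsv``, ``network_edges.tsv``,
    ``network.graphml``, ``predictions.tsv``, ``indications.tsv`` and
    ``report.json`` under the configured output directory.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # stage A: curation
    lists = lio.read_gene_lists(config.gene_lists)
    table = lio.read_ortholog_table(config.ortholog_table)
    human = next((gl for gl in lists if gl.organism == "HS"), None)
    orth_sets = {
        gl.organism: map_to_human_orthologs(gl, table)
        for gl in lists
        if gl.organism != "HS"
    }
    catalog = build_catalog(human.genes if human else (), orth_sets)
    cross = filter_by_organism_support(catalog, config.min_organisms)
    aap = pool_aag_sets(cross, human.genes if human else set())
    lio.write_catalog(catalog, outdir / "catalog.tsv")
    counts.update(
        genes_catalogued=len(catalog),
        genes_cross_organism=len(cross),
        genes_aap=len(aap),
    )
    log.info("curation: %(genes_catalogued)d genes, %(genes_aap)d AAPs", counts)

    # stage B: activity filtering and experimental network
    records = lio.read_activity_records(config.activity_records)
    kept, rejections = filter_activity_records(
        records, config.activity_threshold_um, config.organism
    )
    rejections.to_csv(outdir / "rejection_log.tsv", sep="\t", index=False)
    compounds = dedup_compounds(kept)
    target_genes = _load_target_gene_map(config.target_gene_map)
    exp_net = build_network(
        [(r.compound_id, r.uniprot, r.activity_value_um) for r in kept],
        "experimental",
        target_genes,
    )
    counts.update(
        records_input=len(records),
        records_kept=len(kept),
        records_rejected=len(rejections),
        compounds_unique=len(compounds),
        edges_experimental=exp_net.n_edges,
    )
    log.info("network: %(records_kept)d/%(records_input)d records kept", counts)

    # stage C: substructure-based target inference
    profiles = lio.read_profiles(config.profiles)
    net: DTINetwork = exp_net
    n_pred = 0
    if config.use_predictions:
        predictions = predict_dti_network(exp_net, profiles, config.inference)
        predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        pred_net = build_network(
            list(zip(predictions["drug"], predictions["target"])),
            "predicted",
            target_genes,
        )
        net = merge_networks(exp_net, pred_net)
        n_pred = len(predictions)
    counts.update(edges_predicted=n_pred, edges_total=net.n_edges)

    net, n_at = annotate_aap_targets(net, aap, target_genes)
    stats = network_stats(net)
    counts.update(
        drugs=stats.n_drugs,
        targets=stats.n_targets,
        aap_targets=n_at,
        sparsity_pct=stats.sparsity_pct_2dp,
    )
    lio.write_edge_tsv(net, outdir / "network_edges.tsv")
    lio.write_graphml(net, outdir / "network.graphml")

    # stage D: indication scoring
    perm = config.permutation
    if perm.seed != config.seed:
        from dataclasses import replace

        perm = replace(perm, seed=config.seed)
    drug_profiles = {
        d: {
            g
            for t in net.drug_targets(d)
            if (g := net.target_gene(t)) is not None
        }
        for d in net.drugs
    }
    results = prioritize_indications(drug_profiles, aap, perm)
    results.frame.to_csv(outdir / "indications.tsv", sep="\t", index=False)
    counts.update(
        drugs_scored=len(results.frame),
        drugs_significant=results.n_significant(0.05),
    )
    log.info("scoring: %(drugs_significant)d/%(drugs_scored)d significant", counts)

    report = RunReport(
        config={
            "seed": config.seed,
            "use_predictions": config.use_predictions,
            "activity_threshold_um": config.activity_threshold_um,
            "min_organisms": config.min_organisms,
            "inference": vars(config.inference).copy(),
            "permutation": {
                "universe_size": perm.universe_size,
                "aap_size": perm.aap_size,
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
                "tail_mode": perm.tail_mode,
            },
        },
        counts=counts,
        wall_clock_s=time.time() - t0,
    )
    report.validate()
    report.to_json(outdir / "report.json")
    return report


def export_network(net: DTINetwork, fmt: str, path: str | Path) -> None:
    """Export a network as 'edge_tsv' or 'graphml'."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    if fmt == "edge_tsv":
        lio.write_edge_tsv(net, path)
    elif fmt == "graphml":
        lio.write_graphml(net, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
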