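"""End-to-end orchestration: curate → cluster → networks → hubs →
enrichment → summary network, with a machine-readable run report.

Every stage writes its outputs before the next begins, so a failed run
retains all partial artifacts.  All randomness (clustering init,
synthetic generation) is funneled through one seed recorded in the
report; two runs with identical config and seed produce byte-identical
outputs apart from the report's wall-clock timestamps.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from netpharm import io as npio
from netpharm.chem import compute_descriptors, curate_compounds, kmeans_cluster, standardize
from netpharm.enrichment import enrich
from netpharm.model import ValidationError
from netpharm.networks import (
    assemble_hctp,
    build_bipartite,
    expand_disease_network,
    filter_ppi,
    intersect,
)
from netpharm.synthetic import InputBundle, SyntheticConfig, cki_fixture, generate_inputs
from netpharm.topology import HubCriteria, centralities, resolve_thresholds, select_hubs

logger = logging.getLogger("netpharm")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``inputs`` is a directory containing the five standard input files
    (``compounds.tsv``, ``compound_targets.tsv``, ``disease_genes.txt``,
    ``ppi.tsv``, ``annotations.gmt``), or the literal ``"synthetic"``
    (generated with ``seed``), or ``"cki-fixture"`` for the deterministic
    case-study bundle.
    """

    inputs: str = "cki-fixture"
    outdir: str = "netpharm-run"
    ppi_min_score: float = 0.7
    strict_ppi: bool = True
    k_clusters: int = 5
    fdr_max: float = 0.01
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    compound_hubs: HubCriteria = field(
        default_factory=lambda: HubCriteria(degree_min="mean", role_filter="compound")
    )
    ppi_hubs: HubCriteria = field(
        default_factory=lambda: HubCriteria(
            degree_min="mean", betweenness_min="mean", closeness_min="mean",
            role_filter="target",
        )
    )
    target_hubs: HubCriteria = field(
        default_factory=lambda: HubCriteria(degree_min="mean", role_filter="target")
    )

    def validate(self) -> None:
        if not (0.0 <= self.ppi_min_score <= 1.0):
            raise ValidationError("ppi_min_score must be in [0, 1]")
        if not (0.0 < self.fdr_max <= 1.0):
            raise ValidationError("fdr_max must be in (0, 1]")
        if self.k_clusters < 1:
            raise ValidationError("k_clusters must be positive")


def _load_inputs(config: PipelineConfig) -> tuple:
    """Return (bundle-without-gene-sets, gmt_path or bundle gene sets)."""
    if config.inputs == "cki-fixture":
        return cki_fixture(), None
    if config.inputs == "synthetic" or config.inputs.startswith("synthetic:"):
        seed = config.seed
        if ":" in config.inputs:
            seed = int(config.inputs.split(":", 1)[1])
        sc = SyntheticConfig(**{**config.synthetic.__dict__, "seed": seed})
        return generate_inputs(sc), None
    indir = Path(config.inputs)
    for fname in ("compounds.tsv", "compound_targets.tsv", "disease_genes.txt", "ppi.tsv"):
        if not (indir / fname).exists():
            raise ValidationError(f"missing input file {indir / fname}")
    bundle = InputBundle(
        compounds=npio.read_compound_table(indir / "compounds.tsv"),
        ct_edges=npio.parse_edge_table(indir / "compound_targets.tsv", "compound-target"),
        disease_seeds=npio.parse_gene_list(indir / "disease_genes.txt"),
        ppi_edges=npio.parse_edge_table(indir / "ppi.tsv", "ppi"),
        gene_sets=[],  # read lazily at the enrichment stage
    )
    return bundle, indir / "annotations.gmt"


def _write_centrality(table, path) -> None:
    table.round(9).to_csv(path, sep="\t")


def _write_enrichment(rows, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["term_id", "term_name", "category", "k", "n", "K", "N",
             "p_value", "fdr", "rich_factor", "fold_enrichment", "genes"]
        )
        for r in rows:
            w.writerow(
                [r.term_id, r.term_name, r.category, r.k, r.n, r.K, r.N,
                 f"{r.p_value:.6g}", f"{r.fdr:.6g}", f"{r.rich_factor:.6g}",
                 f"{r.fold_enrichment:.6g}", ",".join(sorted(r.genes))]
            )


def _export(net, outdir: Path, stem: str) -> dict:
    npio.export_network(net, outdir / f"{stem}.sif", "sif")
    npio.export_network(net, outdir / f"{stem}.graphml", "graphml")
    return {"nodes": net.n_nodes, "edges": net.n_edges}


def _audit(report: dict, outdir: Path) -> None:
    """Re-parse every exported network and cross-check the reported counts."""
    for stem, counts in report["networks"].items():
        reread = npio.parse_network(outdir / f"{stem}.graphml", "graphml")
        if (reread.n_nodes, reread.n_edges) != (counts["nodes"], counts["edges"]):
            raise ValidationError(
                f"audit failure for {stem}: report says {counts}, "
                f"file has {reread.n_nodes} nodes / {reread.n_edges} edges"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to
    ``<outdir>/report.json``)."""
    from netpharm import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": config.inputs,
        "thresholds": {},
        "networks": {},
        "hubs": {},
        "enrichment": {},
    }

    stage = "load-inputs"
    try:
        bundle, gmt_path = _load_inputs(config)
        if config.inputs in ("cki-fixture",) or config.inputs.startswith("synthetic"):
            bundle.write(outdir / "inputs")

        stage = "curate"
        curated = curate_compounds(bundle.compounds)
        npio.write_compound_table(curated, outdir / "compounds_curated.tsv")
        report["compounds"] = {"raw": len(bundle.compounds), "curated": len(curated)}
        logger.info("curated %d/%d compounds", len(curated), len(bundle.compounds))

        stage = "cluster"
        matrix = standardize(compute_descriptors(curated))
        k = min(config.k_clusters, len(curated))
        labels = kmeans_cluster(matrix, k=k, seed=config.seed)
        matrix.values.round(9).to_csv(outdir / "descriptors.tsv", sep="\t")
        labels.to_csv(outdir / "clusters.tsv", sep="\t")
        report["clusters"] = {"k": k, "occupied": int(labels.nunique())}

        stage = "build-bipartite"
        bip = build_bipartite(curated, bundle.ct_edges)
        report["networks"]["compound_putative_target"] = _export(bip, outdir, "compound_putative_target")

        stage = "topology-bipartite"
        bip_tab = centralities(bip)
        _write_centrality(bip_tab, outdir / "compound_putative_target.centrality.tsv")
        thr = resolve_thresholds(bip_tab, config.compound_hubs)
        report["thresholds"]["compound_hubs"] = thr
        logger.info("compound hub thresholds: %s", thr)
        report["hubs"]["compounds"] = select_hubs(bip_tab, config.compound_hubs)

        stage = "ppi-filter-expand"
        kept = filter_ppi(bundle.ppi_edges, config.ppi_min_score, config.strict_ppi)
        disease = expand_disease_network(bundle.disease_seeds, kept)
        report["ppi_filter"] = {
            "input_edges": len(bundle.ppi_edges),
            "kept_edges": len(kept),
            "min_score": config.ppi_min_score,
            "strict": config.strict_ppi,
        }
        report["networks"]["disease_ppi"] = _export(disease, outdir, "disease_ppi")

        stage = "topology-ppi"
        if disease.n_nodes:
            ppi_tab = centralities(disease)
            _write_centrality(ppi_tab, outdir / "disease_ppi.centrality.tsv")
            thr = resolve_thresholds(ppi_tab, config.ppi_hubs)
            report["thresholds"]["ppi_hubs"] = thr
            logger.info("PPI hub thresholds: %s", thr)
            report["hubs"]["ppi_major_nodes"] = select_hubs(ppi_tab, config.ppi_hubs)
        else:
            report["hubs"]["ppi_major_nodes"] = []

        stage = "intersect"
        result = intersect(bip, disease)
        inter = result.network
        report["networks"]["compound_disease_target"] = _export(inter, outdir, "compound_disease_target")
        report["intersection"] = {
            "common_targets": sorted(result.common_targets),
            "dropped_compounds": sorted(result.dropped_compounds),
            "n_dropped_targets": len(result.dropped_targets),
        }

        stage = "topology-intersection"
        if inter.n_nodes:
            int_tab = centralities(inter)
            _write_centrality(int_tab, outdir / "compound_disease_target.centrality.tsv")
            thr = resolve_thresholds(int_tab, config.target_hubs)
            report["thresholds"]["target_hubs"] = thr
            logger.info("target hub thresholds: %s", thr)
            report["hubs"]["targets"] = select_hubs(int_tab, config.target_hubs)
        else:
            report["hubs"]["targets"] = []

        stage = "enrichment"
        if gmt_path is not None:
            if not Path(gmt_path).exists():
                raise ValidationError(f"missing gene-set (GMT) file {gmt_path}")
            gene_sets = npio.parse_gene_sets(gmt_path)
        else:
            gene_sets = bundle.gene_sets
        targets = inter.nodes_by_role("target")
        rows = enrich(targets, gene_sets, fdr_max=config.fdr_max) if targets else []
        _write_enrichment(rows, outdir / "enrichment.tsv")
        by_cat: dict = {}
        for r in rows:
            by_cat[r.category] = by_cat.get(r.category, 0) + 1
        report["enrichment"] = {"fdr_max": config.fdr_max, "significant": by_cat}

        stage = "assemble-hctp"
        herb_map = {c.compound_id: c.herb for c in curated if c.herb}
        hctp = assemble_hctp(herb_map, result, rows)
        report["networks"]["herb_compound_target_pathway"] = _export(hctp, outdir, "herb_compound_target_pathway")
        report["hctp"] = {
            "herbs": len(hctp.nodes_by_role("herb")),
            "pathways": len(hctp.nodes_by_role("pathway")),
        }

        stage = "audit"
        _audit(report, outdir)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc

    report["timestamps"] = {
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
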