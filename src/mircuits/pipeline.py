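"""End-to-end orchestration of the two-stage workflow.

Stage one ("ab initio"): per-cohort mixed-circuit inference, cross-cohort
circuit intersection, merged network and the child network of shared
nodes plus first neighbours.  Stage two ("knowledge-based"): per-cohort
topological pathway analysis, meta-pathway construction and the
cross-cohort union network with log2ratio annotation and discrepancy
filtering.  A :class:`RunManifest` snapshots config, input digests and
the seed so every artifact is regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import AnalysisConfig
from .consensus import (extract_child_network, intersect_circuits,
                        merge_networks, shared_relationship_nodes)
from .datasets import ExpressionDataset
from .models import MixedCircuitModel, MixedCircuitResults
from .networks import RegulatoryNetwork
from .pathway_model import (PathwayTopologyModel, PathwayTopologyResults,
                            union_network)
from .pathways import PathwayGraph
from .priors import InteractionPrior

logger = logging.getLogger(__name__)


@dataclass
class CohortInputs:
    """One cohort's inputs: paired matrices plus the shared prior."""

    mirna_ds: ExpressionDataset
    gene_ds: ExpressionDataset
    prior: InteractionPrior

    @property
    def cohort_id(self) -> str:
        return self.gene_ds.cohort_id


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2,
                      sort_keys=True)

    @staticmethod
    def digest(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()


def make_manifest(cfg: AnalysisConfig, input_paths: dict | None = None,
                  ) -> RunManifest:
    digests = {name: RunManifest.digest(p)
               for name, p in (input_paths or {}).items()
               if Path(p).is_file()}
    return RunManifest(config=cfg.to_dict(), seed=cfg.rng_seed,
                       version=__version__, input_digests=digests)


def run_circuits(inputs: CohortInputs, cfg: AnalysisConfig | None = None,
                 ) -> MixedCircuitResults:
    """Stage one for a single cohort: CV filter -> correlations ->
    binary relations -> circuits -> network."""
    cfg = cfg or AnalysisConfig()
    return MixedCircuitModel(inputs.mirna_ds, inputs.gene_ds,
                             inputs.prior, cfg).fit()


@dataclass
class FullRunResults:
    """Everything the two-cohort workflow produces."""

    circuits_a: MixedCircuitResults
    circuits_b: MixedCircuitResults | None
    consensus_circuits: list
    merged_network: RegulatoryNetwork | None
    shared_nodes: set[str]
    child_network: RegulatoryNetwork | None
    pathway_a: PathwayTopologyResults | None
    pathway_b: PathwayTopologyResults | None
    union: RegulatoryNetwork | None
    report: dict

    def summary(self) -> dict:
        return self.report


def run_full(inputs_a: CohortInputs, inputs_b: CohortInputs | None,
             pathways: list[PathwayGraph] | None,
             cfg: AnalysisConfig | None = None,
             n_permutations: int | None = None) -> FullRunResults:
    """Run the complete workflow on one or two cohorts.

    With a single cohort the consensus and union stages are skipped with
    a notice; with no pathways, stage two is skipped.  The summary report
    collects per-stage counts, including the cross-cohort significant-
    pathway overlap.
    """
    cfg = cfg or AnalysisConfig()
    report: dict = {}

    res_a = run_circuits(inputs_a, cfg)
    report["circuits_A"] = len(res_a.circuits)
    res_b = None
    consensus: list = []
    merged = None
    shared: set[str] = set()
    child = None
    if inputs_b is not None:
        res_b = run_circuits(inputs_b, cfg)
        report["circuits_B"] = len(res_b.circuits)
        ref = "A" if cfg.reference_cohort in (None,
                                              inputs_a.cohort_id) else "B"
        consensus = intersect_circuits(res_a.circuits, res_b.circuits,
                                       reference=ref)
        merged = merge_networks(res_a.network, res_b.network,
                                reference=ref)
        shared = shared_relationship_nodes(res_a.network, res_b.network)
        child = (extract_child_network(merged, shared) if shared
                 else RegulatoryNetwork())
        report["consensus_circuits"] = len(consensus)
        report["shared_nodes"] = len(shared)
        report["child_network_nodes"] = child.n_nodes()
        report["child_network_edges"] = child.n_edges()
    else:
        logger.info("single-cohort mode: consensus stage skipped")
        report["consensus"] = "skipped (single cohort)"

    path_a = path_b = None
    union = None
    if pathways:
        path_a = PathwayTopologyModel(pathways, inputs_a.mirna_ds,
                                      inputs_a.gene_ds, inputs_a.prior,
                                      cfg).fit(n_permutations)
        report["significant_pathways_A"] = path_a.significant_pathways
        if inputs_b is not None:
            path_b = PathwayTopologyModel(pathways, inputs_b.mirna_ds,
                                          inputs_b.gene_ds,
                                          inputs_b.prior,
                                          cfg).fit(n_permutations)
            report["significant_pathways_B"] = path_b.significant_pathways
            overlap = (set(path_a.significant_pathways)
                       & set(path_b.significant_pathways))
            report["pathway_overlap"] = sorted(overlap)
            report["pathway_overlap_count"] = len(overlap)
            union = union_network(path_a.selected_nodes,
                                  path_b.selected_nodes,
                                  path_a.meta, path_b.meta,
                                  path_a.annotations, path_b.annotations,
                                  cfg)
            report["union_network_nodes"] = union.n_nodes()
            report["union_network_edges"] = union.n_edges()
        else:
            logger.info("single-cohort mode: union stage skipped")
            report["union"] = "skipped (single cohort)"

    return FullRunResults(
        circuits_a=res_a, circuits_b=res_b,
        consensus_circuits=consensus, merged_network=merged,
        shared_nodes=shared, child_network=child,
        pathway_a=path_a, pathway_b=path_b, union=union, report=report)


def write_artifacts(results: FullRunResults, outdir,
                    cfg: AnalysisConfig,
                    manifest: RunManifest | None = None) -> dict:
    """Write TSV tables, GraphML networks and the JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, writer) -> None:
        writer(outdir / name)
        paths[name] = name  # relative to the run directory

    save("circuits_A.tsv",
         lambda p: results.circuits_a.to_frame().to_csv(p, sep="\t",
                                                        index=False))
    save("network_A.graphml", results.circuits_a.network.to_graphml)
    save("network_A.sif", results.circuits_a.network.to_sif)
    if results.circuits_b is not None:
        save("circuits_B.tsv",
             lambda p: results.circuits_b.to_frame().to_csv(p, sep="\t",
                                                            index=False))
        save("network_B.graphml", results.circuits_b.network.to_graphml)
    if results.merged_network is not None:
        save("merged_network.graphml", results.merged_network.to_graphml)
    if results.child_network is not None:
        save("child_network.graphml", results.child_network.to_graphml)
        genes = sorted(n for n, d in results.child_network.nodes(data=True)
                       if d.get("kind") == "gene")
        save("child_network_genes.tsv",
             lambda p: Path(p).write_text(
                 "gene\n" + "".join(f"{g}\n" for g in genes)))
    for tag, pres in (("A", results.pathway_a), ("B", results.pathway_b)):
        if pres is None:
            continue
        save(f"pathways_{tag}.tsv",
             lambda p, r=pres: r.summary().to_csv(p, sep="\t",
                                                  index=False))
        save(f"pathway_results_{tag}.json",
             lambda p, r=pres: Path(p).write_text(json.dumps({
                 "cohort": r.cohort_id,
                 "significant": r.significant_pathways,
                 "portions": [{
                     "pathway": s.pathway_id,
                     "cliques": list(s.clique_path),
                     "nodes": sorted(s.nodes),
                     "score": s.score, "p_value": s.p_value,
                 } for s in r.portions],
                 "selected_nodes": sorted(r.selected_nodes),
             }, indent=2)))
    if results.union is not None:
        save("union_network.graphml", results.union.to_graphml)
    save("report.json",
         lambda p: Path(p).write_text(json.dumps(results.report,
                                                 indent=2, default=str)))
    if manifest is not None:
        manifest.stage_outputs = paths
        manifest.write(outdir / "manifest.json")
    return paths
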