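"""End-to-end pipeline: catalog -> enrichment -> networks -> scoring -> DE check.

This module is the library face of the ``run-all`` command.  Stages run in
the flowchart order:

1. read the risk-gene catalog, annotation GMT, ontology (and optionally a
   universe file, drug-target table and expression matrix);
2. filter annotation to the requested GO level;
3. hypergeometric enrichment of the catalog (significant terms);
4. term-overlap network (GOFN) + topology;
5. drug filtering and the bipartite drug-term network (DGOFN) + power-law
   degree fit;
6. association scores and permutation Z per drug, candidate selection;
7. optional expression validation (Welch t + FC, catalog overlap).

Every run writes a manifest (parameters, input digests, seed, version) so
outputs are attributable and reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .dgofn import (
    BipartiteNetwork,
    build_dgofn,
    degree_histogram,
    filter_drugs,
    fit_power_law,
)
from .enrichment import EnrichmentRecord, enrich_terms
from .errors import ConfigError, FitError, MGNetError, ScoreError
from .gofn import TermNetwork, build_gofn, node_betweenness, node_degree
from .io_formats import (
    read_drug_targets,
    read_gene_list,
    read_gmt,
    write_network,
)
from .ontology import filter_terms_by_level, parse_obo
from .scoring import (
    AssociationResult,
    make_profiles,
    permutation_z,
    select_candidates,
)
from .validation import DERecord, ExpressionMatrix, differential_expression, overlap_significance

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "RunManifest", "run_all", "DEFAULTS"]

DEFAULTS = {
    "level": 3,
    "min_genes": 5,
    "min_targets": 3,
    "alpha": 0.05,
    "fdr": 0.05,
    "nperm": 10_000,
    "z": 1.96,
    "p": 0.05,
    "fc": 2.0,
    "seed": 0,
    "scale": "log2",
}

_REQUIRED_INPUTS = ("risk_genes", "annotation", "obo", "drugs")


@dataclass
class RunManifest:
    """Provenance stamp: what ran, on what, with which parameters."""

    command: str
    parameters: dict
    input_digests: dict[str, str]
    seed: int
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "parameters": self.parameters,
            "input_digests": self.input_digests,
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp or datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    enrichment: list[EnrichmentRecord]
    significant: list[EnrichmentRecord]
    gofn: TermNetwork
    dgofn: BipartiteNetwork
    power_law: dict | None
    scores: list[AssociationResult]
    candidates: list[AssociationResult]
    de_records: list[DERecord] | None = None
    de_overlap: tuple[int, float] | None = None
    manifest: RunManifest | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "name": r.name, "x": r.inputs.x, "K": r.inputs.K,
                "N": r.inputs.N, "M": r.inputs.M, "p": r.p, "q": r.q,
                "significant": r.significant,
                "genes": "|".join(sorted(r.overlap_genes)),
            }
            for r in records
        ],
        columns=["term", "name", "x", "K", "N", "M", "p", "q", "significant", "genes"],
    )


def scores_frame(
    results: list[AssociationResult], z_threshold: float
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": r.drug, "S": r.S, "perm_mean": r.perm_mean,
                "perm_std": r.perm_std,
                "Z": r.Z if r.Z is not None else float("nan"),
                "n_perm": r.n_perm,
                "candidate": r.Z is not None and r.Z > z_threshold,
            }
            for r in sorted(results, key=lambda r: r.drug)
        ],
        columns=["drug", "S", "perm_mean", "perm_std", "Z", "n_perm", "candidate"],
    )


def de_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "t_stat": r.t_stat, "p": r.p, "fc": r.fc,
                "significant": r.significant, "p_defined": r.p_defined,
            }
            for r in records
        ],
        columns=["gene", "t_stat", "p", "fc", "significant", "p_defined"],
    )


def run_all(config: dict, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the whole pipeline from a configuration mapping.

    Required config keys: ``risk_genes``, ``annotation`` (GMT), ``obo``,
    ``drugs`` (TSV).  Optional: ``universe`` (gene-list file; defaults to
    all genes of the level-filtered annotation plus the catalog),
    ``expression`` + ``groups`` (enables the validation stage), and any
    threshold in :data:`DEFAULTS`.  When ``out_dir`` is given, every stage
    writes its table there along with ``manifest.json``.
    """
    missing = [k for k in _REQUIRED_INPUTS if k not in config]
    if missing:
        raise ConfigError(f"config missing required keys: {missing}")
    params = {**DEFAULTS, **{k: v for k, v in config.items()}}
    seed = int(params["seed"])

    input_paths = {
        k: Path(config[k])
        for k in ("risk_genes", "annotation", "obo", "drugs", "universe",
                  "expression", "groups")
        if k in config
    }
    for key, path in input_paths.items():
        if not path.exists():
            raise ConfigError(f"input {key!r} not found: {path}")

    risk_genes = read_gene_list(input_paths["risk_genes"])
    annotation = read_gmt(input_paths["annotation"])
    ontology = parse_obo(input_paths["obo"])
    drugs = read_drug_targets(input_paths["drugs"])

    leveled = filter_terms_by_level(
        annotation, ontology, int(params["level"]),
        mode=params.get("level_mode", "shortest"),
    )
    if "universe" in input_paths:
        universe = read_gene_list(input_paths["universe"])
    else:
        universe = leveled.all_genes() | risk_genes
        logger.info("universe defaulted to %d annotation+catalog genes", len(universe))

    records = enrich_terms(
        risk_genes & universe, leveled, universe,
        alpha=float(params["alpha"]), min_query_genes=int(params["min_genes"]),
    )
    significant = [r for r in records if r.significant]
    logger.info("%d terms tested, %d significant", len(records), len(significant))

    gofn_net = build_gofn(
        significant, leveled, universe,
        fdr=float(params["fdr"]), risk_genes=risk_genes,
    )
    degrees = node_degree(gofn_net)
    betweenness = node_betweenness(gofn_net)

    risk_in_universe = risk_genes & universe
    filtered_drugs = filter_drugs(
        drugs, risk_in_universe, min_targets=int(params["min_targets"])
    )
    dgofn_net = build_dgofn(
        filtered_drugs, significant, leveled, risk_in_universe,
        fdr=float(params["fdr"]),
    )
    power_law = None
    try:
        hist = degree_histogram(dgofn_net, node_class="all")
        fit = fit_power_law(hist)
        power_law = {"a": fit.a, "b": fit.b, "r2": fit.r2}
    except FitError as exc:
        logger.warning("power-law fit skipped: %s", exc)

    drug_profiles, disease_profile = make_profiles(dgofn_net, significant)
    scores: list[AssociationResult] = []
    for drug_id in sorted(drug_profiles):
        try:
            scores.append(
                permutation_z(
                    drug_profiles[drug_id], disease_profile,
                    n_perm=int(params["nperm"]), seed=seed,
                    perm_domain=params.get("perm_domain", "full"),
                )
            )
        except ScoreError as exc:
            logger.warning("drug %s unscorable: %s", drug_id, exc)
    candidates = select_candidates(scores, z_threshold=float(params["z"]))

    de_records = None
    de_overlap = None
    if "expression" in input_paths:
        if "groups" not in input_paths:
            raise ConfigError("expression given without a groups file")
        expr = ExpressionMatrix.read_tsv(
            input_paths["expression"], scale=params["scale"]
        )
        groups_df = pd.read_csv(input_paths["groups"], sep="\t")
        groups = dict(zip(groups_df["sample"].astype(str), groups_df["label"]))
        de_records = differential_expression(
            expr, groups,
            p_threshold=float(params["p"]), fc_threshold=float(params["fc"]),
        )
        de_genes = {r.gene for r in de_records if r.significant}
        de_overlap = overlap_significance(
            risk_genes, de_genes, set(map(str, expr.values.index))
        )

    tables = {
        "enrichment": enrichment_frame(records),
        "gofn_nodes": pd.DataFrame(
            {"degree": degrees, "betweenness": betweenness}
        ).rename_axis("term").reset_index(),
        "scores": scores_frame(scores, float(params["z"])),
    }
    if de_records is not None:
        tables["de"] = de_frame(de_records)

    manifest = RunManifest(
        command="run-all",
        parameters={k: params[k] for k in DEFAULTS},
        input_digests={k: file_digest(p) for k, p in sorted(input_paths.items())},
        seed=seed,
    )

    result = PipelineResult(
        enrichment=records, significant=significant, gofn=gofn_net,
        dgofn=dgofn_net, power_law=power_law, scores=scores,
        candidates=candidates, de_records=de_records, de_overlap=de_overlap,
        manifest=manifest, tables=tables,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), params)
    return result


def _write_outputs(result: PipelineResult, out: Path, params: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.tables["enrichment"].to_csv(out / "enrichment.tsv", sep="\t", index=False)
    result.tables["gofn_nodes"].to_csv(out / "gofn.nodes.tsv", sep="\t", index=False)
    write_network(result.gofn, out / "gofn.edges.tsv", format="edge-tsv")
    write_network(result.gofn, out / "gofn.graphml", format="graphml")
    write_network(result.dgofn, out / "dgofn.edges.tsv", format="edge-tsv")
    if result.power_law is not None:
        (out / "dgofn.fit.json").write_text(
            json.dumps(result.power_law, indent=2) + "\n"
        )
    result.tables["scores"].to_csv(out / "scores.tsv", sep="\t", index=False)
    if "de" in result.tables:
        result.tables["de"].to_csv(out / "de.tsv", sep="\t", index=False)
        x, p = result.de_overlap
        (out / "de_overlap.json").write_text(
            json.dumps({"overlap": x, "p": p}, indent=2) + "\n"
        )
    if result.manifest is not None:
        result.manifest.write(out / "manifest.json")
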