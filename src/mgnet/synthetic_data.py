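"""Seeded synthetic worlds with planted ground truth.

The generator emulates every input the pipeline consumes — a gene
universe, a toy leveled GO DAG with term gene sets, a disease risk-gene
catalog planted to be enriched in designated level-3 terms, "true" drugs
whose targets concentrate in those terms next to background drugs, and a
two-group expression matrix with planted log2 fold-change shifts — and
records the planted truth so recovery is testable offline.

Defaults describe the study conditions the pipeline is validated under:
a 2,000-gene universe, 150 terms, 8 planted enriched terms supplying 60%
of a 120-gene disease catalog, 13 case vs 12 control samples, and 2.5x
planted expression shifts.  All randomness flows from one seeded
generator, so one seed reproduces the whole world byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, UsageError
from .io_formats import (
    DrugTargetTable,
    GeneSet,
    GeneSetCollection,
    write_drug_targets,
    write_gene_list,
    write_gmt,
)
from .validation import ExpressionMatrix

__all__ = ["SimConfig", "SimTruth", "SimWorld", "generate_world", "truth_report"]

ROOT_ID = "GO:SIM0000001"


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic world; defaults are the validated conditions."""

    n_genes: int = 2000
    n_terms: int = 150
    term_size_range: tuple[int, int] = (10, 50)
    dag_levels: int = 5
    terms_per_module: int = 4
    module_pool_size: int = 40
    module_fraction: float = 0.6
    n_disease_genes: int = 120
    n_enriched_terms: int = 8
    enrichment_fraction: float = 0.6
    n_true_drugs: int = 10
    n_null_drugs: int = 20
    targets_per_drug: int = 6
    true_target_overlap_fraction: float = 0.6
    n_case: int = 13
    n_control: int = 12
    n_de_genes: int = 100
    log2fc_effect: float = math.log2(2.5)
    noise_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_terms": self.n_terms,
            "dag_levels": self.dag_levels, "n_disease_genes": self.n_disease_genes,
            "n_enriched_terms": self.n_enriched_terms,
            "n_true_drugs": self.n_true_drugs, "n_null_drugs": self.n_null_drugs,
            "targets_per_drug": self.targets_per_drug,
            "n_case": self.n_case, "n_control": self.n_control,
            "n_de_genes": self.n_de_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for name, value in (
            ("enrichment_fraction", self.enrichment_fraction),
            ("true_target_overlap_fraction", self.true_target_overlap_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError(
                f"term_size_range {self.term_size_range} must sit within [1, n_genes]"
            )
        if self.terms_per_module < 1 or self.module_pool_size < 1:
            raise ConfigError("module structure parameters must be positive")
        if not 0.0 <= self.module_fraction <= 1.0:
            raise ConfigError("module_fraction must lie in [0, 1]")
        if self.dag_levels < 3:
            raise ConfigError("dag_levels must be >= 3 so a level-3 stratum exists")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes exceeds the universe")


@dataclass
class SimTruth:
    """What was planted: enriched terms, disease genes, true drugs, DE genes."""

    enriched_term_ids: list[str]
    disease_genes: list[str]
    true_drug_ids: list[str]
    de_gene_ids: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimWorld:
    """In-memory synthetic world plus the paths it was written to."""

    config: SimConfig
    universe: set[str]
    annotation: GeneSetCollection
    term_levels: dict[str, int]
    disease_genes: set[str]
    drug_table: DrugTargetTable
    expression: ExpressionMatrix
    groups: dict[str, str]
    truth: SimTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _build_dag(config: SimConfig, rng: np.random.Generator):
    """Assign terms to strata 1..dag_levels (level 3 gets the bulk) and parents."""
    levels = list(range(1, config.dag_levels + 1))
    other = [l for l in levels if l != 3]
    base = max(2, int(0.3 * config.n_terms / max(len(other), 1)))
    counts = {l: base for l in other}
    counts[3] = config.n_terms - sum(counts.values())
    if counts[3] < config.n_enriched_terms:
        raise ConfigError(
            f"only {counts[3]} level-3 terms for {config.n_enriched_terms} planted terms"
        )
    term_ids, term_levels = [], {}
    idx = 2  # root holds id 1
    for level in levels:
        for _ in range(counts[level]):
            tid = f"GO:SIM{idx:07d}"
            term_ids.append(tid)
            term_levels[tid] = level
            idx += 1
    by_level = {l: [t for t in term_ids if term_levels[t] == l] for l in levels}
    parents: dict[str, list[str]] = {}
    for tid in term_ids:
        level = term_levels[tid]
        pool = [ROOT_ID] if level == 1 else by_level[level - 1]
        n_par = int(rng.integers(1, min(2, len(pool)) + 1))
        parents[tid] = sorted(
            rng.choice(pool, size=n_par, replace=False).tolist()
        )
    return term_ids, term_levels, parents


def _write_obo(path: Path, term_ids, term_levels, parents) -> None:
    lines = ["format-version: 1.2", ""]
    lines += [
        "[Term]",
        f"id: {ROOT_ID}",
        "name: simulated biological process root",
        "namespace: biological_process",
        "",
    ]
    for tid in term_ids:
        lines += [
            "[Term]",
            f"id: {tid}",
            f"name: simulated process {tid[-7:]} (level {term_levels[tid]})",
            "namespace: biological_process",
        ]
        lines += [f"is_a: {p} ! parent" for p in parents[tid]]
        lines.append("")
    path.write_text("\n".join(lines))


def generate_world(config: SimConfig, out_dir: str | Path | None = None) -> SimWorld:
    """Build (and optionally write) one synthetic world.

    Everything is derived from ``config.seed`` via a single generator
    stream; infeasible configurations raise :class:`ConfigError` before
    any file is written.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    universe_list = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    universe = set(universe_list)

    term_ids, term_levels, parents = _build_dag(config, rng)
    lo, hi = config.term_size_range
    level3 = [t for t in term_ids if term_levels[t] == 3]

    # Level-3 terms are grouped into "modules" that share a gene pool, so
    # functionally related terms overlap the way real sibling GO terms do;
    # overlapping terms are what give the term-overlap network its edges.
    module_of: dict[str, int] = {
        tid: i // config.terms_per_module for i, tid in enumerate(level3)
    }
    n_modules = max(module_of.values()) + 1 if module_of else 0
    module_pools = [
        rng.choice(universe_list, size=min(config.module_pool_size, config.n_genes),
                   replace=False).tolist()
        for _ in range(n_modules)
    ]

    entries = []
    term_genes: dict[str, set[str]] = {}
    for tid in term_ids:
        size = int(rng.integers(lo, hi + 1))
        genes: set[str] = set()
        if tid in module_of:
            pool = module_pools[module_of[tid]]
            n_pool = min(round(config.module_fraction * size), len(pool))
            genes |= set(rng.choice(pool, size=n_pool, replace=False).tolist())
        rest_pool = sorted(universe - genes)
        genes |= set(
            rng.choice(rest_pool, size=size - len(genes), replace=False).tolist()
        )
        term_genes[tid] = genes
        entries.append(
            GeneSet(tid, f"simulated process {tid[-7:]}", frozenset(genes))
        )
    annotation = GeneSetCollection(entries)

    # Planted enriched terms are whole modules, so they overlap one another.
    module_order = rng.permutation(n_modules).tolist()
    enriched: list[str] = []
    for m in module_order:
        enriched.extend(t for t in level3 if module_of[t] == m)
        if len(enriched) >= config.n_enriched_terms:
            break
    enriched = sorted(enriched[: config.n_enriched_terms])

    n_planted = round(config.enrichment_fraction * config.n_disease_genes)
    pool_union = set().union(*(term_genes[t] for t in enriched))
    if len(pool_union) < n_planted:
        raise ConfigError(
            f"planted terms hold {len(pool_union)} distinct genes; "
            f"{n_planted} disease genes requested from them"
        )
    # round-robin over the planted terms so each term is individually enriched
    disease: set[str] = set()
    per_term = {
        t: rng.permutation(sorted(term_genes[t])).tolist() for t in enriched
    }
    while len(disease) < n_planted:
        progressed = False
        for t in enriched:
            while per_term[t]:
                g = per_term[t].pop()
                if g not in disease:
                    disease.add(g)
                    progressed = True
                    break
            if len(disease) >= n_planted:
                break
        if not progressed:
            break
    rest = sorted(universe - disease)
    n_rest = config.n_disease_genes - len(disease)
    disease |= set(rng.choice(rest, size=n_rest, replace=False).tolist())

    # Each true drug concentrates its signal targets inside ONE planted
    # term (drugs act on genes of a shared function), preferring that
    # term's disease genes; background targets are uniform over the
    # universe.
    k_true = round(config.true_target_overlap_fraction * config.targets_per_drug)
    per_term_pools = {
        t: (sorted(disease & term_genes[t]), sorted(term_genes[t] - disease))
        for t in enriched
    }
    thin = min(len(a) + len(b) for a, b in per_term_pools.values())
    if thin < k_true:
        raise ConfigError(
            f"a planted term holds only {thin} genes; "
            f"true drugs need {k_true} signal targets"
        )
    rows = []
    for i in range(1, config.n_true_drugs + 1):
        drug_id = f"DTRUE{i:03d}"
        home_term = enriched[int(rng.integers(len(enriched)))]
        preferred, backup = per_term_pools[home_term]
        if len(preferred) >= k_true:
            targets = set(rng.choice(preferred, size=k_true, replace=False).tolist())
        else:
            targets = set(preferred) | set(
                rng.choice(backup, size=k_true - len(preferred), replace=False).tolist()
            )
        remaining = sorted(universe - targets)
        targets |= set(
            rng.choice(
                remaining, size=config.targets_per_drug - k_true, replace=False
            ).tolist()
        )
        rows += [
            {"drug_id": drug_id, "drug_name": f"True drug {i}", "target": g}
            for g in sorted(targets)
        ]
    for i in range(1, config.n_null_drugs + 1):
        drug_id = f"DNULL{i:03d}"
        targets = rng.choice(
            universe_list, size=config.targets_per_drug, replace=False
        ).tolist()
        rows += [
            {"drug_id": drug_id, "drug_name": f"Background drug {i}", "target": g}
            for g in sorted(targets)
        ]
    drug_table = DrugTargetTable(pd.DataFrame(rows))

    de_genes = sorted(
        rng.choice(universe_list, size=config.n_de_genes, replace=False).tolist()
    )
    n_samples = config.n_case + config.n_control
    samples = [f"CASE{i:02d}" for i in range(1, config.n_case + 1)] + [
        f"CTRL{i:02d}" for i in range(1, config.n_control + 1)
    ]
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    baseline = rng.uniform(6.0, 10.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_samples)
    )
    signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    gene_index = {g: i for i, g in enumerate(universe_list)}
    for g, s in zip(de_genes, signs):
        values[gene_index[g], : config.n_case] += s * config.log2fc_effect
    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=universe_list, columns=samples),
        scale="log2",
    )

    truth = SimTruth(
        enriched_term_ids=enriched,
        disease_genes=sorted(disease),
        true_drug_ids=[f"DTRUE{i:03d}" for i in range(1, config.n_true_drugs + 1)],
        de_gene_ids=de_genes,
        seed=config.seed,
    )
    world = SimWorld(
        config=config,
        universe=universe,
        annotation=annotation,
        term_levels={ROOT_ID: 0, **term_levels},
        disease_genes=disease,
        drug_table=drug_table,
        expression=expression,
        groups=groups,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "universe": out / "universe.txt",
            "annotation": out / "annotation.gmt",
            "obo": out / "ontology.obo",
            "disease_genes": out / "disease_genes.txt",
            "drug_targets": out / "drug_targets.tsv",
            "expression": out / "expression.tsv",
            "groups": out / "groups.tsv",
            "truth": out / "truth.json",
        }
        write_gene_list(universe, paths["universe"])
        write_gmt(annotation, paths["annotation"])
        _write_obo(paths["obo"], term_ids, term_levels, parents)
        write_gene_list(disease, paths["disease_genes"])
        write_drug_targets(drug_table, paths["drug_targets"])
        expression.write_tsv(paths["expression"])
        with paths["groups"].open("w") as fh:
            fh.write("sample\tlabel\n")
            for s in samples:
                fh.write(f"{s}\t{groups[s]}\n")
        truth.to_json(paths["truth"])
        world.paths = paths
    return world


def _auc(scores: dict[str, float], positives: set[str], negatives: set[str]) -> float:
    """Rank-based AUC; entities without a score rank below every scored one."""
    entities = sorted(positives | negatives)
    finite = [scores[e] for e in entities if e in scores and np.isfinite(scores[e])]
    sentinel = (min(finite) - 1.0) if finite else 0.0
    vals = np.array(
        [scores.get(e, sentinel) if np.isfinite(scores.get(e, sentinel)) else sentinel
         for e in entities]
    )
    labels = np.array([1 if e in positives else 0 for e in entities])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise UsageError("AUC needs both positive and negative entities")
    ranks = rankdata(vals)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = float(ranks[labels == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _precision_recall(found: set[str], truth: set[str]) -> tuple[float, float]:
    tp = len(found & truth)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall


def truth_report(
    truth: SimTruth,
    significant_terms: set[str] | None = None,
    drug_z: dict[str, float] | None = None,
    null_drug_ids: set[str] | None = None,
    de_genes: set[str] | None = None,
) -> dict[str, float]:
    """Recovery metrics against the planted truth.

    Supply whichever outputs exist: significant term ids (term
    precision/recall), per-drug Z with the null-drug id set (Z AUC of true
    vs null drugs; unscored drugs rank last), and DE gene calls (DE
    precision/recall).
    """
    metrics: dict[str, float] = {}
    if significant_terms is not None:
        p, r = _precision_recall(significant_terms, set(truth.enriched_term_ids))
        metrics["term_precision"] = p
        metrics["term_recall"] = r
    if drug_z is not None:
        if null_drug_ids is None:
            raise UsageError("drug AUC needs the null drug id set")
        metrics["z_auc"] = _auc(drug_z, set(truth.true_drug_ids), set(null_drug_ids))
    if de_genes is not None:
        p, r = _precision_recall(de_genes, set(truth.de_gene_ids))
        metrics["de_precision"] = p
        metrics["de_recall"] = r
    return metrics
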