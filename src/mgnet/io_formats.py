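"""Readers and writers for every external format the pipeline touches.

No statistics live here.  The formats are deliberately plain text: gene
lists (one symbol per line), Broad-dialect GMT for term -> gene-set
annotation, TSV with a header for drug targets, and edge-TSV / SIF /
GraphML for networks.

Gene symbols from different sources (OMIM, GAD, DisGeNET, DrugBank exports)
disagree in case and whitespace, so every reader funnels symbols through
:func:`normalize_symbol` (trim + upper-case), which is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import EmptyInputError, FormatError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "GeneSet",
    "GeneSetCollection",
    "DrugTargetTable",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_drug_targets",
    "write_drug_targets",
    "write_network",
    "read_edge_tsv",
]


def normalize_symbol(symbol: str) -> str:
    """Trim surrounding whitespace and upper-case a gene symbol."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line): id, human-readable name, members."""

    set_id: str
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered collection of uniquely-identified gene sets.

    Houses GO-BP annotation (term -> genes) as well as any other GMT-shaped
    input.  Set ids are unique; genes are normalized and deduplicated
    within each set.
    """

    def __init__(self, entries: Iterable[GeneSet] = ()):
        self._entries: list[GeneSet] = []
        self._by_id: dict[str, GeneSet] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: GeneSet) -> None:
        if entry.set_id in self._by_id:
            raise FormatError(f"duplicate set id {entry.set_id!r}")
        self._entries.append(entry)
        self._by_id[entry.set_id] = entry

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def ids(self) -> list[str]:
        return [e.set_id for e in self._entries]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for e in self._entries:
            out |= e.genes
        return out

    def subset(self, set_ids: Iterable[str]) -> "GeneSetCollection":
        wanted = set(set_ids)
        return GeneSetCollection(e for e in self._entries if e.set_id in wanted)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass
class DrugTargetTable:
    """Normalized drug -> target-gene rows.

    (drug_id, target) pairs are unique after symbol normalization; drug
    names are carried along for reporting.
    """

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["drug_id", "drug_name", "target"])
    )

    def __post_init__(self) -> None:
        required = ["drug_id", "drug_name", "target"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"drug table missing columns: {missing}")
        self.rows = (
            self.rows[required]
            .drop_duplicates(subset=["drug_id", "target"])
            .reset_index(drop=True)
        )

    def drug_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["drug_id"]))

    def targets_of(self, drug_id: str) -> set[str]:
        return set(self.rows.loc[self.rows["drug_id"] == drug_id, "target"])

    def name_of(self, drug_id: str) -> str:
        sub = self.rows.loc[self.rows["drug_id"] == drug_id, "drug_name"]
        return sub.iloc[0] if len(sub) else drug_id

    def by_drug(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for drug_id, grp in self.rows.groupby("drug_id", sort=False):
            out[drug_id] = set(grp["target"])
        return out

    def __len__(self) -> int:
        return len(self.rows)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list: one symbol per line, ``#`` comments.

    Returns the deduplicated, normalized symbol set.  Raises
    :class:`EmptyInputError` if no genes remain.
    """
    path = Path(path)
    genes: set[str] = set()
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(normalize_symbol(line))
    if not genes:
        raise EmptyInputError(f"no genes found in {path}")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: ``id<TAB>description<TAB>gene...``."""
    path = Path(path)
    collection = GeneSetCollection()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} columns, expected >= 3"
                )
            set_id, name, *genes = fields
            normalized = frozenset(
                normalize_symbol(g) for g in genes if g.strip()
            )
            collection.add(GeneSet(set_id.strip(), name.strip(), normalized))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for entry in collection:
            fh.write(
                "\t".join([entry.set_id, entry.name, *sorted(entry.genes)]) + "\n"
            )


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a TSV with header ``drug_id  drug_name  target``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("drug_id", "drug_name", "target") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("drug target table %s is empty (header only)", path)
        return DrugTargetTable()
    df = df.dropna(subset=["drug_id", "target"])
    df["drug_id"] = df["drug_id"].str.strip()
    df["drug_name"] = df["drug_name"].fillna("").str.strip()
    df["target"] = df["target"].map(normalize_symbol)
    return DrugTargetTable(df)


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "x", "p", "q", "shared_genes"]


def _ordered_edges(graph: nx.Graph) -> list[tuple[str, str, dict]]:
    """Undirected edges, each once, endpoints lexicographically ordered."""
    out = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        out.append((a, b, data))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def write_network(network, path: str | Path, format: str = "edge-tsv") -> None:
    """Serialize a term or bipartite network.

    ``edge-tsv`` carries x/p/q and a pipe-joined shared-gene list per edge
    plus a companion ``<path>.nodes.tsv`` with node type and degree;
    ``sif`` emits Cytoscape ``A pp B`` lines; ``graphml`` keeps all
    attributes.  Edges are written once with lexicographically ordered
    endpoints so output files are byte-stable.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    path = Path(path)
    if format == "edge-tsv":
        records = []
        for a, b, data in _ordered_edges(graph):
            records.append(
                {
                    "source": a,
                    "target": b,
                    "x": data.get("x", ""),
                    "p": data.get("p", ""),
                    "q": data.get("q", ""),
                    "shared_genes": "|".join(sorted(data.get("shared_genes", ()))),
                }
            )
        pd.DataFrame(records, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
        node_records = [
            {
                "node": str(n),
                "type": graph.nodes[n].get("kind", "term"),
                "degree": graph.degree(n),
            }
            for n in sorted(graph.nodes, key=str)
        ]
        pd.DataFrame(
            node_records, columns=["node", "type", "degree"]
        ).to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)
    elif format == "sif":
        with path.open("w") as fh:
            for a, b, _ in _ordered_edges(graph):
                fh.write(f"{a}\tpp\t{b}\n")
    elif format == "graphml":
        export = nx.Graph()
        for n, data in graph.nodes(data=True):
            export.add_node(
                str(n), **{k: _graphml_scalar(v) for k, v in data.items()}
            )
        for a, b, data in _ordered_edges(graph):
            export.add_edge(a, b, **{k: _graphml_scalar(v) for k, v in data.items()})
        nx.write_graphml(export, path)
    else:
        raise UsageError(f"unknown network format {format!r}")


def _graphml_scalar(value):
    if isinstance(value, (frozenset, set, list, tuple)):
        return "|".join(sorted(map(str, value)))
    return value


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Read an ``edge-tsv`` file back into an undirected graph."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        shared = (
            frozenset(str(row.shared_genes).split("|"))
            if isinstance(row.shared_genes, str) and row.shared_genes
            else frozenset()
        )
        graph.add_edge(
            row.source,
            row.target,
            x=int(row.x),
            p=float(row.p),
            q=float(row.q),
            shared_genes=shared,
        )
    return graph
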