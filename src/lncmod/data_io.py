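"""Readers and writers for the standard formats the pipeline touches.

Expression matrices are gene x sample TSVs with a two-column gene-class
table (lncRNA / mRNA) and an optional two-column sample-group table.
PPI networks come from TSV edge lists or SIF files; self-interactions and
duplicates (in either orientation, across files) are removed on read.
GO is read from OBO 1.2/1.4 plus either a GAF 2.x file or a two-column
gene-to-term TSV; annotations are propagated up is_a (and part_of)
ancestors.

Gene identifiers are treated as opaque strings in a single harmonized
namespace; no identifier mapping is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

GENE_CLASSES = frozenset({"lncRNA", "mRNA"})

#: GO relations along which annotations propagate by default.
DEFAULT_PROPAGATION_RELATIONS = ("is_a", "part_of")


class FormatError(ValueError):
    """A malformed input record (readers reject rather than coerce)."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with lncRNA/mRNA class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Units are
        taken as given; downstream correlation is rank-based so any
        monotone transform of the values is irrelevant.
    gene_class
        Mapping gene id -> ``"lncRNA"`` or ``"mRNA"`` covering every gene.
    sample_group
        Optional mapping sample id -> subtype label.
    """

    values: pd.DataFrame
    gene_class: dict[str, str]
    sample_group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene id(s): {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dups}")
        missing = [g for g in idx if g not in self.gene_class]
        if missing:
            raise FormatError(f"genes without a class label: {missing[:10]}")
        bad = {g: c for g, c in self.gene_class.items() if c not in GENE_CLASSES}
        if bad:
            raise FormatError(
                f"gene class labels outside {sorted(GENE_CLASSES)}: {bad}"
            )
        if not self.values.notna().any(axis=1).all():
            empty = self.values.index[~self.values.notna().any(axis=1)].tolist()
            raise FormatError(f"gene rows without any finite value: {empty[:10]}")
        if self.sample_group is not None:
            unknown = [s for s in self.sample_group if s not in set(cols)]
            if unknown:
                raise FormatError(f"sample_group refers to unknown samples: {unknown}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def lnc_ids(self) -> list[str]:
        return [g for g in self.values.index if self.gene_class[g] == "lncRNA"]

    @property
    def mrna_ids(self) -> list[str]:
        return [g for g in self.values.index if self.gene_class[g] == "mRNA"]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples (e.g. one subtype)."""
        group = None
        if self.sample_group is not None:
            group = {s: g for s, g in self.sample_group.items() if s in set(samples)}
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.gene_class, group)


def _read_two_column(path: str | Path, what: str) -> dict[str, str]:
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns in {what}")
            key, value = parts[0], parts[1]
            if key in table and table[key] != value:
                raise FormatError(
                    f"{path}: line {lineno}: conflicting {what} entries for {key!r}"
                )
            table[key] = value
    return table


def read_expression(
    matrix_path: str | Path,
    class_path: str | Path,
    group_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV plus gene-class (and optional sample-group) tables.

    The matrix TSV carries a header row of sample ids and gene ids in the
    first column. Every gene in the matrix must appear in the class table
    with label ``lncRNA`` or ``mRNA``.
    """
    try:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                             float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{matrix_path}: malformed expression TSV: {exc}") from exc
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ].tolist()
    if non_numeric:
        raise FormatError(
            f"{matrix_path}: non-numeric expression values in column(s) {non_numeric}"
        )
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    gene_class = _read_two_column(class_path, "gene class")
    sample_group = _read_two_column(group_path, "sample group") if group_path else None
    return ExpressionMatrix(values, gene_class, sample_group)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     class_path: str | Path,
                     group_path: str | Path | None = None) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    with open(class_path, "w") as fh:
        for g in expr.gene_ids:
            fh.write(f"{g}\t{expr.gene_class[g]}\n")
    if group_path is not None and expr.sample_group is not None:
        with open(group_path, "w") as fh:
            for s, grp in expr.sample_group.items():
                fh.write(f"{s}\t{grp}\n")


def read_ppi(paths: Sequence[str | Path] | str | Path) -> nx.Graph:
    """Read and merge PPI edge lists (TSV) or SIF files into one simple graph.

    Self-interactions are dropped and duplicate interactions (within or
    across files, in either node order) are collapsed; the counts of
    dropped records are logged. SIF lines have the layout
    ``node relation node [node ...]``; anything else with >= 2 columns is
    treated as an edge list using the first two columns.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    graph = nx.Graph()
    n_self = n_dup = 0
    for path in paths:
        is_sif = str(path).lower().endswith(".sif")
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if is_sif:
                    if len(parts) < 3:
                        if len(parts) == 1:  # isolated node, legal SIF
                            graph.add_node(parts[0])
                            continue
                        raise FormatError(f"{path}: line {lineno}: bad SIF record")
                    pairs = [(parts[0], t) for t in parts[2:]]
                else:
                    if len(parts) < 2:
                        raise FormatError(
                            f"{path}: line {lineno}: expected >= 2 columns"
                        )
                    pairs = [(parts[0], parts[1])]
                for a, b in pairs:
                    if a == b:
                        n_self += 1
                        continue
                    if graph.has_edge(a, b):
                        n_dup += 1
                        continue
                    graph.add_edge(a, b, source=str(path))
    if graph.number_of_edges() == 0:
        raise FormatError("no interactions after merging input files")
    logger.info(
        "read_ppi: %d nodes, %d edges (%d self-interactions and %d duplicates dropped)",
        graph.number_of_nodes(), graph.number_of_edges(), n_self, n_dup,
    )
    return graph


@dataclass
class GoResource:
    """Ontology DAG plus gene annotations propagated to ancestors.

    ``dag`` holds one directed edge child -> parent for every propagating
    relation. ``term_genes`` is the exact inverse of
    ``propagated_annotations``.
    """

    dag: nx.DiGraph
    namespaces: dict[str, str]
    term_names: dict[str, str]
    direct_annotations: dict[str, set[str]]
    propagated_annotations: dict[str, set[str]] = field(repr=False, default_factory=dict)
    term_genes: dict[str, set[str]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise FormatError("ontology relation graph contains a cycle")
        if not self.propagated_annotations:
            self._propagate()

    def _propagate(self) -> None:
        ancestors: dict[str, frozenset[str]] = {}
        # reversed topological order: parents (topologically later along
        # child -> parent edges) are resolved before their children
        for term in reversed(list(nx.topological_sort(self.dag))):
            anc = {term}
            for parent in self.dag.successors(term):
                anc |= ancestors[parent]
            ancestors[term] = frozenset(anc)
        self._ancestors = ancestors
        self.propagated_annotations = {}
        self.term_genes = {t: set() for t in self.dag.nodes}
        for gene, terms in self.direct_annotations.items():
            closed: set[str] = set()
            for t in terms:
                closed |= ancestors[t]
            self.propagated_annotations[gene] = closed
            for t in closed:
                self.term_genes[t].add(gene)

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a/part_of ancestors of ``term``, including itself."""
        if not hasattr(self, "_ancestors"):
            self._propagate()
        return self._ancestors[term]

    def terms_in_namespace(self, namespace: str) -> set[str]:
        return {t for t, ns in self.namespaces.items() if ns == namespace}

    def gene_terms(self, gene: str, namespace: str | None = None) -> set[str]:
        terms = self.propagated_annotations.get(gene, set())
        if namespace is None:
            return set(terms)
        return {t for t in terms if self.namespaces[t] == namespace}


def _read_gaf(path: str | Path) -> dict[str, set[str]]:
    """GAF 2.x: column 2 = gene symbol/id, column 5 = GO term, skip NOT rows."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}: line {lineno}: bad GAF record")
            gene, qualifier, term = parts[1], parts[3], parts[4]
            if "NOT" in qualifier.split("|"):
                continue
            annotations.setdefault(gene, set()).add(term)
    return annotations


def read_go(
    obo_path: str | Path,
    annotation_path: str | Path,
    relations: Iterable[str] = DEFAULT_PROPAGATION_RELATIONS,
) -> GoResource:
    """Read an OBO ontology and gene annotations; propagate to ancestors.

    ``annotation_path`` may be a GAF 2.x file (detected by a ``!gaf``
    header or a ``.gaf`` suffix) or a two-column gene<TAB>term TSV.
    Obsolete terms are dropped by the OBO reader; annotations to unknown
    terms are skipped with a warning.
    """
    multigraph = obonet.read_obo(str(obo_path))
    relations = set(relations)
    dag = nx.DiGraph()
    namespaces: dict[str, str] = {}
    term_names: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        dag.add_node(term)
        namespaces[term] = data.get("namespace", "biological_process")
        term_names[term] = data.get("name", term)
    for child, parent, rel in multigraph.edges(keys=True):
        if rel in relations:
            dag.add_edge(child, parent)

    path_str = str(annotation_path)
    is_gaf = path_str.lower().endswith((".gaf", ".gaf.txt"))
    if not is_gaf:
        with open(annotation_path) as fh:
            first = fh.readline()
        is_gaf = first.startswith("!")
    if is_gaf:
        raw = _read_gaf(annotation_path)
    else:
        raw = {}
        for gene, term in (
            line.rstrip("\n").split("\t")[:2]
            for line in open(annotation_path)
            if line.strip() and not line.startswith("#")
        ):
            raw.setdefault(gene, set()).add(term)

    known = set(dag.nodes)
    direct: dict[str, set[str]] = {}
    skipped: set[str] = set()
    for gene, terms in raw.items():
        keep = terms & known
        skipped |= terms - known
        if keep:
            direct[gene] = keep
    if skipped:
        warnings.warn(
            f"skipped annotations to {len(skipped)} unknown/obsolete term(s): "
            f"{sorted(skipped)[:5]}...",
            stacklevel=2,
        )
    return GoResource(dag, namespaces, term_names, direct)


def write_network(graph: nx.Graph, path: str | Path, fmt: str,
                  relation: str = "pp") -> None:
    """Export a network as SIF, GraphML, or a TSV edge table.

    SIF uses one relation token per edge (default ``pp``); GraphML keeps
    all node/edge attributes; TSV writes ``source<TAB>target`` plus one
    column per edge attribute. Output is byte-stable for a fixed input.
    """
    fmt = fmt.lower()
    path = Path(path)
    edges = sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b, _ in edges:
                fh.write(f"{a}\t{relation}\t{b}\n")
            connected = {n for e in graph.edges for n in e}
            for n in sorted(set(graph.nodes) - connected, key=str):
                fh.write(f"{n}\n")
    elif fmt == "graphml":
        # edge_id keys make the output order-stable
        ordered = nx.Graph()
        ordered.add_nodes_from(sorted(graph.nodes(data=True), key=lambda n: str(n[0])))
        ordered.add_edges_from(edges)
        nx.write_graphml(ordered, path, named_key_ids=True)
    elif fmt == "tsv":
        attr_keys = sorted({k for _, _, d in edges for k in d})
        with open(path, "w") as fh:
            fh.write("\t".join(["source", "target", *attr_keys]) + "\n")
            for a, b, d in edges:
                row = [str(a), str(b)]
                for k in attr_keys:
                    v = d.get(k, "")
                    row.append(repr(v) if isinstance(v, float) else str(v))
                fh.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown network format: {fmt!r} (use SIF, GraphML, or TSV)")
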