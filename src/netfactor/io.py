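"""Reading and writing networks, expression matrices and cluster files.

The on-disk formats are deliberately plain: PPI networks are STRING-style
delimited edge lists (two identifier columns plus an optional numeric
confidence column), expression data are delimited text with samples as rows
and a gene-symbol header, and clusterings are one named complex per line.
The study graph ``G_S`` is the subgraph of the PPI network induced on the
genes actually measured in the expression dataset.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ExpressionDataset",
    "Clustering",
    "read_ppi_edgelist",
    "read_id_mapping",
    "relabel_network",
    "induce_study_graph",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clusters",
    "write_clusters",
    "write_edgelist",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """An m x k expression matrix with ordered gene names and optional labels.

    Parameters
    ----------
    values : ndarray of shape (m, k)
        Continuous expression levels, samples as rows.
    gene_names : list of str
        Column names; the gene set ``K``. Must be unique.
    sample_ids : list of str
        Row names. Must be unique.
    labels : ndarray of str, optional
        One categorical phenotype label per sample.
    classes : list of str, optional
        Fixed label vocabulary; defaults to the sorted distinct labels.
    """

    values: np.ndarray
    gene_names: list
    sample_ids: list
    labels: np.ndarray | None = None
    classes: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, k = self.values.shape
        if len(self.gene_names) != k:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {k} columns"
            )
        if len(set(self.gene_names)) != k:
            raise ValueError("gene names must be unique")
        if len(self.sample_ids) != m:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {m} rows"
            )
        if len(set(self.sample_ids)) != m:
            raise ValueError("sample ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != m:
                raise ValueError("one label per sample required")
            if self.classes is None:
                self.classes = sorted(set(self.labels))
            unknown = set(self.labels) - set(self.classes)
            if unknown:
                raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Clustering:
    """An ordered list of named, possibly overlapping gene sets.

    ``clusters`` maps a unique cluster name to a set of node identifiers.
    ``meta`` may carry per-cluster extras (e.g. the COACH core of a complex).
    """

    clusters: list  # list of (name, frozenset of members)
    algorithm: str = ""
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [name for name, _ in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")
        self.clusters = [(n, frozenset(m)) for n, m in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def names(self) -> list:
        return [n for n, _ in self.clusters]

    def members(self, name: str) -> frozenset:
        for n, m in self.clusters:
            if n == name:
                return m
        raise KeyError(name)

    def member_sets(self) -> list:
        return [m for _, m in self.clusters]


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_ppi_edgelist(path, min_score: float | None = None,
                      delimiter: str | None = None) -> nx.Graph:
    """Read a STRING-style protein-links edge list into an undirected graph.

    Accepts two columns (node, node) or three (node, node, numeric score).
    Space- and tab-delimited files are both accepted when ``delimiter`` is
    None. A header row is auto-detected by a non-numeric third column.
    Self-loop rows are dropped (with a logged count) and duplicate edges are
    collapsed, so the result is a simple undirected graph. When ``min_score``
    is given, rows with score < min_score are discarded.
    """
    graph = nx.Graph()
    n_self_loops = 0
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=2 columns, got "
                    f"{len(fields)}"
                )
            if lineno == 1 and len(fields) >= 3 and not _looks_numeric(fields[2]):
                continue  # header row
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncols} columns, got "
                    f"{len(fields)}"
                )
            a, b = fields[0], fields[1]
            if len(fields) >= 3:
                if not _looks_numeric(fields[2]):
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric score "
                        f"{fields[2]!r}"
                    )
                score = float(fields[2])
                if min_score is not None and score < min_score:
                    continue
            if a == b:
                n_self_loops += 1
                continue
            graph.add_edge(a, b)
    if graph.number_of_nodes() == 0:
        raise ParseError(f"{path}: no edges parsed (empty or fully filtered)")
    if n_self_loops:
        logger.info("dropped %d self-loop rows from %s", n_self_loops, path)
    return graph


def read_id_mapping(path, delimiter: str | None = None) -> dict:
    """Read a two-column identifier mapping (e.g. Ensembl protein -> symbol)."""
    mapping = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(delimiter) if delimiter else line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got "
                    f"{len(fields)}"
                )
            mapping[fields[0]] = fields[1]
    return mapping


def relabel_network(graph: nx.Graph, mapping: dict) -> nx.Graph:
    """Relabel nodes through ``mapping``; unmapped nodes keep their name.

    Edges whose endpoints collapse onto the same target become self-loops and
    are dropped, keeping the result a simple graph.
    """
    out = nx.Graph()
    out.add_nodes_from(mapping.get(v, v) for v in graph.nodes)
    for a, b in graph.edges:
        a2, b2 = mapping.get(a, a), mapping.get(b, b)
        if a2 != b2:
            out.add_edge(a2, b2)
    return out


def induce_study_graph(ppi: nx.Graph, genes) -> nx.Graph:
    """Induce the study graph G_S on the genes measured in the dataset.

    V_S = genes ∩ V_PPI; E_S keeps every PPI edge with both endpoints in V_S.
    The returned graph carries provenance counts under
    ``graph.graph["provenance"]``: genes absent from the PPI network and PPI
    nodes absent from the gene set.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    common = genes & set(ppi.nodes)
    if not common:
        raise ValueError(
            "no overlap between expression genes and PPI nodes; check the "
            "identifier namespace (an id mapping file may be needed)"
        )
    sub = nx.Graph()
    sub.add_nodes_from(common)
    sub.add_edges_from(
        (a, b) for a, b in ppi.edges if a in common and b in common
    )
    sub.graph["provenance"] = {
        "genes_not_in_ppi": len(genes) - len(common),
        "ppi_nodes_not_measured": ppi.number_of_nodes() - len(common),
    }
    return sub


def write_edgelist(graph: nx.Graph, path, delimiter: str = "\t") -> None:
    """Write a graph as a two-column edge list (isolates are not preserved)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}{delimiter}{b}\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_expression_matrix(path, label_column: str | None = None,
                           sample_column: str | None = None,
                           delimiter: str | None = None) -> ExpressionDataset:
    """Read a samples x genes delimited table with a gene-symbol header.

    The first row is the header. ``sample_column`` (if given) supplies sample
    ids, and ``label_column`` a categorical phenotype per sample; all other
    columns are genes and must be numeric.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file")
        delim = delimiter or _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        rows = list(csv.reader(fh, delimiter=delim))

    special = {}
    for colname in (sample_column, label_column):
        if colname is not None:
            if colname not in header:
                raise ParseError(f"{path}: column {colname!r} not in header")
            special[colname] = header.index(colname)
    gene_cols = [i for i, name in enumerate(header) if i not in special.values()]
    gene_names = [header[i] for i in gene_cols]
    if len(set(gene_names)) != len(gene_names):
        dupes = sorted({g for g in gene_names if gene_names.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene names in header: {dupes}")

    values = np.empty((len(rows), len(gene_cols)), dtype=float)
    sample_ids, labels = [], []
    for r, row in enumerate(rows):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: row {r + 2} has {len(row)} fields, header has "
                f"{len(header)}"
            )
        for j, i in enumerate(gene_cols):
            try:
                values[r, j] = float(row[i])
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {row[i]!r} at row {r + 2}, "
                    f"column {header[i]!r}"
                ) from None
        sample_ids.append(
            row[special[sample_column]] if sample_column else f"sample_{r + 1}"
        )
        if label_column:
            labels.append(row[special[label_column]])
    return ExpressionDataset(
        values=values,
        gene_names=gene_names,
        sample_ids=sample_ids,
        labels=np.asarray(labels, dtype=object) if label_column else None,
    )


def write_expression_matrix(dataset: ExpressionDataset, path,
                            delimiter: str = ",",
                            label_column: str = "label",
                            sample_column: str = "sample_id") -> None:
    """Write an expression dataset in the format ``read_expression_matrix`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        header = [sample_column] + list(dataset.gene_names)
        if dataset.labels is not None:
            header.append(label_column)
        writer.writerow(header)
        for r in range(dataset.n_samples):
            row = [dataset.sample_ids[r]] + [repr(float(v))
                                             for v in dataset.values[r]]
            if dataset.labels is not None:
                row.append(dataset.labels[r])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# cluster files
# ---------------------------------------------------------------------------


def write_clusters(clustering: Clustering, path) -> None:
    """One cluster per line: name, then tab-separated member identifiers."""
    with open(path, "w") as fh:
        for name, members in clustering:
            fh.write("\t".join([name] + sorted(members)) + "\n")


def read_clusters(path, algorithm: str = "") -> Clustering:
    """Exact inverse of :func:`write_clusters`."""
    clusters = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name, members = fields[0], fields[1:]
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate cluster "
                                 f"name {name!r}")
            if not members:
                raise ParseError(f"{path}: line {lineno}: cluster {name!r} "
                                 "has no members")
            seen.add(name)
            clusters.append((name, frozenset(members)))
    return Clustering(clusters=clusters, algorithm=algorithm)
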