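"""Bipartite gene→complex factor graphs and random-structure controls.

The factor graph records which genes feed which complex-activity units and
therefore defines the sparsity mask of the predictive model's first layer.
Edge counting here is the model's parameter accounting: a clustered factor
graph has Σ_i |c_i| edges, against k × l for its fully connected counterpart.

Two randomized controls are provided: ``random_factor_graph_R`` draws both
the number of complexes l (uniform on [30, 6000]) and the number of
membership edges u (uniform on [1, l·k]), while ``random_factor_graph_M``
keeps a template's (l, u) and re-draws only the membership edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Clustering, ParseError

__all__ = [
    "FactorGraph",
    "build_factor_graph",
    "count_edges",
    "fc_edge_count",
    "random_factor_graph_R",
    "random_factor_graph_M",
    "write_factor_graph",
    "read_factor_graph",
]


@dataclass
class FactorGraph:
    """Bipartite membership structure between genes and complexes.

    ``memberships`` is a set of (gene, complex) pairs; ``origin`` records how
    the structure was produced (clustered | random_R | random_M |
    fully_connected).
    """

    gene_index: list
    complex_names: list
    memberships: set
    origin: str = "clustered"
    _gene_pos: dict = field(init=False, repr=False)
    _complex_pos: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.gene_index = list(self.gene_index)
        self.complex_names = list(self.complex_names)
        if len(self.complex_names) < 1:
            raise ValueError("a factor graph needs at least one complex")
        if len(set(self.gene_index)) != len(self.gene_index):
            raise ValueError("gene_index entries must be unique")
        if len(set(self.complex_names)) != len(self.complex_names):
            raise ValueError("complex names must be unique")
        self._gene_pos = {g: i for i, g in enumerate(self.gene_index)}
        self._complex_pos = {c: j for j, c in enumerate(self.complex_names)}
        self.memberships = set(self.memberships)
        for g, c in self.memberships:
            if g not in self._gene_pos:
                raise ValueError(f"membership gene {g!r} not in gene_index")
            if c not in self._complex_pos:
                raise ValueError(f"membership complex {c!r} unknown")

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_complexes(self) -> int:
        return len(self.complex_names)

    @property
    def n_edges(self) -> int:
        return len(self.memberships)

    def mask(self) -> np.ndarray:
        """Boolean k × l membership mask (genes as rows)."""
        m = np.zeros((self.n_genes, self.n_complexes), dtype=bool)
        for g, c in self.memberships:
            m[self._gene_pos[g], self._complex_pos[c]] = True
        return m

    def complex_members(self, name: str) -> set:
        return {g for g, c in self.memberships if c == name}


def build_factor_graph(clustering: Clustering, gene_index) -> FactorGraph:
    """One complex node per cluster, one membership edge per (member,
    cluster) pair; genes in no cluster keep their position but have no edges.
    """
    if len(clustering) == 0:
        raise ValueError(
            "empty clustering: no factor graph (and hence no model) can be "
            "built"
        )
    gene_index = list(gene_index)
    known = set(gene_index)
    memberships = set()
    for name, members in clustering:
        for g in members:
            if g not in known:
                raise ValueError(
                    f"cluster {name!r} member {g!r} is not in the gene index"
                )
            memberships.add((g, name))
    return FactorGraph(
        gene_index=gene_index,
        complex_names=clustering.names,
        memberships=memberships,
        origin="clustered",
    )


def count_edges(fg: FactorGraph) -> int:
    """Number of membership edges — the first-layer parameter count (biases
    excluded)."""
    return fg.n_edges


def fc_edge_count(k: int, l: int) -> int:
    """Edge count k × l of the fully connected bipartite counterpart."""
    if k < 0 or l < 0:
        raise ValueError("k and l must be non-negative")
    return int(k) * int(l)


def _place_random_memberships(gene_index, complex_names, u: int,
                              rng: np.random.Generator) -> set:
    k, l = len(gene_index), len(complex_names)
    flat = rng.choice(k * l, size=u, replace=False, shuffle=False)
    return {(gene_index[i // l], complex_names[i % l]) for i in flat}


def random_factor_graph_R(gene_index, seed,
                          l_range: tuple = (30, 6000)) -> FactorGraph:
    """Fully random control: l ~ U[30, 6000] complexes (inclusive), then
    u ~ U[1, l·k] membership edges placed uniformly without replacement."""
    gene_index = list(gene_index)
    k = len(gene_index)
    if k < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    l = int(rng.integers(l_range[0], l_range[1] + 1))
    u = int(rng.integers(1, l * k + 1))
    names = [f"rc_{j + 1}" for j in range(l)]
    return FactorGraph(
        gene_index=gene_index,
        complex_names=names,
        memberships=_place_random_memberships(gene_index, names, u, rng),
        origin="random_R",
    )


def random_factor_graph_M(template: FactorGraph, seed) -> FactorGraph:
    """Matched control: keep the template's (l, u), re-draw the membership
    edges uniformly without replacement. Complexes that end up with zero
    members are permitted (their activity is constant)."""
    l, u = template.n_complexes, template.n_edges
    k = template.n_genes
    if u < 1:
        raise ValueError("template has no membership edges")
    if u > l * k:
        raise ValueError(f"cannot place {u} distinct edges on a {l}x{k} grid")
    rng = np.random.default_rng(seed)
    names = [f"rc_{j + 1}" for j in range(l)]
    return FactorGraph(
        gene_index=list(template.gene_index),
        complex_names=names,
        memberships=_place_random_memberships(
            template.gene_index, names, u, rng
        ),
        origin="random_M",
    )


# ---------------------------------------------------------------------------
# serialization: small header plus (gene, complex) pair lines
# ---------------------------------------------------------------------------


def write_factor_graph(fg: FactorGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#origin\t{fg.origin}\n")
        fh.write(f"#k\t{fg.n_genes}\n#l\t{fg.n_complexes}\n#u\t{fg.n_edges}\n")
        fh.write("#genes\t" + "\t".join(fg.gene_index) + "\n")
        fh.write("#complexes\t" + "\t".join(fg.complex_names) + "\n")
        for g, c in sorted(fg.memberships):
            fh.write(f"{g}\t{c}\n")


def read_factor_graph(path) -> FactorGraph:
    header, pairs = {}, set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if line.startswith("#"):
                header[fields[0][1:]] = fields[1:]
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns"
                )
            pairs.add((fields[0], fields[1]))
    for key in ("origin", "genes", "complexes"):
        if key not in header:
            raise ParseError(f"{path}: missing #{key} header line")
    return FactorGraph(
        gene_index=header["genes"],
        complex_names=header["complexes"],
        memberships=pairs,
        origin=header["origin"][0],
    )
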