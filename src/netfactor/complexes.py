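"""Deterministic overlapping protein-complex discovery on PPI graphs.

Implements four topological clustering algorithms from the protein-complex
prediction literature — MCODE, DPClus, IPCA and COACH — all of which allow a
protein to belong to several complexes and leave sparsely connected proteins
unassigned. Every algorithm is fully deterministic: there is no randomness
anywhere, and all ties are broken by (weight descending, degree descending,
identifier ascending).

Each algorithm is exposed both as a small estimator-style class
(``MCODE(vwp=0.2, ...).fit(graph)`` leaving the result in ``clusters_``) and
as a plain function (``mcode(graph, params)``).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx

from .io import Clustering

__all__ = [
    "MCODEParams", "DPClusParams", "IPCAParams", "COACHParams",
    "MCODE", "DPClus", "IPCA", "COACH",
    "mcode", "dpclus", "ipca", "coach",
    "ClusterStats", "cluster_stats",
    "neighbourhood_affinity", "match_score",
]


def density(graph: nx.Graph) -> float:
    """Edge density 2|E| / (|V|(|V|-1)); a single node has density 1.0."""
    n = graph.number_of_nodes()
    if n <= 1:
        return 1.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _subset_density(graph: nx.Graph, nodes) -> float:
    return density(graph.subgraph(nodes))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class MCODEParams:
    """MCODE defaults from the original molecular-complex-detection method."""
    vwp: float = 0.2          # vertex weight percentage for seeded growth
    haircut: bool = True      # iteratively strip degree-1 members
    fluff: bool = False       # add densely attached neighbours (creates overlap)
    fluff_density: float = 0.2
    min_size: int = 3

    def validate(self):
        if not 0.0 <= self.vwp <= 1.0:
            raise ValueError("vwp must be in [0, 1]")
        if not 0.0 <= self.fluff_density <= 1.0:
            raise ValueError("fluff_density must be in [0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class DPClusParams:
    d_min: float = 0.9        # minimum cluster density during growth
    cp_min: float = 0.5       # minimum cluster property cp(v)
    min_size: int = 2
    mode: str = "overlapping"  # "overlapping" removes internal edges only;
                               # "partition" removes member nodes

    def validate(self):
        if not 0.0 <= self.d_min <= 1.0:
            raise ValueError("d_min must be in [0, 1]")
        if self.cp_min < 0:
            raise ValueError("cp_min must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.mode not in ("overlapping", "partition"):
            raise ValueError("mode must be 'overlapping' or 'partition'")


@dataclass
class IPCAParams:
    t_in: float = 0.5         # minimum interaction probability to join
    d_max: int = 2            # maximum cluster diameter
    min_size: int = 2

    def validate(self):
        if not 0.0 <= self.t_in <= 1.0:
            raise ValueError("t_in must be in [0, 1]")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class COACHParams:
    core_density: float = 0.7
    affinity_threshold: float = 0.225  # NA threshold for redundant cores
    min_size: int = 3

    def validate(self):
        if not 0.0 <= self.core_density <= 1.0:
            raise ValueError("core_density must be in [0, 1]")
        if not 0.0 <= self.affinity_threshold <= 1.0:
            raise ValueError("affinity_threshold must be in [0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


# ---------------------------------------------------------------------------
# shared weighting used by DPClus and IPCA
# ---------------------------------------------------------------------------


def _common_neighbour_weights(graph: nx.Graph):
    """Edge weight = number of common neighbours; node weight = sum over
    incident edges."""
    edge_w = {}
    node_w = {v: 0 for v in graph}
    adj = {v: set(graph[v]) for v in graph}
    for u, v in graph.edges:
        w = len(adj[u] & adj[v])
        edge_w[frozenset((u, v))] = w
        node_w[u] += w
        node_w[v] += w
    return edge_w, node_w


def _priority_order(graph: nx.Graph, node_w: dict, nodes):
    """Sort by (weight desc, degree desc, identifier asc)."""
    return sorted(nodes, key=lambda v: (-node_w[v], -graph.degree(v), v))


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------


def _mcode_vertex_weights(graph: nx.Graph) -> dict:
    """weight(v) = k * density of the highest k-core of v's closed
    neighbourhood subgraph."""
    weights = {}
    for v in graph:
        nbhd = graph.subgraph(set(graph[v]) | {v})
        if nbhd.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_numbers = nx.core_number(nbhd)
        k = max(core_numbers.values())
        core = nbhd.subgraph(
            [u for u, c in core_numbers.items() if c >= k]
        )
        weights[v] = k * density(core)
    return weights


def mcode(graph: nx.Graph, params: MCODEParams | None = None) -> Clustering:
    """MCODE: k-core based vertex weighting, seeded greedy growth, and
    haircut/fluff post-processing.

    Growth from the heaviest unassigned seed proceeds breadth-first, adding
    neighbours whose weight is at least ``(1 - vwp)`` of the seed weight;
    each vertex joins at most one grown cluster. Fluff (off by default) is
    the step that can create overlapping complexes.
    """
    params = params or MCODEParams()
    params.validate()
    weights = _mcode_vertex_weights(graph)
    order = sorted(graph, key=lambda v: (-weights[v], -graph.degree(v), v))
    assigned = set()
    grown = []  # (seed weight, seed, member set)
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = (1.0 - params.vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(graph[u]):
                    if w in assigned or w in members:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        assigned |= members
        grown.append((weights[seed], seed, members))

    clusters = []
    for _, seed, members in grown:
        members = set(members)
        if params.haircut:
            while True:
                sub = graph.subgraph(members)
                strip = [v for v in members if sub.degree(v) <= 1]
                if not strip or len(members) <= len(strip):
                    members -= set(strip)
                    break
                members -= set(strip)
        if params.fluff and members:
            extras = set()
            boundary = {w for v in members for w in graph[v]} - members
            for w in sorted(boundary):
                nbhd = graph.subgraph(set(graph[w]) | {w})
                if density(nbhd) > params.fluff_density:
                    extras.add(w)
            members |= extras
        if len(members) >= params.min_size:
            clusters.append(members)

    return Clustering(
        clusters=[(f"mcode_{i + 1}", frozenset(m))
                  for i, m in enumerate(clusters)],
        algorithm="mcode",
        params=asdict(params),
    )


# ---------------------------------------------------------------------------
# DPClus
# ---------------------------------------------------------------------------


def dpclus(graph: nx.Graph, params: DPClusParams | None = None) -> Clustering:
    """DPClus: common-neighbour weighting, density/cluster-property growth.

    The seed is the node with the highest weight (sum of incident
    common-neighbour edge weights). Neighbours are added by priority (edges
    into the cluster, then node weight, then identifier) while the extended
    cluster keeps density >= ``d_min`` and the candidate's cluster property
    cp(v) = |edges(v, cluster)| / (density * |cluster|) stays >= ``cp_min``.
    After a cluster is emitted, its internal edges (default) or its member
    nodes ("partition" mode) are removed, weights are recomputed, and the
    process repeats until no edges remain.
    """
    params = params or DPClusParams()
    params.validate()
    work = graph.copy()
    clusters = []
    while work.number_of_edges() > 0:
        _, node_w = _common_neighbour_weights(work)
        candidates = [v for v in work if work.degree(v) > 0]
        seed = _priority_order(work, node_w, candidates)[0]
        members = {seed}
        while True:
            boundary = {}
            for v in members:
                for w in work[v]:
                    if w not in members:
                        boundary[w] = boundary.get(w, 0) + 1
            if not boundary:
                break
            cur_density = _subset_density(work, members)
            order = sorted(
                boundary,
                key=lambda v: (-boundary[v], -node_w[v], v),
            )
            added = None
            for v in order:
                cp = boundary[v] / (cur_density * len(members))
                if cp < params.cp_min:
                    continue
                if _subset_density(work, members | {v}) < params.d_min:
                    continue
                added = v
                break
            if added is None:
                break
            members.add(added)
        if len(members) >= params.min_size:
            clusters.append(set(members))
        # graph update guarantees termination: edge count strictly decreases
        internal = list(work.subgraph(members).edges)
        if params.mode == "partition":
            work.remove_nodes_from(members)
        elif internal:
            work.remove_edges_from(internal)
        else:
            work.remove_edges_from(list(work.edges(seed)))
    return Clustering(
        clusters=[(f"dpclus_{i + 1}", frozenset(m))
                  for i, m in enumerate(clusters)],
        algorithm="dpclus",
        params=asdict(params),
    )


# ---------------------------------------------------------------------------
# IPCA
# ---------------------------------------------------------------------------


def ipca(graph: nx.Graph, params: IPCAParams | None = None) -> Clustering:
    """IPCA: DPClus-style weights computed once, growth of small-diameter
    clusters.

    A vertex v joins the growing cluster when its interaction probability
    IP(v) = |edges(v, cluster)| / |cluster| is >= ``t_in`` and the extended
    cluster's diameter stays <= ``d_max``. Emitted members leave the seed
    queue but remain eligible to join later clusters, so complexes may
    overlap; weights are never recomputed.
    """
    params = params or IPCAParams()
    params.validate()
    _, node_w = _common_neighbour_weights(graph)
    queue = _priority_order(graph, node_w, graph.nodes)
    seeded = set()
    clusters = []
    for seed in queue:
        if seed in seeded or graph.degree(seed) == 0:
            continue
        members = {seed}
        while True:
            boundary = {}
            for v in members:
                for w in graph[v]:
                    if w not in members:
                        boundary[w] = boundary.get(w, 0) + 1
            order = sorted(
                boundary, key=lambda v: (-boundary[v], -node_w[v], v)
            )
            added = None
            for v in order:
                if boundary[v] / len(members) < params.t_in:
                    continue
                ext = graph.subgraph(members | {v})
                if nx.diameter(ext) > params.d_max:
                    continue
                added = v
                break
            if added is None:
                break
            members.add(added)
        if len(members) >= params.min_size:
            clusters.append(set(members))
            seeded |= members
        else:
            seeded.add(seed)
    return Clustering(
        clusters=[(f"ipca_{i + 1}", frozenset(m))
                  for i, m in enumerate(clusters)],
        algorithm="ipca",
        params=asdict(params),
    )


# ---------------------------------------------------------------------------
# COACH
# ---------------------------------------------------------------------------


def neighbourhood_affinity(a, b) -> float:
    """NA(A, B) = |A ∩ B|^2 / (|A| * |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def coach(graph: nx.Graph, params: COACHParams | None = None) -> Clustering:
    """COACH: core-attachment complex discovery.

    For each vertex v the preliminary core is v plus the neighbours whose
    degree within v's closed-neighbourhood subgraph is at least the average
    degree of that subgraph. Sparse cores (density < ``core_density``) are
    dropped, redundant cores (neighbourhood affinity >= the threshold) are
    collapsed keeping the denser, then larger, then lexicographically first.
    Any outside vertex adjacent to more than half of a core is attached.
    """
    params = params or COACHParams()
    params.validate()
    cores = []
    for v in sorted(graph):
        closed = set(graph[v]) | {v}
        nbhd = graph.subgraph(closed)
        if nbhd.number_of_edges() == 0:
            continue
        avg_deg = 2.0 * nbhd.number_of_edges() / nbhd.number_of_nodes()
        core = {v} | {u for u in graph[v] if nbhd.degree(u) >= avg_deg}
        d = _subset_density(graph, core)
        if d >= params.core_density:
            cores.append((frozenset(core), d))

    # redundant-core removal: keep the denser, then larger, then lexicographic
    cores.sort(key=lambda cd: (-cd[1], -len(cd[0]), tuple(sorted(cd[0]))))
    kept = []
    for core, d in cores:
        if all(neighbourhood_affinity(core, k) < params.affinity_threshold
               for k, _ in kept):
            kept.append((core, d))

    clusters, metas, seen = [], [], set()
    for core, _ in kept:
        attachments = set()
        boundary = {w for v in core for w in graph[v]} - core
        for u in sorted(boundary):
            if len(set(graph[u]) & core) > 0.5 * len(core):
                attachments.add(u)
        complex_ = frozenset(core | attachments)
        if len(complex_) < params.min_size or complex_ in seen:
            continue
        seen.add(complex_)
        clusters.append(complex_)
        metas.append(frozenset(core))
    return Clustering(
        clusters=[(f"coach_{i + 1}", m) for i, m in enumerate(clusters)],
        algorithm="coach",
        params=asdict(params),
        meta={f"coach_{i + 1}": {"core": core}
              for i, core in enumerate(metas)},
    )


# ---------------------------------------------------------------------------
# estimator-style wrappers
# ---------------------------------------------------------------------------


class _BaseClusterer:
    """Estimator-style wrapper: parameters at construction, ``fit(graph)``
    stores the resulting :class:`~netfactor.io.Clustering` in ``clusters_``."""

    _params_cls = None
    _func = None

    def __init__(self, **kwargs):
        self._params = self._params_cls(**kwargs)

    def get_params(self, deep: bool = True) -> dict:
        return asdict(self._params)

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if not hasattr(self._params, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self._params, key, value)
        return self

    def fit(self, graph: nx.Graph):
        self.clusters_ = type(self)._func(graph, self._params)
        return self

    def fit_predict(self, graph: nx.Graph) -> Clustering:
        return self.fit(graph).clusters_


class MCODE(_BaseClusterer):
    _params_cls = MCODEParams
    _func = staticmethod(mcode)


class DPClus(_BaseClusterer):
    _params_cls = DPClusParams
    _func = staticmethod(dpclus)


class IPCA(_BaseClusterer):
    _params_cls = IPCAParams
    _func = staticmethod(ipca)


class COACH(_BaseClusterer):
    _params_cls = COACHParams
    _func = staticmethod(coach)


ALGORITHMS = {"mcode": mcode, "dpclus": dpclus, "ipca": ipca, "coach": coach}
PARAM_CLASSES = {"mcode": MCODEParams, "dpclus": DPClusParams,
                 "ipca": IPCAParams, "coach": COACHParams}


# ---------------------------------------------------------------------------
# statistics and matching
# ---------------------------------------------------------------------------


@dataclass
class ClusterStats:
    n_clusters: int
    max_size: int
    min_size: int
    mean_size: float


def cluster_stats(clustering: Clustering, ndigits: int = 2) -> ClusterStats:
    """Count / max / min / arithmetic-mean cluster size; zeros when empty."""
    sizes = [len(m) for _, m in clustering]
    if not sizes:
        return ClusterStats(0, 0, 0, 0.0)
    return ClusterStats(
        n_clusters=len(sizes),
        max_size=max(sizes),
        min_size=min(sizes),
        mean_size=round(sum(sizes) / len(sizes), ndigits),
    )


def match_score(predicted: Clustering, reference: Clustering,
                omega: float = 0.25):
    """Precision-, recall-like recovery of reference complexes and their
    harmonic mean.

    A predicted cluster matches a reference cluster when their neighbourhood
    affinity NA(A, B) = |A ∩ B|^2 / (|A||B|) is at least ``omega``.
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must be in (0, 1]")
    if len(reference) == 0:
        raise ValueError("reference clustering is empty")
    pred = predicted.member_sets()
    ref = reference.member_sets()
    if not pred:
        return 0.0, 0.0, 0.0
    matched_pred = sum(
        1 for p in pred
        if any(neighbourhood_affinity(p, r) >= omega for r in ref)
    )
    matched_ref = sum(
        1 for r in ref
        if any(neighbourhood_affinity(p, r) >= omega for p in pred)
    )
    precision = matched_pred / len(pred)
    recall = matched_ref / len(ref)
    f = (0.0 if precision + recall == 0
         else 2 * precision * recall / (precision + recall))
    return precision, recall, f
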