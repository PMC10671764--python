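"""Maxwell-style multi-stage clustering (MAC) over a distance matrix.

The forward pass turns a pairwise distance matrix into clusters in four
stages:

1. *Triangle filtering* — every unordered triple of points defines a
   triangle with side lengths taken from the matrix; its area follows from
   Heron's formula.  Triangles whose area exceeds ``mean + sigma_filter *
   sd`` are outliers ("large and deformed"); an edge survives iff it
   belongs to at least one non-outlier triangle.
2. *First-of-first pruning* — mutual-kNN filtering of the surviving edges,
   with every node's single nearest surviving neighbor always kept so that
   no node is spuriously isolated.
3. *Local-minima partitioning* — within each connected component, nodes
   whose neighborhood contains no node closer to the component than
   themselves are local minima; components with several minima are split by
   assigning each node to its nearest minimum by shortest weighted path
   (a graph Voronoi partition), iterated to fixpoint.
4. *Singleton formation and final recall* — isolated nodes become
   singletons; the whole pipeline is re-run once on the singleton subset
   and any new clusters of size >= 2 are appended.

Clusters are summarized by a *multiset representative*: every member whose
summed distance to the other members is within ``tie_tol`` of the minimum.
The auto-correction backward pass deletes clusters whose multiset exceeds
``multiset_max`` (a symptom of diffuse, overgrown clusters) and
redistributes their members to the nearest surviving cluster, cycling to a
fixpoint.

All ties break lexicographically by label; the algorithm is deterministic
and permutation-equivariant.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .seqio import DistanceMatrix

__all__ = [
    "MACParams",
    "TriangleStats",
    "Cluster",
    "Clustering",
    "heron_area",
    "triangle_stats",
    "triangle_filter",
    "first_of_first_prune",
    "local_minima_partition",
    "best_representative",
    "forward_pass",
    "auto_correct",
    "mac_cluster",
    "clusters_to_newick",
    "MACClustering",
]


@dataclasses.dataclass(frozen=True)
class MACParams:
    """Tunable parameters of the clustering pipeline.

    sigma_filter : number of standard deviations above the mean triangle
        area beyond which a triangle is an outlier (one-sided).
    knn : neighborhood size for mutual-kNN pruning.
    tie_tol : absolute tolerance within which representative candidates are
        considered tied and enter the multiset.
    multiset_max : largest representative multiset a cluster may have before
        auto-correction deletes and redistributes it.
    max_cycles : cap on auto-correction cycles.
    """

    sigma_filter: float = 2.0
    knn: int = 1
    tie_tol: float = 1e-9
    multiset_max: int = 3
    max_cycles: int = 5

    def __post_init__(self) -> None:
        if self.sigma_filter <= 0:
            raise ValueError("sigma_filter must be positive")
        if self.knn < 1:
            raise ValueError("knn must be a positive integer")
        if self.tie_tol < 0:
            raise ValueError("tie_tol must be non-negative")
        if self.multiset_max < 1:
            raise ValueError("multiset_max must be a positive integer")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be a positive integer")


@dataclasses.dataclass(frozen=True)
class TriangleStats:
    """Heron areas over all unordered triples of a distance matrix."""

    areas: np.ndarray
    mean_area: float
    sd_area: float
    n_flagged_nonmetric: int


@dataclasses.dataclass(frozen=True)
class Cluster:
    """A cluster with its multiset of best-representative members.

    ``mean_radius`` is the mean distance of the members to the
    representative multiset (distance to the nearest multiset member, zero
    for the representatives themselves).
    """

    members: tuple[str, ...]
    representatives: tuple[str, ...]
    mean_radius: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if not set(self.representatives) <= set(self.members):
            raise ValueError("representatives must be members of the cluster")


@dataclasses.dataclass(frozen=True)
class Clustering:
    """A partition of the labels into clusters plus surviving singletons."""

    clusters: tuple[Cluster, ...]
    singletons: tuple[str, ...]
    cycles: tuple[str, ...]

    def all_labels(self) -> set[str]:
        out: set[str] = set(self.singletons)
        for c in self.clusters:
            out.update(c.members)
        return out

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "members": list(c.members),
                    "representatives": list(c.representatives),
                    "mean_radius": c.mean_radius,
                }
                for c in self.clusters
            ],
            "singletons": list(self.singletons),
            "cycles": list(self.cycles),
        }


def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from side lengths via the semi-perimeter.

    Non-metric triples (negative radicand) return 0; negative side lengths
    raise ``ValueError``.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError(f"side lengths must be non-negative, got ({a}, {b}, {c})")
    p = (a + b + c) / 2.0
    radicand = p * (p - a) * (p - b) * (p - c)
    if radicand < 0:
        return 0.0
    return math.sqrt(radicand)


def _triple_areas(V: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized Heron areas for all C(n,3) triples.

    Returns (triples, areas, n_nonmetric); triples is an (m, 3) index array.
    """
    n = V.shape[0]
    triples = np.array(list(itertools.combinations(range(n), 3)), dtype=int)
    if len(triples) == 0:
        return triples, np.empty(0), 0
    a = V[triples[:, 0], triples[:, 1]]
    b = V[triples[:, 1], triples[:, 2]]
    c = V[triples[:, 2], triples[:, 0]]
    p = (a + b + c) / 2.0
    radicand = p * (p - a) * (p - b) * (p - c)
    nonmetric = int(np.sum(radicand < 0))
    areas = np.sqrt(np.clip(radicand, 0.0, None))
    return triples, areas, nonmetric


def triangle_stats(D: DistanceMatrix) -> TriangleStats:
    """Heron areas of every unordered triple plus their mean and sd."""
    _, areas, nonmetric = _triple_areas(D.values)
    if len(areas) == 0:
        return TriangleStats(areas, 0.0, 0.0, nonmetric)
    return TriangleStats(areas, float(np.mean(areas)), float(np.std(areas)), nonmetric)


def triangle_filter(D: DistanceMatrix, sigma_filter: float = 2.0) -> nx.Graph:
    """Drop edges that only ever participate in outlier triangles.

    A triangle is an outlier iff its area exceeds ``mean + sigma_filter *
    sd`` over all triangles (one-sided: only large, deformed triangles are
    suspect).  The returned graph contains every label as a node and each
    retained edge weighted by its distance.  For n < 3 the complete graph
    is returned with a warning (no triangles to judge).
    """
    labels = D.labels
    n = len(labels)
    G = nx.Graph()
    G.add_nodes_from(labels)
    V = D.values
    if n < 3:
        warnings.warn("fewer than 3 points: triangle filter returns the complete graph")
        for i in range(n):
            for j in range(i + 1, n):
                G.add_edge(labels[i], labels[j], weight=V[i, j])
        return G
    triples, areas, _ = _triple_areas(V)
    threshold = float(np.mean(areas)) + sigma_filter * float(np.std(areas))
    keep = areas <= threshold
    retained: set[tuple[int, int]] = set()
    for (i, j, k) in triples[keep]:
        retained.add((i, j))
        retained.add((j, k))
        retained.add((i, k))
    for i, j in sorted(retained):
        G.add_edge(labels[i], labels[j], weight=V[i, j])
    return G


def first_of_first_prune(G: nx.Graph, D: DistanceMatrix, knn: int = 1) -> nx.Graph:
    """Neighborhood pruning: mutual-kNN plus structural safeguards.

    An edge (u, v) survives iff any of the following holds:

    - each endpoint is among the other's *knn* nearest retained neighbors
      (mutual-kNN, the "best" edges of well-connected nodes);
    - it is some node's single nearest retained neighbor edge (the
      "first-of-first" guarantee, preventing spurious isolation);
    - it is a *scale-consistent* relative-neighborhood edge: no third
      point w lies within the closed ball of radius d(u, v) around both
      endpoints (with at least one of the two distances strictly smaller),
      and the edge is no longer than twice the larger of its endpoints'
      nearest-neighbor distances.  The relative-neighborhood clause keeps
      genuine bridges inside elongated clusters — cutting through them is
      the job of the local-minima partition — while the scale gate stops
      it from retaining the one minimal link between well-separated
      groups, which is witness-free by definition but an order of
      magnitude longer than either endpoint's neighbor scale.

    Long edges between well-separated groups fail all three conditions
    (each endpoint has same-group witnesses closer to both ends) and are
    removed.  The pruning only ever removes edges present in *G*.
    """
    idx = {lab: i for i, lab in enumerate(D.labels)}
    V = D.values

    def nearest(u: str, k: int) -> list[str]:
        nbrs = sorted(G.neighbors(u), key=lambda v: (V[idx[u], idx[v]], v))
        return nbrs[:k]

    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    topk = {u: set(nearest(u, knn)) for u in G.nodes}
    nn_dist = {
        u: (V[idx[u], idx[nearest(u, 1)[0]]] if G.degree(u) else 0.0)
        for u in G.nodes
    }
    all_idx = np.arange(len(D.labels))
    for u, v in G.edges:
        keep = v in topk[u] and u in topk[v]
        iu, iv = idx[u], idx[v]
        d_uv = V[iu, iv]
        if not keep and d_uv <= 2.0 * max(nn_dist[u], nn_dist[v]):
            du, dv = V[iu, all_idx], V[iv, all_idx]
            witness = (du <= d_uv) & (dv <= d_uv) & ((du < d_uv) | (dv < d_uv))
            witness[[iu, iv]] = False
            keep = not bool(np.any(witness))
        if keep:
            H.add_edge(u, v, weight=G.edges[u, v]["weight"])
    for u in G.nodes:
        first = nearest(u, 1)
        if first:
            v = first[0]
            H.add_edge(u, v, weight=G.edges[u, v]["weight"])
    return H


def _mean_dist_to_group(u: str, group: list[str], idx: dict[str, int], V: np.ndarray) -> float:
    others = [idx[v] for v in group if v != u]
    if not others:
        return 0.0
    return float(np.mean(V[idx[u], others]))


def local_minima_partition(G: nx.Graph, D: DistanceMatrix) -> list[list[str]]:
    """Split components until each contains exactly one local minimum.

    A node is minimum-eligible iff no graph neighbor has a strictly
    smaller mean distance to the component.  Adjacent eligible nodes with
    *equal* means merge into a single plateau (otherwise any exact-tie
    configuration — equidistant points, symmetric pairs — would declare
    every node a minimum and shatter into singletons).  Components with
    several minima/plateaus are partitioned by a graph Voronoi rule: each
    node joins the minimum with the shortest weighted path distance (to
    the nearest plateau member), ties going to the plateau with the
    lexicographically smallest label.  Splitting repeats, with means
    recomputed on each sub-component, until stable.
    """
    idx = {lab: i for i, lab in enumerate(D.labels)}
    V = D.values
    final: list[list[str]] = []
    work = [sorted(comp) for comp in nx.connected_components(G)]
    while work:
        comp = work.pop()
        if len(comp) <= 1:
            final.append(comp)
            continue
        sub = G.subgraph(comp)
        means = {u: _mean_dist_to_group(u, comp, idx, V) for u in comp}
        eligible = {
            u for u in comp if all(means[v] >= means[u] for v in sub.neighbors(u))
        }
        # merge adjacent equal-mean eligible nodes into plateaus
        P = nx.Graph()
        P.add_nodes_from(eligible)
        for u in eligible:
            for v in sub.neighbors(u):
                if v in eligible and math.isclose(
                    means[u], means[v], rel_tol=0.0, abs_tol=1e-12
                ):
                    P.add_edge(u, v)
        plateaus = [sorted(p) for p in nx.connected_components(P)]
        if len(plateaus) <= 1:
            final.append(comp)
            continue
        # graph Voronoi: nearest plateau by shortest weighted path, where
        # distance to a plateau is the min over its members
        dist_from: dict[str, dict[str, float]] = {}
        for p in plateaus:
            acc: dict[str, float] = {}
            for src in p:
                for u, d in nx.single_source_dijkstra_path_length(
                    sub, src, weight="weight"
                ).items():
                    acc[u] = min(acc.get(u, math.inf), d)
            dist_from[p[0]] = acc
        reps = sorted(p[0] for p in plateaus)
        assignment: dict[str, str] = {}
        for u in comp:
            assignment[u] = min(
                reps, key=lambda m: (dist_from[m].get(u, math.inf), m)
            )
        groups: dict[str, list[str]] = {}
        for u in sorted(comp):
            groups.setdefault(assignment[u], []).append(u)
        parts = [sorted(g) for g in groups.values()]
        if len(parts) == 1:  # all nodes drawn to one plateau: stable
            final.append(comp)
            continue
        # sub-components may be disconnected after the cut; reconnect via
        # induced subgraphs and iterate
        for part in parts:
            for sub_comp in nx.connected_components(G.subgraph(part)):
                work.append(sorted(sub_comp))
    return sorted(final)


def best_representative(
    members: list[str] | tuple[str, ...], D: DistanceMatrix, tie_tol: float = 1e-9
) -> tuple[str, ...]:
    """Medoid multiset: members minimizing summed distance to the others.

    Every member whose sum is within *tie_tol* of the minimum enters the
    multiset (sorted lexicographically).
    """
    if not members:
        raise ValueError("cannot pick a representative of an empty member set")
    idx = {lab: i for i, lab in enumerate(D.labels)}
    V = D.values
    sums = {}
    for u in members:
        sums[u] = float(sum(V[idx[u], idx[v]] for v in members if v != u))
    lo = min(sums.values())
    return tuple(sorted(u for u, s in sums.items() if s <= lo + tie_tol))


def _dist_to_multiset(u: str, reps: tuple[str, ...], idx: dict[str, int], V: np.ndarray) -> float:
    if u in reps:
        return 0.0
    return float(min(V[idx[u], idx[r]] for r in reps))


def _make_cluster(members: list[str], D: DistanceMatrix, tie_tol: float) -> Cluster:
    idx = {lab: i for i, lab in enumerate(D.labels)}
    reps = best_representative(members, D, tie_tol)
    radius = float(
        np.mean([_dist_to_multiset(u, reps, idx, D.values) for u in members])
    )
    return Cluster(tuple(sorted(members)), reps, radius)


def _forward_once(D: DistanceMatrix, params: MACParams) -> tuple[list[list[str]], list[str]]:
    """One run of filter -> prune -> partition; returns (groups>=2, singles)."""
    G = triangle_filter(D, params.sigma_filter)
    G = first_of_first_prune(G, D, params.knn)
    parts = local_minima_partition(G, D)
    groups = [p for p in parts if len(p) >= 2]
    singles = sorted(u for p in parts if len(p) == 1 for u in p)
    return groups, singles


def forward_pass(D: DistanceMatrix, params: MACParams | None = None) -> Clustering:
    """Full forward pass: pipeline plus one final recall on the singletons."""
    params = params or MACParams()
    if D.n < 2:
        raise ValueError("need at least 2 points to cluster")
    groups, singles = _forward_once(D, params)
    log = [f"forward: {len(groups)} clusters, {len(singles)} singletons"]
    if len(singles) >= 2:
        recalled, singles2 = _forward_once(D.submatrix(singles), params)
        if recalled:
            groups.extend(recalled)
            singles = singles2
        log.append(f"recall: {len(recalled)} new clusters, {len(singles)} singletons")
    clusters = tuple(_make_cluster(g, D, params.tie_tol) for g in sorted(groups))
    return Clustering(clusters, tuple(sorted(singles)), tuple(log))


def auto_correct(C: Clustering, D: DistanceMatrix, params: MACParams | None = None) -> Clustering:
    """Backward-pass auto-correction of overgrown clusters.

    Clusters whose representative multiset exceeds ``multiset_max`` are
    deleted and their members redistributed to the surviving cluster with
    the nearest representative multiset (to singletons if none survives).
    Repeats until a fixpoint or ``max_cycles``.
    """
    params = params or MACParams()
    idx = {lab: i for i, lab in enumerate(D.labels)}
    V = D.values
    clusters = list(C.clusters)
    singletons = list(C.singletons)
    log = list(C.cycles)
    for cycle in range(params.max_cycles):
        overgrown = [c for c in clusters if len(c.representatives) > params.multiset_max]
        if not overgrown:
            break
        kept = [c for c in clusters if c not in overgrown]
        survivors = [list(c.members) for c in kept]
        survivor_reps = [c.representatives for c in kept]
        orphans = sorted(u for c in overgrown for u in c.members)
        for u in orphans:
            if not survivors:
                singletons.append(u)
                continue
            best_i = min(
                range(len(survivors)),
                key=lambda i: (
                    _dist_to_multiset(u, survivor_reps[i], idx, V),
                    survivor_reps[i],
                ),
            )
            survivors[best_i].append(u)
        clusters = [_make_cluster(sorted(m), D, params.tie_tol) for m in survivors]
        log.append(
            f"auto-correct cycle {cycle + 1}: deleted {len(overgrown)}, "
            f"redistributed {len(orphans)}"
        )
    return Clustering(tuple(clusters), tuple(sorted(singletons)), tuple(log))


def mac_cluster(D: DistanceMatrix, params: MACParams | None = None) -> Clustering:
    """Forward pass followed by auto-correction (the full pipeline)."""
    params = params or MACParams()
    return auto_correct(forward_pass(D, params), D, params)


# ---------------------------------------------------------------------------
# Newick export

def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _linkage_newick(labels: list[str], V: np.ndarray) -> tuple[str, float]:
    """Average-linkage subtree over the given labels; returns (newick, height)."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    k = len(labels)
    if k == 1:
        return _quote(labels[0]), 0.0
    sub = V.copy()
    np.fill_diagonal(sub, 0.0)
    Z = average(squareform(sub, checks=False))
    nodes: dict[int, tuple[str, float]] = {i: (_quote(labels[i]), 0.0) for i in range(k)}
    for step, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0  # ultrametric display height
        (na, ha), (nb, hb) = nodes[a], nodes[b]
        text = f"({na}:{max(h - ha, 0.0):.6f},{nb}:{max(h - hb, 0.0):.6f})"
        nodes[k + step] = (text, h)
    return nodes[2 * k - 2]


def clusters_to_newick(C: Clustering, D: DistanceMatrix) -> str:
    """Render a clustering as a Newick tree.

    Within each cluster, members are agglomerated by average linkage on the
    distance submatrix; clusters are then agglomerated by average linkage
    on the mean pairwise distance between their representative multisets;
    singletons attach at the root.
    """
    idx = {lab: i for i, lab in enumerate(D.labels)}
    V = D.values
    subtrees: list[tuple[str, float]] = []
    for c in C.clusters:
        members = list(c.members)
        sub = V[np.ix_([idx[u] for u in members], [idx[u] for u in members])]
        subtrees.append(_linkage_newick(members, sub))
    if len(subtrees) >= 2:
        k = len(subtrees)
        reps = [c.representatives for c in C.clusters]
        M = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                pairs = [V[idx[a], idx[b]] for a in reps[i] for b in reps[j]]
                M[i, j] = M[j, i] = float(np.mean(pairs))
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        Z = average(squareform(M, checks=False))
        nodes: dict[int, tuple[str, float]] = dict(enumerate(subtrees))
        for step, (a, b, dist, _) in enumerate(Z):
            a, b = int(a), int(b)
            h = dist / 2.0
            (na, ha), (nb, hb) = nodes[a], nodes[b]
            text = f"({na}:{max(h - ha, 0.0):.6f},{nb}:{max(h - hb, 0.0):.6f})"
            nodes[k + step] = (text, h)
        top, top_h = nodes[2 * k - 2]
    elif len(subtrees) == 1:
        top, top_h = subtrees[0]
    else:
        top, top_h = "", 0.0

    singleton_parts = [_quote(s) for s in C.singletons]
    if top and singleton_parts:
        root_h = top_h * 1.1 if top_h > 0 else 1.0
        parts = [f"{top}:{root_h - top_h:.6f}"] + [
            f"{s}:{root_h:.6f}" for s in singleton_parts
        ]
        return "(" + ",".join(parts) + ");"
    if top:
        if top.startswith("("):
            return top + ";"
        return top + ";"
    if len(singleton_parts) == 1:
        return singleton_parts[0] + ";"
    if singleton_parts:
        return "(" + ",".join(singleton_parts) + ");"
    raise ValueError("empty clustering: nothing to render")


# ---------------------------------------------------------------------------
# sklearn estimator

class MACClustering(ClusterMixin, BaseEstimator):
    """Maxwell-style clustering as a scikit-learn estimator.

    Operates on a precomputed square distance matrix (e.g. the output of
    :class:`~ncdclust.ncd.NCDTransformer.fit_transform`).  After ``fit``:

    - ``labels_`` : integer cluster index per sample, -1 for singletons;
    - ``clustering_`` : the full :class:`Clustering` with member names,
      representative multisets, radii and the cycle log.

    Parameters mirror :class:`MACParams`; ``run_auto_correct`` toggles the
    backward pass.
    """

    def __init__(
        self,
        sigma_filter: float = 2.0,
        knn: int = 1,
        tie_tol: float = 1e-9,
        multiset_max: int = 3,
        max_cycles: int = 5,
        run_auto_correct: bool = True,
    ):
        self.sigma_filter = sigma_filter
        self.knn = knn
        self.tie_tol = tie_tol
        self.multiset_max = multiset_max
        self.max_cycles = max_cycles
        self.run_auto_correct = run_auto_correct

    def _params(self) -> MACParams:
        return MACParams(
            sigma_filter=self.sigma_filter,
            knn=self.knn,
            tie_tol=self.tie_tol,
            multiset_max=self.multiset_max,
            max_cycles=self.max_cycles,
        )

    def fit(self, X, y=None, names: list[str] | None = None) -> "MACClustering":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("MACClustering expects a precomputed square distance matrix")
        n = X.shape[0]
        if names is None:
            width = len(str(n - 1))
            names = [f"s{str(i).zfill(width)}" for i in range(n)]
        D = DistanceMatrix(list(names), 0.5 * (X + X.T))
        params = self._params()
        clustering = forward_pass(D, params)
        if self.run_auto_correct:
            clustering = auto_correct(clustering, D, params)
        self.clustering_ = clustering
        name_to_cluster = {}
        for ci, c in enumerate(clustering.clusters):
            for u in c.members:
                name_to_cluster[u] = ci
        self.labels_ = np.array([name_to_cluster.get(nm, -1) for nm in names], dtype=int)
        self.n_clusters_ = len(clustering.clusters)
        return self

    def fit_predict(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, **kwargs).labels_
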