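"""Twelve per-node centrality features of a patient similarity network.

Column order is fixed: weighted_degree, closeness, current_flow_closeness,
current_flow_betweenness, eigenvector, katz, hits, pagerank, load,
local_clustering, iterative_weighted_degree, iterative_local_clustering.

Conventions (the network is a complete weighted graph, weights in [0, 1]):

* shortest-path metrics (closeness, load) use distance = 1 / weight;
  zero-weight pairs are treated as absent edges;
* flow and spectral metrics (current-flow pair, eigenvector, Katz, HITS,
  pagerank) use the weight directly as conductance / affinity;
* the local clustering coefficient is the weighted geometric-mean (Onnela)
  variant;
* iterative variants repeatedly record the most central node's value, remove
  it, and recompute on the shrinking graph; ties break by ascending
  patient id.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .datatypes import PatientSimilarityNetwork, TopoFeatureSet, ValidationError

logger = logging.getLogger(__name__)

CENTRALITY_COLUMNS = (
    "weighted_degree",
    "closeness",
    "current_flow_closeness",
    "current_flow_betweenness",
    "eigenvector",
    "katz",
    "hits",
    "pagerank",
    "load",
    "local_clustering",
    "iterative_weighted_degree",
    "iterative_local_clustering",
)


def _to_graph(psn: PatientSimilarityNetwork) -> nx.Graph:
    """Weighted graph with 1/w distances; zero-weight pairs are non-edges."""
    if psn.w.min() < 0:
        raise ValidationError("negative edge weight: cannot form distances")
    g = nx.Graph()
    g.add_nodes_from(psn.patient_ids)
    ids = psn.patient_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        w = psn.w[i, j]
        if w > 0:
            g.add_edge(ids[i], ids[j], weight=float(w), dist=float(1.0 / w))
    return g


def weighted_local_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela geometric-mean weighted clustering coefficient per node.

    Weights are normalized by the maximum weight of the (sub)graph; the
    coefficient of a node with fewer than two neighbours is 0.
    """
    n = w.shape[0]
    if n == 0:
        return np.zeros(0)
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(n)
    what = np.cbrt(w / wmax)
    triangles = np.einsum("ij,jk,ki->i", what, what, what)
    deg = (w > 0).sum(axis=1).astype(float)
    denom = deg * (deg - 1.0)
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = triangles[ok] / denom[ok]
    return out


def iterative_centrality(psn: PatientSimilarityNetwork,
                         base: str = "weighted_degree") -> np.ndarray:
    """Value each node carried when it was the most central and was removed.

    At every iteration the base metric is recomputed on the surviving
    subgraph, the highest-scoring node (ties by ascending patient id) records
    its current value and is deleted; the last node keeps its value in the
    singleton graph (0 for both supported bases).
    """
    if base not in ("weighted_degree", "local_clustering"):
        raise ValidationError(f"unsupported base metric {base!r}")
    ids = psn.patient_ids
    n = len(ids)
    values = np.zeros(n)
    alive = list(range(n))
    while alive:
        sub = psn.w[np.ix_(alive, alive)]
        if base == "weighted_degree":
            scores = sub.sum(axis=1)
        else:
            scores = weighted_local_clustering(sub)
        top = scores.max()
        tied = [t for t in range(len(alive)) if scores[t] >= top - 1e-15]
        best = min(tied, key=lambda t: ids[alive[t]])
        node = alive[best]
        values[node] = scores[best]
        alive.pop(best)
    return values


def _principal_eigenvector(w: np.ndarray) -> np.ndarray:
    """Perron eigenvector of a symmetric non-negative matrix (deterministic).

    Dense ``eigh`` avoids the randomized starts of iterative eigensolvers so
    repeated runs are bit-identical.
    """
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return np.abs(v)


def _katz(w: np.ndarray) -> np.ndarray:
    lam = np.max(np.abs(np.linalg.eigvalsh(w)))
    if lam <= 0:
        return np.ones(w.shape[0]) / np.sqrt(w.shape[0])
    alpha = 0.9 / lam
    n = w.shape[0]
    x = np.linalg.solve(np.eye(n) - alpha * w, np.ones(n))
    return x / np.linalg.norm(x)


def compute_centralities(psn: PatientSimilarityNetwork,
                         standardize: bool = False) -> TopoFeatureSet:
    """All twelve centrality columns for one network (raw by default)."""
    if psn.n_patients < 2:
        raise ValidationError("centralities need at least 2 patients")
    g = _to_graph(psn)
    if not nx.is_connected(g):
        raise ValidationError("network is disconnected after removing "
                              "zero-weight pairs")
    ids = psn.patient_ids
    n = len(ids)

    def vec(d: dict) -> np.ndarray:
        return np.array([d[p] for p in ids], dtype=float)

    cols = np.empty((n, 12))
    cols[:, 0] = psn.w.sum(axis=1)
    cols[:, 1] = vec(nx.closeness_centrality(g, distance="dist"))
    cols[:, 2] = vec(nx.current_flow_closeness_centrality(g, weight="weight"))
    cols[:, 3] = vec(nx.current_flow_betweenness_centrality(g, weight="weight"))
    principal = _principal_eigenvector(psn.w)
    cols[:, 4] = principal / np.linalg.norm(principal)
    cols[:, 5] = _katz(psn.w)
    # HITS on an undirected graph: hub and authority scores coincide with
    # the principal eigenvector, conventionally normalized to unit sum
    cols[:, 6] = principal / principal.sum()
    cols[:, 7] = vec(nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-8,
                                 max_iter=1000))
    cols[:, 8] = vec(nx.load_centrality(g, weight="dist"))
    cols[:, 9] = weighted_local_clustering(psn.w)
    cols[:, 10] = iterative_centrality(psn, "weighted_degree")
    cols[:, 11] = iterative_centrality(psn, "local_clustering")

    fs = TopoFeatureSet(list(ids), list(CENTRALITY_COLUMNS), cols,
                        family="centrality", standardized=False)
    return standardize_features(fs) if standardize else fs


def standardize_features(fs: TopoFeatureSet) -> TopoFeatureSet:
    """Column-wise z-score; zero-variance columns become all-zero."""
    if len(fs.patient_ids) < 2:
        raise ValidationError("standardization needs at least 2 rows")
    values = fs.values.astype(float).copy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        names = [fs.feature_ids[j] for j in np.nonzero(degenerate)[0]]
        logger.warning("constant feature columns zeroed: %s", names[:10])
    sd_safe = np.where(degenerate, 1.0, sd)
    values = (values - mean) / sd_safe
    values[:, degenerate] = 0.0
    return TopoFeatureSet(list(fs.patient_ids), list(fs.feature_ids), values,
                          family=fs.family, standardized=True)
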