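"""Typed directed phenotype network: construction and structural summaries.

Nodes are ``(category, term)`` pairs; edges are typed by relation and carry a
support count (number of distinct supporting sentences).  Parallel edges of
the same (source, target, type) collapse into one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
from scipy import optimize, special

from phenonet.corpus import ENTITY_CATEGORIES, RELATION_TYPES

logger = logging.getLogger(__name__)

SCORE_THRESHOLD = 0.5


@dataclass(frozen=True)
class RelationRecord:
    """One extracted relation: the atom from which the network is built."""

    sentence_id: str
    source_term: str
    source_category: str
    target_term: str
    target_category: str
    relation_type: str
    score: float

    def __post_init__(self) -> None:
        if self.source_category not in ENTITY_CATEGORIES:
            raise ValueError(f"unknown category {self.source_category!r}")
        if self.target_category not in ENTITY_CATEGORIES:
            raise ValueError(f"unknown category {self.target_category!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def source(self) -> tuple[str, str]:
        return (self.source_category, self.source_term)

    @property
    def target(self) -> tuple[str, str]:
        return (self.target_category, self.target_term)


@dataclass
class DegreeFit:
    """Discrete power-law fit with a log-normal comparison."""

    alpha: float
    xmin: int
    n_tail: int
    ks_powerlaw: float
    ks_lognormal: float
    lognormal_mu: float
    lognormal_sigma: float
    loglik_ratio: float  # sum of pointwise log-likelihood differences (PL - LN)
    p_value: float  # Vuong-style normal approximation


def build_graph(records, min_score: float = SCORE_THRESHOLD) -> nx.MultiDiGraph:
    """Build the typed directed multigraph from a relation-record stream.

    One node per unique ``(category, term)``; one edge per (source, target,
    relation type), keyed by the relation type, with a ``support`` count of
    distinct supporting sentences.  Records scoring below ``min_score``,
    carrying an unknown relation type, or forming self-loops are excluded
    (logged).  Construction is order-invariant over the stream.
    """
    g = nx.MultiDiGraph()
    dropped = {"low_score": 0, "unknown_relation": 0, "self_loop": 0}
    support: dict[tuple, set[str]] = {}
    for rec in records:
        if rec.relation_type not in RELATION_TYPES:
            dropped["unknown_relation"] += 1
            continue
        if rec.score < min_score:
            dropped["low_score"] += 1
            continue
        if rec.source == rec.target:
            dropped["self_loop"] += 1
            continue
        support.setdefault((rec.source, rec.target, rec.relation_type), set()).add(
            rec.sentence_id
        )
    for (src, tgt, rel), sids in sorted(support.items()):
        g.add_node(src, category=src[0], term=src[1])
        g.add_node(tgt, category=tgt[0], term=tgt[1])
        g.add_edge(src, tgt, key=rel, relation_type=rel, support=len(sids))
    if any(dropped.values()):
        logger.info("build_graph dropped records: %s", dropped)
    return g


# ---------------------------------------------------------------------------
# Scale-free degree-distribution fitting
# ---------------------------------------------------------------------------


def power_law_alpha_mle(x: np.ndarray, xmin: int) -> float:
    """Maximum-likelihood exponent of a discrete power law on ``x >= xmin``."""
    x = np.asarray(x, dtype=float)
    s = np.log(x).sum()
    n = len(x)

    def nll(alpha: float) -> float:
        return n * np.log(special.zeta(alpha, xmin)) + alpha * s

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded")
    return float(res.x)


def _pl_pmf(k: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    return k.astype(float) ** -alpha / special.zeta(alpha, xmin)


def _discrete_lognormal_fit(x: np.ndarray, xmin: int) -> tuple[float, float, np.ndarray]:
    """MLE of a discrete log-normal on integers >= xmin; returns (mu, sigma, pmf_at_x)."""
    support = np.arange(xmin, max(int(x.max()) * 4, xmin + 50) + 1, dtype=float)
    logx = np.log(x)

    def nll(params) -> float:
        mu, sigma = params
        if sigma <= 0:
            return np.inf
        logw = -np.log(support) - (np.log(support) - mu) ** 2 / (2 * sigma**2)
        logz = special.logsumexp(logw)
        ll = (-logx - (logx - mu) ** 2 / (2 * sigma**2) - logz).sum()
        return -ll

    res = optimize.minimize(
        nll, x0=[float(np.mean(logx)), float(np.std(logx)) or 1.0], method="Nelder-Mead"
    )
    mu, sigma = res.x
    logw = -np.log(support) - (np.log(support) - mu) ** 2 / (2 * sigma**2)
    logz = special.logsumexp(logw)
    pmf_x = np.exp(-np.log(x) - (np.log(x) - mu) ** 2 / (2 * sigma**2) - logz)
    return float(mu), float(sigma), pmf_x


def _ks_distance(x: np.ndarray, pmf_fn, xmin: int) -> float:
    """Max distance between the empirical tail CDF and a discrete model CDF."""
    values = np.arange(xmin, int(x.max()) + 1)
    model_cdf = np.cumsum(pmf_fn(values))
    ecdf = np.searchsorted(np.sort(x), values, side="right") / len(x)
    return float(np.abs(ecdf - model_cdf).max())


def fit_power_law(
    degrees, xmin: int | None = None, min_tail: int = 10
) -> DegreeFit:
    """Clauset-style discrete power-law fit with KS-minimizing lower cutoff.

    When ``xmin`` is not given, every distinct degree value (with a tail of at
    least ``min_tail`` points) is tried and the one minimizing the KS distance
    between the tail data and the fitted model is kept.  A discrete log-normal
    alternative is fitted on the same tail and compared through a Vuong-style
    normalized likelihood-ratio test; positive ``loglik_ratio`` favours the
    power law.
    """
    x_all = np.asarray([d for d in degrees if d >= 1], dtype=np.int64)
    if len(x_all) < 2 or np.all(x_all == x_all[0]):
        raise ValueError("degenerate degree sequence: need at least two distinct degrees")
    if xmin is None:
        candidates = [
            int(v) for v in np.unique(x_all) if (x_all >= v).sum() >= min_tail
        ] or [int(x_all.min())]
        best = None
        for cand in candidates:
            tail = x_all[x_all >= cand]
            if len(np.unique(tail)) < 2:
                continue
            alpha = power_law_alpha_mle(tail, cand)
            ks = _ks_distance(tail, lambda v: _pl_pmf(v, alpha, cand), cand)
            if best is None or ks < best[0]:
                best = (ks, cand, alpha)
        if best is None:
            raise ValueError("no viable lower cutoff for the power-law fit")
        ks_pl, xmin, alpha = best
    else:
        tail = x_all[x_all >= xmin]
        alpha = power_law_alpha_mle(tail, xmin)
        ks_pl = _ks_distance(tail, lambda v: _pl_pmf(v, alpha, xmin), xmin)
    tail = x_all[x_all >= xmin]
    mu, sigma, ln_pmf_x = _discrete_lognormal_fit(tail, xmin)
    pl_pmf_x = _pl_pmf(tail.astype(float), alpha, xmin)
    diffs = np.log(np.maximum(pl_pmf_x, 1e-300)) - np.log(np.maximum(ln_pmf_x, 1e-300))
    ratio = float(diffs.sum())
    sd = float(diffs.std())
    if sd == 0:
        p = 1.0
    else:
        z = ratio / (sd * np.sqrt(len(diffs)))
        p = float(special.erfc(abs(z) / np.sqrt(2)))
    ks_ln = _ks_distance(
        tail, lambda v: _ln_pmf(v, mu, sigma, xmin, int(tail.max())), xmin
    )
    return DegreeFit(
        alpha=alpha,
        xmin=int(xmin),
        n_tail=int(len(tail)),
        ks_powerlaw=ks_pl,
        ks_lognormal=ks_ln,
        lognormal_mu=mu,
        lognormal_sigma=sigma,
        loglik_ratio=ratio,
        p_value=p,
    )


def _ln_pmf(values: np.ndarray, mu: float, sigma: float, xmin: int, xmax: int) -> np.ndarray:
    support = np.arange(xmin, max(xmax * 4, xmin + 50) + 1, dtype=float)
    logw = -np.log(support) - (np.log(support) - mu) ** 2 / (2 * sigma**2)
    logz = special.logsumexp(logw)
    v = np.asarray(values, dtype=float)
    return np.exp(-np.log(v) - (np.log(v) - mu) ** 2 / (2 * sigma**2) - logz)


def fit_degree_distribution(graph: nx.MultiDiGraph, direction: str = "in") -> DegreeFit:
    """Fit the in- or out-degree distribution of the graph to a discrete power law."""
    if direction == "in":
        degs = [d for _, d in graph.in_degree()]
    elif direction == "out":
        degs = [d for _, d in graph.out_degree()]
    else:
        raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    degs = [d for d in degs if d >= 1]
    if len(degs) < 100:
        logger.warning("fitting a power law on only %d positive degrees", len(degs))
    return fit_power_law(degs)


# ---------------------------------------------------------------------------
# Structural summaries
# ---------------------------------------------------------------------------


def component_stats(graph: nx.MultiDiGraph) -> tuple[float, float]:
    """(node fraction, edge fraction) of the largest weakly connected component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comp = max(nx.weakly_connected_components(graph), key=len)
    sub = graph.subgraph(comp)
    edge_total = graph.number_of_edges()
    return (
        sub.number_of_nodes() / graph.number_of_nodes(),
        (sub.number_of_edges() / edge_total) if edge_total else 1.0,
    )


def centrality_table(graph: nx.MultiDiGraph) -> dict:
    """Per node: in/out degree over typed (collapsed) edges and exact betweenness.

    Betweenness is computed on the unweighted directed simple projection
    (type multiplicity ignored), unnormalized.
    """
    simple = nx.DiGraph(graph)
    bc = nx.betweenness_centrality(simple, normalized=False)
    return {
        v: {
            "indegree": graph.in_degree(v),
            "outdegree": graph.out_degree(v),
            "betweenness": bc[v],
        }
        for v in graph.nodes
    }


def jaccard_pairs(graph: nx.MultiDiGraph, top_n: int = 10) -> list[tuple[tuple, tuple, float]]:
    """Top ``top_n`` node pairs by Jaccard similarity of their neighborhoods.

    The neighborhood of a node is the union of its in- and out-neighbors on
    the simple projection; for each pair the two pair members are excluded
    from both sets.  Only pairs sharing at least one neighbor are considered.
    Ordered by index descending, ties lexicographic.
    """
    simple = nx.DiGraph(graph)
    nbrs = {
        v: set(simple.predecessors(v)) | set(simple.successors(v)) for v in simple
    }
    candidates = set()
    for w, ns in nbrs.items():
        for u, v in itertools.combinations(sorted(ns), 2):
            candidates.add((u, v))
    scored = []
    for u, v in candidates:
        a = nbrs[u] - {u, v}
        b = nbrs[v] - {u, v}
        inter = a & b
        if not inter:
            continue
        scored.append((u, v, len(inter) / len(a | b)))
    scored.sort(key=lambda t: (-t[2], t[0], t[1]))
    return scored[:top_n]


def community_modularity(
    graph: nx.MultiDiGraph, seed: int = 0
) -> tuple[dict, float]:
    """Leiden partition of the undirected projection and its modularity.

    Returns a node -> community-id mapping and the modularity score.
    Deterministic for a fixed seed.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    und = nx.Graph()
    und.add_nodes_from(nodes)
    und.add_edges_from((u, v) for u, v, _ in graph.edges(keys=True) if u != v)
    g = ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in und.edges], directed=False
    )
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, seed=seed, n_iterations=2
    )
    membership = part.membership
    return {v: membership[index[v]] for v in nodes}, float(part.modularity)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def _node_id(node: tuple[str, str]) -> str:
    return f"{node[0]}:{node[1]}"


def to_edge_table(graph: nx.MultiDiGraph):
    """Edge list rows: (source, source_category, target, target_category, type, support)."""
    rows = []
    for u, v, k, data in graph.edges(keys=True, data=True):
        rows.append(
            {
                "source": u[1],
                "source_category": u[0],
                "target": v[1],
                "target_category": v[0],
                "relation_type": k,
                "support": data.get("support", 1),
            }
        )
    rows.sort(key=lambda r: (r["source"], r["target"], r["relation_type"]))
    return rows


def write_graphml(graph: nx.MultiDiGraph, path) -> None:
    """GraphML export with string node ids (``CATEGORY:term``)."""
    relabeled = nx.relabel_nodes(graph, {v: _node_id(v) for v in graph.nodes}, copy=True)
    nx.write_graphml(relabeled, path)


def subsample_edges(graph: nx.MultiDiGraph, n_edges: int, seed: int = 0) -> nx.MultiDiGraph:
    """Seeded random edge subsample (export/plotting utility only)."""
    edges = sorted(graph.edges(keys=True))
    rng = np.random.default_rng(seed)
    take = rng.choice(len(edges), size=min(n_edges, len(edges)), replace=False)
    sub = nx.MultiDiGraph()
    for i in sorted(take):
        u, v, k = edges[i]
        sub.add_node(u, **graph.nodes[u])
        sub.add_node(v, **graph.nodes[v])
        sub.add_edge(u, v, key=k, **graph.edges[u, v, k])
    return sub
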