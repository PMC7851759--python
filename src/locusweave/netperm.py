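"""Seed-network connectivity to a mendelian gene set, with a permutation null.

Given a scored protein-protein interaction graph, a candidate ("seed") gene
set and a mendelian disease gene set, a mendelian protein counts as
connected when it is reachable from a seed within two hops: either a direct
seed neighbour (first degree) or adjacent to a seed's interactor via an
inter-node.  Significance of the observed count is assessed against B
control networks whose seed sets are drawn uniformly without replacement
from a null pool of genes, with the add-one empirical p-value

    p_emp = (1 + #{null counts >= observed}) / (B + 1),

which can never be exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_B = 1000
#: Size of the null gene pool the control seed sets are drawn from (genes with
#: evidence against colocalization, PPH3 > 0.75, in the reference analysis).
NULL_POOL_SIZE = 118


@dataclass
class SeedNetwork:
    """The layered interactome around a seed set."""

    seeds: set
    first_degree: set
    internodes: set
    connected_mendelian: set


@dataclass
class PermutationResult:
    observed_count: int
    null_counts: np.ndarray
    p_emp: float
    B: int
    rng_seed: int
    null_pool: list = field(default_factory=list)


def read_edge_list(path, score_default: float = 1.0) -> nx.Graph:
    """Read a TSV edge list (proteinA, proteinB[, score]) into a scored graph.

    Self-loops are dropped; duplicate pairs keep the maximum score.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["a", "b", "score"], dtype={"a": str, "b": str})
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(score_default)
    G = nx.Graph()
    for r in df.itertuples():
        if r.a == r.b:
            continue
        if G.has_edge(r.a, r.b):
            G[r.a][r.b]["score"] = max(G[r.a][r.b]["score"], r.score)
        else:
            G.add_edge(r.a, r.b, score=r.score)
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b, d in G.edges(data=True):
            fh.write(f"{a}\t{b}\t{d.get('score', 1.0):.4f}\n")


def build_seed_network(graph: nx.Graph, seeds: set, mendelian: set,
                       score_min: float = 0.0, max_hops: int = 2) -> SeedNetwork:
    """Layered network around ``seeds`` after removing low-confidence edges.

    A mendelian protein is connected if adjacent to a seed (first degree) or,
    at ``max_hops`` = 2, adjacent to any first-degree interactor; the
    non-seed, non-mendelian bridging nodes are recorded as inter-nodes.
    Seeds absent from the graph are kept with zero degree (warned).
    """
    seeds, mendelian = set(seeds), set(mendelian)
    if not seeds:
        raise ValueError("empty seed set")
    overlap = seeds & mendelian
    if overlap:
        raise ValueError(f"seeds overlap the mendelian set: {sorted(overlap)}")
    if max_hops not in (1, 2):
        raise ValueError("max_hops must be 1 or 2")
    missing = seeds - set(graph.nodes)
    if missing:
        logger.warning("%d seed(s) absent from the graph (zero degree): %s",
                       len(missing), sorted(missing))

    def neighbors(node):
        if node not in graph:
            return ()
        return (v for v in graph[node]
                if graph[node][v].get("score", 1.0) >= score_min)

    first_degree = set()
    for s in seeds:
        first_degree.update(neighbors(s))
    first_degree -= seeds

    connected = mendelian & first_degree
    internodes = set()
    if max_hops == 2:
        for v in first_degree - mendelian:
            hits = mendelian & set(neighbors(v))
            if hits:
                connected |= hits
                internodes.add(v)
    internodes -= seeds | mendelian
    return SeedNetwork(seeds=seeds, first_degree=first_degree,
                       internodes=internodes, connected_mendelian=connected)


def count_mendelian_connections(net: SeedNetwork) -> int:
    """Number of distinct mendelian proteins connected to the seed network."""
    return len(net.connected_mendelian)


def _adjacency(graph: nx.Graph, score_min: float):
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b, d in graph.edges(data=True):
        if d.get("score", 1.0) >= score_min:
            adj[index[a], index[b]] = adj[index[b], index[a]] = True
    return adj, index


def permutation_test(graph: nx.Graph, observed_seeds: set, mendelian: set,
                     null_pool: list, B: int = DEFAULT_B, rng_seed: int = 0,
                     score_min: float = 0.0, max_hops: int = 2
                     ) -> PermutationResult:
    """Empirical permutation p-value for seed-to-mendelian connectivity.

    ``B`` control seed sets of size |observed_seeds| are drawn uniformly
    without replacement (within each set, independently across sets) from
    ``null_pool`` and scored exactly like the observed set.  Overlap between
    the pool and the observed seeds is permitted (needed when calibrating
    under the null) but logged.
    """
    observed_seeds = set(observed_seeds)
    null_pool = list(null_pool)
    if len(null_pool) < len(observed_seeds):
        raise ValueError("null pool smaller than the observed seed set")
    if observed_seeds & set(null_pool):
        logger.info("observed seeds overlap the null pool (%d shared)",
                    len(observed_seeds & set(null_pool)))
    rng = np.random.default_rng(rng_seed)

    observed = count_mendelian_connections(
        build_seed_network(graph, observed_seeds, mendelian,
                           score_min=score_min, max_hops=max_hops))

    adj, index = _adjacency(graph, score_min)
    mend_mask = np.zeros(len(index), dtype=bool)
    for m in mendelian:
        if m in index:
            mend_mask[index[m]] = True
    pool_idx = np.array([index[g] for g in null_pool if g in index])
    absent = len(null_pool) - len(pool_idx)
    if absent:
        logger.warning("%d null-pool gene(s) absent from the graph", absent)

    k = len(observed_seeds)
    null_counts = np.empty(B, dtype=int)
    for b in range(B):
        pick = rng.choice(pool_idx, size=min(k, len(pool_idx)), replace=False)
        neigh1 = adj[pick].any(axis=0)
        neigh1[pick] = False
        reach = neigh1.copy()
        if max_hops == 2:
            bridge = neigh1 & ~mend_mask
            if bridge.any():
                reach |= adj[bridge].any(axis=0)
        reach[pick] = False
        null_counts[b] = int((reach & mend_mask).sum())
    p_emp = (1.0 + int((null_counts >= observed).sum())) / (B + 1.0)
    return PermutationResult(observed_count=observed, null_counts=null_counts,
                             p_emp=p_emp, B=B, rng_seed=rng_seed,
                             null_pool=null_pool)


def result_to_json_dict(res: PermutationResult) -> dict:
    hist = np.bincount(res.null_counts)
    return {
        "observed_count": int(res.observed_count),
        "null_histogram": {str(i): int(c) for i, c in enumerate(hist) if c},
        "p_emp": res.p_emp,
        "B": res.B,
        "rng_seed": res.rng_seed,
    }
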