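"""Discrete dynamic-Bayesian-network scoring and structure search.

Variables are the (population, lag) columns of a binned-and-sliced table.
Lag-0 columns are the *effect* variables; every edge must point at one of
them.  Edges from lagged columns carry the Granger-causal interpretation;
edges among lag-0 columns are allowed during search (they can absorb
sub-bin-width dependencies) but are flagged non-causal downstream, and the
lag-0 subgraph must stay acyclic.

Structure search is a restarted greedy hill climb with a tabu list over the
inverses of the last seven applied moves, scored by AIC in the "maximise
log-likelihood minus free parameters" convention (natural log; equivalent to
standard AIC up to a factor of -2).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .tables import BinnedSlicedTable

__all__ = [
    "LagGraph",
    "DbnScorer",
    "aic_score",
    "random_start_graph",
    "hillclimb_tabu",
    "learn_unweighted_ensemble",
]

Edge = tuple[int, int]  # (cause column index, effect column index)


@dataclass
class LagGraph:
    """Directed graph over (population, lag) nodes; edges end at lag-0 nodes."""

    n_nodes: int
    lag0_nodes: tuple[int, ...]
    edges: frozenset = frozenset()

    def __post_init__(self):
        lag0 = set(self.lag0_nodes)
        for u, v in self.edges:
            if v not in lag0:
                raise ValueError("edges must terminate at a lag-0 node")
            if u == v:
                raise ValueError("self-loops not allowed")
        if self._lag0_cyclic():
            raise ValueError("lag-0 subgraph must be acyclic")

    def _lag0_cyclic(self, extra: Edge | None = None,
                     removed: Edge | None = None) -> bool:
        lag0 = set(self.lag0_nodes)
        adj: dict[int, list[int]] = {v: [] for v in lag0}
        edges = set(self.edges)
        if removed is not None:
            edges.discard(removed)
        if extra is not None:
            edges.add(extra)
        for u, v in edges:
            if u in lag0 and v in lag0:
                adj[u].append(v)
        color = {v: 0 for v in lag0}

        def dfs(v):
            color[v] = 1
            for w in adj[v]:
                if color[w] == 1:
                    return True
                if color[w] == 0 and dfs(w):
                    return True
            color[v] = 2
            return False

        return any(color[v] == 0 and dfs(v) for v in lag0)

    def parents(self, v: int) -> tuple[int, ...]:
        return tuple(sorted(u for u, w in self.edges if w == v))

    def with_edge(self, e: Edge) -> "LagGraph":
        return LagGraph(self.n_nodes, self.lag0_nodes, self.edges | {e})

    def without_edge(self, e: Edge) -> "LagGraph":
        return LagGraph(self.n_nodes, self.lag0_nodes, self.edges - {e})


class DbnScorer:
    """Cached decomposable AIC scoring of parent sets on one table.

    Family score of an effect variable v with parent set P:
        max log-likelihood of v | P  -  (levels - 1) * levels^|P|
    (natural log; higher is better).  Parent configurations unseen in the
    data contribute zero log-likelihood.
    """

    def __init__(self, table: BinnedSlicedTable, max_parents: int | None = None):
        self.values = np.ascontiguousarray(table.values.astype(np.int64))
        self.levels = table.levels
        self.n_rows, self.n_nodes = self.values.shape
        self.lag0_nodes = tuple(table.lag0_columns())
        self.max_parents = max_parents
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        L = self.levels
        child = self.values[:, v]
        if parents:
            code = np.zeros(self.n_rows, dtype=np.int64)
            for p in parents:
                code = code * L + self.values[:, p]
            n_cfg = L ** len(parents)
        else:
            code = np.zeros(self.n_rows, dtype=np.int64)
            n_cfg = 1
        counts = np.bincount(code * L + child, minlength=n_cfg * L).reshape(n_cfg, L)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.sum(xlogy(counts, counts / np.where(totals > 0, totals, 1))))
        k = (L - 1) * n_cfg
        score = ll - k
        self._cache[key] = score
        return score

    def graph_score(self, graph: LagGraph) -> float:
        return sum(self.family_score(v, graph.parents(v)) for v in self.lag0_nodes)

    def candidate_edges(self) -> list[Edge]:
        lag0 = set(self.lag0_nodes)
        out = []
        for v in self.lag0_nodes:
            for u in range(self.n_nodes):
                if u != v:
                    out.append((u, v))
        return out


def aic_score(graph: LagGraph, table: BinnedSlicedTable) -> float:
    """AIC (log-likelihood minus free parameters) of a graph on a table."""
    if graph.n_nodes != table.values.shape[1]:
        raise ValueError("graph nodes do not match table columns")
    return DbnScorer(table).graph_score(graph)


def random_start_graph(scorer: DbnScorer, rng: np.random.Generator,
                       expected_in_degree: float = 2.0) -> LagGraph:
    """Erdos-Renyi start over the allowed-edge mask, lag-0-acyclic.

    Each allowed edge is included independently so that each effect node's
    expected in-degree is ``expected_in_degree``; resampled until the lag-0
    subgraph is acyclic.
    """
    candidates = scorer.candidate_edges()
    per_head = scorer.n_nodes - 1
    p = min(1.0, expected_in_degree / per_head)
    for _ in range(1000):
        mask = rng.random(len(candidates)) < p
        edges = frozenset(e for e, m in zip(candidates, mask) if m)
        try:
            return LagGraph(scorer.n_nodes, scorer.lag0_nodes, edges)
        except ValueError:
            continue
    return LagGraph(scorer.n_nodes, scorer.lag0_nodes, frozenset())


# Move encoding: ("add", edge), ("del", edge), ("rev", edge).
def _inverse(move):
    kind, e = move
    if kind == "add":
        return ("del", e)
    if kind == "del":
        return ("add", e)
    return ("rev", (e[1], e[0]))


def hillclimb_tabu(table_or_scorer, seed: int | None = None,
                   tabu_history: int = 7,
                   restart_graph: LagGraph | None = None,
                   max_parents: int | None = None,
                   max_iter: int = 500) -> LagGraph:
    """Greedy best-improving hill climb with a tabu list of inverse moves.

    Moves are single-edge additions and deletions over the allowed mask, and
    reversals within lag-0 pairs that preserve acyclicity.  Terminates at a
    local optimum; the returned graph scores at least as high as the start.
    """
    scorer = (table_or_scorer if isinstance(table_or_scorer, DbnScorer)
              else DbnScorer(table_or_scorer, max_parents=max_parents))
    rng = np.random.default_rng(seed)
    graph = restart_graph if restart_graph is not None else random_start_graph(scorer, rng)
    lag0 = set(scorer.lag0_nodes)
    candidates = scorer.candidate_edges()
    tabu: deque = deque(maxlen=tabu_history)
    parent_map = {v: list(graph.parents(v)) for v in scorer.lag0_nodes}

    def fam(v):
        return scorer.family_score(v, tuple(sorted(parent_map[v])))

    def fam_with(v, parents):
        return scorer.family_score(v, tuple(sorted(parents)))

    for _ in range(max_iter):
        best_delta = 0.0
        best_move = None
        edges = graph.edges
        tabu_set = set(tabu)
        for e in candidates:
            u, v = e
            if e in edges:
                move = ("del", e)
                if move in tabu_set:
                    continue
                delta = fam_with(v, [p for p in parent_map[v] if p != u]) - fam(v)
            else:
                move = ("add", e)
                if move in tabu_set:
                    continue
                if scorer.max_parents is not None and \
                        len(parent_map[v]) >= scorer.max_parents:
                    continue
                if u in lag0 and graph._lag0_cyclic(extra=e):
                    continue
                delta = fam_with(v, parent_map[v] + [u]) - fam(v)
            if delta > best_delta + 1e-12:
                best_delta, best_move = delta, move
        # reversals within lag-0 pairs
        for e in list(edges):
            u, v = e
            if u in lag0 and v in lag0:
                move = ("rev", e)
                if move in tabu_set or (v, u) in edges:
                    continue
                if graph._lag0_cyclic(extra=(v, u), removed=e):
                    continue
                delta = (fam_with(v, [p for p in parent_map[v] if p != u])
                         + fam_with(u, parent_map[u] + [v])
                         - fam(v) - fam(u))
                if delta > best_delta + 1e-12:
                    best_delta, best_move = delta, move
        if best_move is None:
            break
        kind, e = best_move
        u, v = e
        if kind == "add":
            graph = graph.with_edge(e)
            parent_map[v].append(u)
        elif kind == "del":
            graph = graph.without_edge(e)
            parent_map[v].remove(u)
        else:
            graph = graph.without_edge(e).with_edge((v, u))
            parent_map[v].remove(u)
            parent_map[u].append(v)
        tabu.append(_inverse(best_move))
    return graph


def learn_unweighted_ensemble(table: BinnedSlicedTable, B: int,
                              n_restarts: int = 120,
                              seed: int | None = None,
                              bootstrap_size: int | None = None,
                              max_parents: int | None = None) -> list[LagGraph]:
    """B row-bootstraps, each searched from ``n_restarts`` random starts.

    For each bootstrap only the best-AIC local optimum is kept (ties broken
    by lowest restart index).  ``bootstrap_size`` defaults to the table's row
    count.
    """
    from .tables import bootstrap_rows

    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    size = bootstrap_size if bootstrap_size is not None else table.n_rows
    out = []
    for _ in range(B):
        boot = bootstrap_rows(table, size, seed=int(rng.integers(2**31)))
        scorer = DbnScorer(boot, max_parents=max_parents)
        best_graph, best_score = None, -np.inf
        for _r in range(n_restarts):
            g = hillclimb_tabu(scorer, seed=int(rng.integers(2**31)))
            s = scorer.graph_score(g)
            if s > best_score + 1e-9:
                best_graph, best_score = g, s
        best_graph.bootstrap_score = best_score  # AIC on its own bootstrap
        out.append(best_graph)
    return out
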