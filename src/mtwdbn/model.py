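"""Multi-timescale weighted DBN (MTwDBN): model and results objects.

:class:`MTwDBN` wraps a binned-and-sliced table.  ``fit`` learns an ensemble
of unweighted directed acyclic graphs on row bootstraps (restarted tabu hill
climb under AIC), converts it into weighted graphs (edge weight = bootstrap
presence frequency), repeats the procedure on time-shuffled surrogate data,
and tests per cross-lag edge whether real weights exceed the null.  Edges
that pass are said to survive time shuffling.  The default significance
test compares edge-presence proportions among the B independent bootstrap
graphs (alpha-controlled); a one-sided Mann-Whitney U over the pooled
weighted-DAG weights is available but is anti-conservative because the
weighted DAGs are correlated resamples of the same ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .dbn import DbnScorer, LagGraph, learn_unweighted_ensemble
from .tables import BinnedSlicedTable, bin_and_slice, time_shuffle

__all__ = ["MTwDBN", "MTwDBNResults", "weight_ensemble", "edge_significance"]

Edge = tuple[int, int]


def weight_ensemble(graphs: list[LagGraph], n_weighted: int = 100,
                    seed: int | None = None) -> list[dict[Edge, float]]:
    """Weighted graphs from an unweighted ensemble.

    Each weighted graph resamples the B unweighted graphs with replacement
    and records, per edge, the fraction of resampled graphs containing it.
    """
    if not graphs:
        raise ValueError("need at least one unweighted graph")
    rng = np.random.default_rng(seed)
    B = len(graphs)
    all_edges = sorted(set().union(*(g.edges for g in graphs)))
    presence = np.array([[e in g.edges for e in all_edges] for g in graphs],
                        dtype=float)
    out = []
    for _ in range(n_weighted):
        idx = rng.integers(0, B, size=B)
        freq = presence[idx].mean(axis=0)
        out.append({e: float(w) for e, w in zip(all_edges, freq) if w > 0})
    return out


def edge_significance(real: list[dict[Edge, float]],
                      shuffled: list[dict[Edge, float]],
                      lag0_nodes: set[int],
                      alpha: float = 0.05,
                      method: str = "mannwhitney",
                      B: int | None = None) -> pd.DataFrame:
    """Test, per cross-lag edge, whether real edge weights exceed shuffled.

    Weight lists may pool several sessions' weighted graphs.  Lag-0 -> lag-0
    edges carry no causal interpretation and are excluded.  Two tests:

    * ``mannwhitney`` — one-sided Mann-Whitney U on the pooled weighted-DAG
      weights.  Because the weighted DAGs of one ensemble are bootstrap
      resamples of the same B unweighted graphs, this treats correlated
      replicates as independent and rejects far above its nominal alpha for
      chance edges.
    * ``presence`` — one-sided two-proportion (Fisher exact) test on the
      implied edge-presence counts among the underlying B unweighted graphs
      per ensemble (requires ``B``); controls alpha.

    Returns a frame with one row per cross-lag edge: (cause, effect, weight,
    p_value, significant).
    """
    if not real or not shuffled:
        raise ValueError("both weighted-graph lists must be non-empty")
    if method not in ("mannwhitney", "presence"):
        raise ValueError("method must be 'mannwhitney' or 'presence'")
    if method == "presence" and B is None:
        raise ValueError("method='presence' requires B")
    edges = sorted({e for g in real for e in g}
                   | {e for g in shuffled for e in g})
    rows = []
    for e in edges:
        u, v = e
        if u in lag0_nodes:
            continue
        w_real = np.array([g.get(e, 0.0) for g in real])
        w_null = np.array([g.get(e, 0.0) for g in shuffled])
        if np.all(w_real == w_null[0]) and np.all(w_null == w_null[0]):
            p = 1.0
        elif method == "mannwhitney":
            p = float(mannwhitneyu(w_real, w_null, alternative="greater").pvalue)
        else:
            # mean weight over an ensemble's resamples estimates the
            # presence fraction among its B independent bootstrap graphs
            n_r = max(B, int(round(len(w_real) * B / 100)))
            n_s = max(B, int(round(len(w_null) * B / 100)))
            k_r = int(round(w_real.mean() * n_r))
            k_s = int(round(w_null.mean() * n_s))
            table = [[k_r, n_r - k_r], [k_s, n_s - k_s]]
            p = float(fisher_exact(table, alternative="greater").pvalue)
        rows.append({"cause": u, "effect": v, "weight": float(w_real.mean()),
                     "p_value": p, "significant": p < alpha})
    return pd.DataFrame(rows, columns=["cause", "effect", "weight", "p_value",
                                       "significant"])


class MTwDBN:
    """Multi-timescale weighted DBN over a binned-and-sliced table."""

    def __init__(self, table: BinnedSlicedTable, max_parents: int | None = None):
        self.table = table
        self.max_parents = max_parents

    @classmethod
    def from_spikes(cls, spikes, bin_ms: float, n_lags: int, levels: int = 3,
                    **kw) -> "MTwDBN":
        return cls(bin_and_slice(spikes, bin_ms, n_lags, levels), **kw)

    def fit(self, B: int = 200, n_restarts: int = 120,
            bootstrap_size: int | None = 8000, n_weighted: int = 100,
            shuffle_null: bool = True, alpha: float = 0.05,
            significance_method: str = "presence",
            seed: int | None = None) -> "MTwDBNResults":
        rng = np.random.default_rng(seed)
        size = bootstrap_size
        if size is not None:
            size = min(size, self.table.n_rows) if self.table.n_rows else size
        unweighted = learn_unweighted_ensemble(
            self.table, B, n_restarts=n_restarts,
            seed=int(rng.integers(2**31)), bootstrap_size=size,
            max_parents=self.max_parents)
        weighted = weight_ensemble(unweighted, n_weighted,
                                   seed=int(rng.integers(2**31)))
        null_unweighted = null_weighted = None
        if shuffle_null:
            shuffled = time_shuffle(self.table, seed=int(rng.integers(2**31)))
            null_unweighted = learn_unweighted_ensemble(
                shuffled, B, n_restarts=n_restarts,
                seed=int(rng.integers(2**31)), bootstrap_size=size,
                max_parents=self.max_parents)
            null_weighted = weight_ensemble(null_unweighted, n_weighted,
                                            seed=int(rng.integers(2**31)))
        return MTwDBNResults(self, unweighted, weighted, null_unweighted,
                             null_weighted, alpha=alpha, B=B, seed=seed,
                             significance_method=significance_method)


@dataclass
class MTwDBNResults:
    """Fitted MTwDBN: graph ensembles, edge weights, and significance."""

    model: MTwDBN
    unweighted_graphs: list[LagGraph]
    weighted_graphs: list[dict[Edge, float]]
    null_unweighted_graphs: list[LagGraph] | None
    null_weighted_graphs: list[dict[Edge, float]] | None
    alpha: float = 0.05
    B: int = 0
    seed: int | None = None
    significance_method: str = "presence"
    _edge_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def table(self) -> BinnedSlicedTable:
        return self.model.table

    def edge_weights(self) -> dict[Edge, float]:
        """Mean weight per edge over the weighted-graph pool."""
        edges = sorted({e for g in self.weighted_graphs for e in g})
        return {e: float(np.mean([g.get(e, 0.0) for g in self.weighted_graphs]))
                for e in edges}

    def edge_weight_ci(self, edge: Edge, level: float = 0.95) -> tuple[float, float]:
        w = np.array([g.get(edge, 0.0) for g in self.weighted_graphs])
        lo, hi = np.percentile(w, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
        return float(lo), float(hi)

    def edges(self) -> pd.DataFrame:
        """Per cross-lag edge: weight, p-value against the shuffle null,
        significance flag, and (population, lag) labels."""
        if self._edge_table is None:
            lag0 = set(self.table.lag0_columns())
            if self.null_weighted_graphs is not None:
                df = edge_significance(self.weighted_graphs,
                                       self.null_weighted_graphs, lag0,
                                       alpha=self.alpha,
                                       method=self.significance_method,
                                       B=self.B or None)
            else:
                rows = [{"cause": u, "effect": v, "weight": w,
                         "p_value": np.nan, "significant": np.nan}
                        for (u, v), w in self.edge_weights().items()
                        if u not in lag0]
                df = pd.DataFrame(rows, columns=["cause", "effect", "weight",
                                                 "p_value", "significant"])
            labels = self.table.column_labels()
            df["cause_population"] = [labels[u][0] for u in df["cause"]]
            df["cause_lag_ms"] = [labels[u][1] for u in df["cause"]]
            df["effect_population"] = [labels[v][0] for v in df["effect"]]
            self._edge_table = df
        return self._edge_table

    def significant_edges(self) -> set[Edge]:
        df = self.edges()
        return {(int(u), int(v)) for u, v, s in
                zip(df["cause"], df["effect"], df["significant"]) if s is True or s == True}  # noqa: E712

    def population_edges(self, significant_only: bool = True) -> set[tuple[str, str]]:
        """Lag-collapsed directed population-level edges (cross-lag only)."""
        df = self.edges()
        if significant_only and df["significant"].notna().all():
            df = df[df["significant"].astype(bool)]
        return {(c, e) for c, e in
                zip(df["cause_population"], df["effect_population"])}

    def significant_edge_weights(self) -> dict[Edge, float]:
        w = self.edge_weights()
        return {e: w[e] for e in self.significant_edges()}

    def summary(self) -> str:
        df = self.edges().sort_values("weight", ascending=False)
        lines = [
            "MTwDBN results",
            "==============",
            f"table: {self.table.n_rows} rows, "
            f"{len(self.table.populations)} populations x "
            f"{self.table.n_slices} slices, levels={self.table.levels}",
            f"ensemble: B={self.B}, {len(self.weighted_graphs)} weighted DAGs, "
            f"shuffle null={'yes' if self.null_weighted_graphs else 'no'}, "
            f"alpha={self.alpha}",
            "",
            f"{'cause':>14} {'lag_ms':>8} -> {'effect':<12} "
            f"{'weight':>7} {'p':>10} sig",
        ]
        for _, r in df.iterrows():
            sig = "*" if r["significant"] is True or r["significant"] == True else ""  # noqa: E712
            p = "" if pd.isna(r["p_value"]) else f"{r['p_value']:.2e}"
            lines.append(
                f"{r['cause_population']:>14} {r['cause_lag_ms']:>8g} -> "
                f"{r['effect_population']:<12} {r['weight']:>7.3f} {p:>10} {sig}")
        return "\n".join(lines)

    def save_edges(self, path) -> None:
        path = Path(path)
        df = self.edges()
        out = df[["cause_population", "cause_lag_ms", "effect_population",
                  "weight", "p_value", "significant"]]
        out.to_csv(path, sep="\t", index=False)

    def plot_graph(self, ax=None, significant_only: bool = True):
        """Draw the lag-collapsed population graph, edge width ~ weight."""
        import matplotlib.pyplot as plt
        import networkx as nx

        df = self.edges()
        if significant_only and df["significant"].notna().all():
            df = df[df["significant"].astype(bool)]
        g = nx.DiGraph()
        g.add_nodes_from(self.table.populations)
        agg = df.groupby(["cause_population", "effect_population"])["weight"].max()
        for (c, e), w in agg.items():
            g.add_edge(c, e, weight=w)
        if ax is None:
            _, ax = plt.subplots()
        pos = nx.circular_layout(g)
        widths = [3 * g[u][v]["weight"] for u, v in g.edges]
        nx.draw_networkx(g, pos, ax=ax, width=widths, node_color="#c6dbef")
        ax.set_axis_off()
        return ax
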