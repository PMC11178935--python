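"""Validation of recovered dependency structures against ground truth.

Edges are scored at the population level, collapsed across lags: an inferred
(cause population -> effect population) pair counts once regardless of the
lag it was found at, and population self-edges are legitimate ground truth
(they capture refractoriness and within-population recurrence).  The module
also provides the LASSO regression baseline, the unit-subsampling and
lag-count sweeps, and the edge-weight-biased decoder comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel
from sklearn.linear_model import Lasso
from sklearn.metrics import matthews_corrcoef

from .dbn import DbnScorer, LagGraph
from .model import MTwDBN, MTwDBNResults
from .spiking import SpikeData, drop_units
from .tables import BinnedSlicedTable, bin_and_slice

__all__ = [
    "FScoreResult",
    "DecoderResult",
    "f_score",
    "rr_baseline",
    "rr_penalty_sweep",
    "subsampling_experiment",
    "lag_sweep",
    "sample_edge_subgraph",
    "fit_and_predict",
    "m_score",
    "compare_decoders",
    "decoder_experiment",
    "RR_PENALTY_GRID",
    "DEFAULT_RR_PENALTY",
]

RR_PENALTY_GRID = tuple(np.round(np.arange(0.005, 0.0501, 0.005), 4))
DEFAULT_RR_PENALTY = 0.02


@dataclass(frozen=True)
class FScoreResult:
    f: float
    recall: float
    precision: float
    correct: int
    missed: int
    spurious: int


def f_score(inferred_edges: set, ground_truth: set) -> FScoreResult:
    """Precision/recall/F over deduplicated directed population edges."""
    inferred = set(inferred_edges)
    truth = set(ground_truth)
    c = len(inferred & truth)
    m = len(truth - inferred)
    i = len(inferred - truth)
    recall = c / (c + m) if (c + m) else 0.0
    precision = c / (c + i) if (c + i) else 0.0
    f = 2 * recall * precision / (recall + precision) if (recall + precision) else 0.0
    return FScoreResult(f, recall, precision, c, m, i)


def rr_baseline(table: BinnedSlicedTable, penalty: float = DEFAULT_RR_PENALTY) -> set:
    """LASSO regression edge set: one model per lag-0 variable.

    An edge (cause population -> effect population) is present iff any lagged
    slice of the cause population gets a nonzero coefficient; lag-0
    predictors are ignored for edge calling.
    """
    labels = table.column_labels()
    lag0 = table.lag0_columns()
    X_all = table.values.astype(float)
    edges: set[tuple[str, str]] = set()
    for v in lag0:
        predictors = [j for j in range(X_all.shape[1]) if j != v]
        model = Lasso(alpha=penalty, max_iter=5000)
        model.fit(X_all[:, predictors], X_all[:, v])
        for j, coef in zip(predictors, model.coef_):
            pop, lag = labels[j]
            if lag != 0.0 and coef != 0.0:
                edges.add((pop, labels[v][0]))
    return edges


def rr_penalty_sweep(table: BinnedSlicedTable, ground_truth: set,
                     penalties=RR_PENALTY_GRID) -> pd.DataFrame:
    """F-score of the LASSO baseline across a penalty grid."""
    rows = []
    for pen in penalties:
        res = f_score(rr_baseline(table, pen), ground_truth)
        rows.append({"penalty": float(pen), "f": res.f, "recall": res.recall,
                     "precision": res.precision})
    return pd.DataFrame(rows)


def _edges_from_graphs(graphs, table: BinnedSlicedTable) -> set:
    labels = table.column_labels()
    lag0 = set(table.lag0_columns())
    out = set()
    for g in graphs if isinstance(graphs, list) else [graphs]:
        for u, v in g.edges:
            if u not in lag0:
                out.add((labels[u][0], labels[v][0]))
    return out


def _weighted_ft_edges(results: MTwDBNResults, threshold: float = 0.5) -> set:
    """Edges whose mean bootstrap weight passes a fixed threshold."""
    labels = results.table.column_labels()
    lag0 = set(results.table.lag0_columns())
    out = set()
    for (u, v), w in results.edge_weights().items():
        if u not in lag0 and w > threshold:
            out.add((labels[u][0], labels[v][0]))
    return out


def _best_unweighted_edges(results: MTwDBNResults) -> set:
    """Edge set of the single unweighted DAG with the highest AIC, each
    scored on its own bootstrap table."""
    graphs = results.unweighted_graphs
    scores = [getattr(g, "bootstrap_score", None) for g in graphs]
    if any(s is None for s in scores):
        scorer = DbnScorer(results.table)
        scores = [scorer.graph_score(g) for g in graphs]
    best = graphs[int(np.argmax(scores))]
    return _edges_from_graphs(best, results.table)


def subsampling_experiment(spikes: SpikeData, ground_truth: set,
                           d_list=(0, 20, 40, 60, 80), n_reps: int = 5,
                           methods=("MTwDBN", "weightedFT", "unweighted", "RR"),
                           bin_ms: float = 1.2, n_lags: int = 2,
                           levels: int = 3, B: int = 200,
                           n_restarts: int = 120,
                           bootstrap_size: int | None = 8000,
                           rr_penalty: float = DEFAULT_RR_PENALTY,
                           significance_method: str = "mannwhitney",
                           seed: int | None = None) -> pd.DataFrame:
    """F-scores of each method after dropping d% of units per population.

    d = 0 is run once; other levels ``n_reps`` times with different random
    unit subsets.  Edge selection defaults to the published one-sided
    Mann-Whitney rule so the method comparison matches the original
    experiment.  Returns a tidy frame (d, rep, method, f, recall,
    precision).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in d_list:
        reps = 1 if d == 0 else n_reps
        for rep in range(reps):
            sub = drop_units(spikes, d, seed=int(rng.integers(2**31)))
            table = bin_and_slice(sub, bin_ms, n_lags, levels)
            need_dbn = any(m in methods for m in
                           ("MTwDBN", "weightedFT", "unweighted"))
            results = None
            if need_dbn:
                results = MTwDBN(table).fit(
                    B=B, n_restarts=n_restarts, bootstrap_size=bootstrap_size,
                    shuffle_null="MTwDBN" in methods,
                    significance_method=significance_method,
                    seed=int(rng.integers(2**31)))
            for method in methods:
                if method == "MTwDBN":
                    edges = results.population_edges(significant_only=True)
                elif method == "weightedFT":
                    edges = _weighted_ft_edges(results)
                elif method == "unweighted":
                    edges = _best_unweighted_edges(results)
                elif method == "RR":
                    edges = rr_baseline(table, rr_penalty)
                else:
                    raise ValueError(f"unknown method {method}")
                res = f_score(edges, ground_truth)
                rows.append({"d": d, "rep": rep, "method": method,
                             "f": res.f, "recall": res.recall,
                             "precision": res.precision})
    return pd.DataFrame(rows)


def lag_sweep(spikes: SpikeData, ground_truth: set,
              n_lags_list=(3, 4, 5, 6, 7), bin_ms: float = 1.2,
              levels: int = 3, B: int = 50, n_restarts: int = 120,
              bootstrap_size: int | None = 8000,
              significance_method: str = "mannwhitney",
              seed: int | None = None) -> pd.DataFrame:
    """MTwDBN recovery scores as a function of the number of lags."""
    rng = np.random.default_rng(seed)
    rows = []
    for n_lags in n_lags_list:
        table = bin_and_slice(spikes, bin_ms, n_lags, levels)
        results = MTwDBN(table).fit(B=B, n_restarts=n_restarts,
                                    bootstrap_size=bootstrap_size,
                                    significance_method=significance_method,
                                    seed=int(rng.integers(2**31)))
        res = f_score(results.population_edges(significant_only=True),
                      ground_truth)
        rows.append({"n_lags": n_lags, "f": res.f, "recall": res.recall,
                     "precision": res.precision})
    return pd.DataFrame(rows)


def sample_edge_subgraph(edge_weights: dict, n_edges: int, mode: str = "uniform",
                         seed: int | None = None) -> frozenset:
    """Sample ``n_edges`` edges without replacement from a weighted edge set.

    ``mode`` is "uniform" or "weighted" (inclusion probability proportional
    to edge weight).
    """
    edges = sorted(edge_weights)
    if n_edges > len(edges):
        raise ValueError("n_edges exceeds the available edge set")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        idx = rng.choice(len(edges), size=n_edges, replace=False)
    elif mode == "weighted":
        w = np.array([edge_weights[e] for e in edges], dtype=float)
        if w.sum() <= 0:
            raise ValueError("edge weights must not all be zero")
        idx = rng.choice(len(edges), size=n_edges, replace=False,
                         p=w / w.sum())
    else:
        raise ValueError("mode must be 'uniform' or 'weighted'")
    return frozenset(edges[i] for i in idx)


def fit_and_predict(dag_edges, fit_values: np.ndarray, val_values: np.ndarray,
                    lag0_nodes, levels: int,
                    seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """MLE conditional-probability-table decoder.

    Fits one CPT per effect variable from its parents in ``dag_edges`` on the
    fit rows; for each validation row one effect variable is chosen at random
    and its most probable level given the observed parent values is
    predicted.  Unseen parent configurations fall back to the marginal mode.
    Returns (predictions, truths).
    """
    rng = np.random.default_rng(seed)
    lag0_nodes = list(lag0_nodes)
    parents = {v: sorted(u for (u, w) in dag_edges if w == v) for v in lag0_nodes}
    fit_values = np.asarray(fit_values, dtype=np.int64)
    val_values = np.asarray(val_values, dtype=np.int64)
    n_val = val_values.shape[0]
    choice = rng.integers(0, len(lag0_nodes), size=n_val)
    preds = np.zeros(n_val, dtype=np.int64)
    truths = np.zeros(n_val, dtype=np.int64)
    L = levels
    for k, v in enumerate(lag0_nodes):
        P = parents[v]
        sel = choice == k
        if not np.any(sel):
            continue
        child = fit_values[:, v]
        marginal_mode = int(np.bincount(child, minlength=L).argmax())
        if P:
            code_fit = np.zeros(fit_values.shape[0], dtype=np.int64)
            code_val = np.zeros(n_val, dtype=np.int64)
            for p in P:
                code_fit = code_fit * L + fit_values[:, p]
                code_val = code_val * L + val_values[:, p]
            n_cfg = L ** len(P)
            counts = np.bincount(code_fit * L + child,
                                 minlength=n_cfg * L).reshape(n_cfg, L)
            seen = counts.sum(axis=1) > 0
            mode_per_cfg = np.where(seen, counts.argmax(axis=1), marginal_mode)
            preds[sel] = mode_per_cfg[code_val[sel]]
        else:
            preds[sel] = marginal_mode
        truths[sel] = val_values[sel, v]
    return preds, truths


def m_score(predictions, truth, metric: str = "matthews") -> float:
    """Multiclass prediction-quality score in [-1, 1].

    Defaults to the multiclass Matthews correlation coefficient; ``metric``
    may also be "accuracy" for transparency.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    if metric == "matthews":
        return float(matthews_corrcoef(truth, predictions))
    if metric == "accuracy":
        return float(np.mean(predictions == truth))
    raise ValueError("metric must be 'matthews' or 'accuracy'")


def decoder_experiment(table: BinnedSlicedTable, n_sessions: int = 10,
                       B: int = 50, n_restarts: int = 120,
                       bootstrap_size: int | None = 8000,
                       n_model_seeds: int = 100, ns=(6, 13),
                       test_fraction: float = 0.05,
                       significance_method: str = "mannwhitney",
                       seed: int | None = None) -> dict:
    """Full edge-weight predictive-power experiment.

    The table is split into train (95%) and held-out test rows.  The train
    part is bootstrapped ``n_sessions`` times to mimic multi-session data;
    each bootstrap runs the full weighted pipeline with its shuffle null.
    Edges surviving time shuffling across the pooled sessions form the edge
    set; their mean weights are the sampling weights for
    :func:`compare_decoders`, which fits and validates on the held-out rows.
    """
    from .model import MTwDBN, edge_significance
    from .tables import bootstrap_rows

    rng = np.random.default_rng(seed)
    n_rows = table.n_rows
    perm = rng.permutation(n_rows)
    n_test = int(round(n_rows * test_fraction))
    train = table.replace_values(table.values[perm[n_test:]])
    test = table.replace_values(table.values[perm[:n_test]])
    real_pool, null_pool = [], []
    for _ in range(n_sessions):
        boot = bootstrap_rows(train, train.n_rows, seed=int(rng.integers(2**31)))
        res = MTwDBN(boot).fit(B=B, n_restarts=n_restarts,
                               bootstrap_size=bootstrap_size,
                               significance_method=significance_method,
                               seed=int(rng.integers(2**31)))
        real_pool += res.weighted_graphs
        null_pool += res.null_weighted_graphs
    lag0 = set(table.lag0_columns())
    sig = edge_significance(real_pool, null_pool, lag0,
                            method=significance_method, B=B)
    sig = sig[sig["significant"].astype(bool)]
    edge_weights = {}
    for _, r in sig.iterrows():
        e = (int(r["cause"]), int(r["effect"]))
        edge_weights[e] = float(np.mean([g.get(e, 0.0) for g in real_pool]))
    cmp = compare_decoders(test, edge_weights, n_model_seeds=n_model_seeds,
                           ns=ns, test_fraction=1.0,
                           seed=int(rng.integers(2**31)))
    cmp["edge_weights"] = edge_weights
    return cmp


@dataclass
class DecoderResult:
    mode: str  # "uniform" | "weight_biased"
    n_edges: int
    m_scores: np.ndarray  # one per model seed


def compare_decoders(table: BinnedSlicedTable, edge_weights: dict,
                     n_model_seeds: int = 100, ns=(6, 13),
                     fit_n: int = 12000, val_n: int = 4000,
                     test_fraction: float = 0.05,
                     seed: int | None = None) -> dict:
    """Weight-biased vs uniform edge-subgraph decoders, paired per seed.

    The table is split 95%/5%; within the held-out part ``fit_n`` rows train
    the CPTs and ``val_n`` rows are scored.  If the held-out part is too
    small for both, the split is scaled up with a warning.  Per ``n`` in
    ``ns``, returns DecoderResult pairs, a two-tailed paired t-test p-value,
    and the Bonferroni-adjusted p over the tested ``n`` values.
    """
    rng = np.random.default_rng(seed)
    n_rows = table.n_rows
    n_test = int(round(n_rows * test_fraction))
    if n_test < fit_n + val_n:
        n_test = min(n_rows // 2, fit_n + val_n)
        warnings.warn(f"held-out fraction too small for fit_n + val_n; "
                      f"using {n_test} held-out rows")
    perm = rng.permutation(n_rows)
    test_idx = perm[:n_test]
    fit_idx = test_idx[:fit_n]
    val_idx = test_idx[fit_n:fit_n + val_n]
    fit_values = table.values[fit_idx]
    val_values = table.values[val_idx]
    lag0 = table.lag0_columns()

    out = {"per_n": {}, "ns": tuple(ns)}
    pvals = {}
    for n_edges in ns:
        scores = {"uniform": [], "weight_biased": []}
        for s in range(n_model_seeds):
            sub_seed = int(rng.integers(2**31))
            for mode, key in (("uniform", "uniform"), ("weighted", "weight_biased")):
                edges = sample_edge_subgraph(edge_weights, n_edges, mode,
                                             seed=sub_seed + (0 if mode == "uniform" else 1))
                preds, truths = fit_and_predict(edges, fit_values, val_values,
                                                lag0, table.levels,
                                                seed=sub_seed)
                scores[key].append(m_score(preds, truths))
        w = np.array(scores["weight_biased"])
        uw = np.array(scores["uniform"])
        if np.allclose(w, uw):
            p = 1.0
        else:
            p = float(ttest_rel(w, uw).pvalue)
        pvals[n_edges] = p
        out["per_n"][n_edges] = {
            "uniform": DecoderResult("uniform", n_edges, uw),
            "weight_biased": DecoderResult("weight_biased", n_edges, w),
            "p_value": p,
        }
    for n_edges in ns:
        adj = min(1.0, pvals[n_edges] * len(ns))
        entry = out["per_n"][n_edges]
        entry["p_adjusted"] = adj
        entry["weight_biased_better"] = bool(
            entry["weight_biased"].m_scores.mean()
            > entry["uniform"].m_scores.mean() and adj < 0.05)
    return out
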