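"""Condition-wise modulation of unique and total dependencies.

Unique-dependency modulation compares MTwDBN edge weights across two
conditions with the index (w_A - w_B) / (w_A + w_B) in [-1, 1]; total
dependency is the absolute univariate logistic slope |beta_1| between a
cause and an effect variable, modulated the same way.  Distributions of
5000 bootstrap indices per edge are summarised by their mean and a
bias-corrected and accelerated (BCa) bootstrap confidence interval, and the
sign of shared-dependency modulation is inferred from total ~ unique +
shared with nonnegative components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .tables import BinnedSlicedTable

__all__ = [
    "ModulationSamples",
    "TotalDependency",
    "modulation_index",
    "bootstrap_edge_modulation",
    "total_dependency_bootstrap",
    "bca_ci",
    "group_indices",
    "infer_shared_sign",
    "psychometric_threshold",
]

log = logging.getLogger(__name__)


@dataclass
class ModulationSamples:
    edge: tuple
    lag_ms: float | None
    samples: np.ndarray
    tags: dict = field(default_factory=dict)
    n_dropped: int = 0  # 0/0 pairs skipped


@dataclass
class TotalDependency:
    cause: str
    effect: str
    beta_a: np.ndarray  # |beta_1| per bootstrap, condition A
    beta_b: np.ndarray


def modulation_index(w_a: float, w_b: float) -> float:
    """(w_a - w_b) / (w_a + w_b); undefined when both are zero."""
    if w_a + w_b <= 0:
        raise ValueError("modulation index undefined: w_a + w_b must be > 0")
    return (w_a - w_b) / (w_a + w_b)


def bootstrap_edge_modulation(weighted_a: list, weighted_b: list,
                              edges=None, n_pairs: int = 5000,
                              seed: int | None = None,
                              lag_of=None) -> list[ModulationSamples]:
    """Bootstrap modulation indices for edges across two weighted-DAG pools.

    Per pair, one weighted graph is drawn with replacement from each
    condition and the index computed per edge.  ``edges`` restricts the
    analysis (e.g. to edges surviving the shuffle null in at least one
    condition); pairs where both weights are zero are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    if edges is None:
        edges = sorted({e for g in weighted_a for e in g}
                       | {e for g in weighted_b for e in g})
    else:
        edges = sorted(edges)
    ia = rng.integers(0, len(weighted_a), size=n_pairs)
    ib = rng.integers(0, len(weighted_b), size=n_pairs)
    out = []
    for e in edges:
        wa = np.array([weighted_a[i].get(e, 0.0) for i in ia])
        wb = np.array([weighted_b[i].get(e, 0.0) for i in ib])
        denom = wa + wb
        ok = denom > 0
        n_dropped = int(np.sum(~ok))
        if n_dropped:
            log.info("edge %s: dropped %d undefined (0/0) pairs", e, n_dropped)
        samples = (wa[ok] - wb[ok]) / denom[ok]
        lag = lag_of(e) if lag_of is not None else None
        out.append(ModulationSamples(e, lag, samples, n_dropped=n_dropped))
    return out


def _abs_logistic_slopes(x: np.ndarray, y: np.ndarray, n_boot: int,
                         size: int, rng: np.random.Generator) -> np.ndarray:
    """|logistic slope| for each of ``n_boot`` row bootstraps (binary x, y).

    For a binary predictor the logistic MLE slope equals the log odds ratio
    of the 2x2 table, so each fit reduces to counting, and a row bootstrap
    of the table is a multinomial draw over the four cells.  Separated
    tables get a small jitter (0.5 added to each cell) with a warning.
    """
    cell = 2 * x + y  # 0:00 1:01 2:10 3:11
    p = np.bincount(cell, minlength=4) / len(cell)
    counts = rng.multinomial(size, p, size=n_boot)
    c = counts.astype(float)
    separated = np.any(counts == 0, axis=1)
    if np.any(separated):
        warnings.warn(f"{separated.sum()} bootstrap fits separated; "
                      "jittered with 0.5 per cell")
        c[separated] += 0.5
    slope = np.log(c[:, 3] * c[:, 0]) - np.log(c[:, 1] * c[:, 2])
    return np.abs(slope)


def total_dependency_bootstrap(table_a: BinnedSlicedTable,
                               table_b: BinnedSlicedTable,
                               cause: tuple, effect: tuple,
                               n: int = 5000,
                               bootstrap_size: int | None = None,
                               seed: int | None = None
                               ) -> tuple[TotalDependency, np.ndarray]:
    """Bootstrap |beta_1| of effect on cause in each condition and modulate.

    ``cause``/``effect`` are (population, lag_ms) column labels.  The
    bootstrap size defaults to the maximum row count of the two conditions so
    both are resampled on equal footing.  Binary responses are obtained by
    thresholding levels at >= 1.
    """
    ca = table_a.column_index(*cause)
    ea = table_a.column_index(*effect)
    cb = table_b.column_index(*cause)
    eb = table_b.column_index(*effect)
    size = bootstrap_size or max(table_a.n_rows, table_b.n_rows)
    rng = np.random.default_rng(seed)
    xa = (table_a.values[:, ca] >= 1).astype(np.int64)
    ya = (table_a.values[:, ea] >= 1).astype(np.int64)
    xb = (table_b.values[:, cb] >= 1).astype(np.int64)
    yb = (table_b.values[:, eb] >= 1).astype(np.int64)
    beta_a = _abs_logistic_slopes(xa, ya, n, size, rng)
    beta_b = _abs_logistic_slopes(xb, yb, n, size, rng)
    denom = beta_a + beta_b
    ok = denom > 0
    indices = (beta_a[ok] - beta_b[ok]) / denom[ok]
    dep = TotalDependency(str(cause), str(effect), beta_a, beta_b)
    return dep, indices


def bca_ci(samples, level: float = 0.95, n_resamples: int = 5000,
           resample_size: int | None = 5000,
           seed: int | None = None) -> tuple[float, float, float]:
    """Mean and bias-corrected & accelerated bootstrap CI of the mean.

    ``resample_size`` sets the size of each bootstrap resample (it may differ
    from the sample size, giving more conservative intervals for very large
    bootstrap-generated samples); constant input yields a degenerate
    interval.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    theta = float(x.mean())
    if np.all(x == x[0]):
        return theta, theta, theta
    rng = np.random.default_rng(seed)
    m = resample_size or len(x)
    idx = rng.integers(0, len(x), size=(n_resamples, m))
    boot = x[idx].mean(axis=1)
    # bias correction
    prop = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / n_resamples
    prop = min(max(prop, 1.0 / (n_resamples + 1)), 1 - 1.0 / (n_resamples + 1))
    z0 = ndtri(prop)
    # acceleration from the jackknife of the mean
    jack = (x.sum() - x) / (len(x) - 1)
    d = jack.mean() - jack
    denom = np.sum(d**2) ** 1.5
    a = np.sum(d**3) / (6 * denom) if denom > 0 else 0.0
    alpha = (1 - level) / 2
    out = []
    for q in (alpha, 1 - alpha):
        z = ndtri(q)
        adj = ndtr(z0 + (z0 + z) / (1 - a * (z0 + z)))
        out.append(float(np.quantile(boot, adj)))
    return theta, out[0], out[1]


def _ci_sign(mean: float, lo: float, hi: float) -> int:
    if lo > 0:
        return 1
    if hi < 0:
        return -1
    return 0


def group_indices(samples: list[ModulationSamples], scheme,
                  level: float = 0.95, seed: int | None = None) -> pd.DataFrame:
    """Pool modulation samples per group; summarise mean, BCa CI and sign.

    ``scheme`` maps a ModulationSamples object to a hashable group key (or
    None to exclude it).  Modulation sign is the sign of the mean when the
    CI excludes zero, else 0.  Empty groups are omitted with a log message.
    """
    groups: dict = {}
    for s in samples:
        key = scheme(s)
        if key is None:
            continue
        groups.setdefault(key, []).append(s.samples)
    rows = []
    for key, chunks in groups.items():
        pooled = np.concatenate(chunks)
        if len(pooled) < 2:
            log.info("group %s: too few samples, omitted", key)
            continue
        mean, lo, hi = bca_ci(pooled, level=level, seed=seed)
        rows.append({"group": key, "n": len(pooled), "mean": mean,
                     "ci_lo": lo, "ci_hi": hi, "sign": _ci_sign(mean, lo, hi)})
    return pd.DataFrame(rows, columns=["group", "n", "mean", "ci_lo",
                                       "ci_hi", "sign"])


def infer_shared_sign(total_sign: int, unique_sign: int):
    """Sign of shared-dependency modulation from total ~ unique + shared.

    With nonnegative components, a total/unique sign disagreement pins the
    shared sign; agreement (or both flat) leaves it indeterminate.
    Returns -1, +1 or "indeterminate".
    """
    for s in (total_sign, unique_sign):
        if s not in (-1, 0, 1):
            raise ValueError("signs must be in {-1, 0, +1}")
    if total_sign == unique_sign:
        return "indeterminate"
    if total_sign == 0:
        return -unique_sign
    # total_sign != 0 and unique_sign in {0, -total_sign}
    return total_sign


def psychometric_threshold(orientation_changes, hit_rates) -> float:
    """Tested orientation change closest to the fitted 50% threshold.

    Fits a two-parameter logistic (midpoint, slope) to hit rate versus
    orientation change and returns the tested condition nearest the fitted
    midpoint; raises if the rates never cross 50% in range.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(orientation_changes, dtype=float)
    y = np.asarray(hit_rates, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 conditions")
    if y.min() > 0.5 or y.max() < 0.5:
        raise ValueError("hit rates do not cross 50% in the tested range")

    def logistic(t, x0, k):
        return 1.0 / (1.0 + np.exp(-(t - x0) / k))

    p0 = (float(np.interp(0.5, y, x)) if np.all(np.diff(y) >= 0)
          else float(x.mean()), max(np.ptp(x) / 4, 1e-3))
    popt, _ = curve_fit(logistic, x, y, p0=p0, maxfev=10000)
    x0 = popt[0]
    if not (x.min() - np.ptp(x) <= x0 <= x.max() + np.ptp(x)):
        raise ValueError("fitted 50% point lies far outside the tested range")
    return float(x[np.argmin(np.abs(x - x0))])
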