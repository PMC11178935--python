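"""Partial information decomposition on a parameterised binary toy network.

The generator builds an eight-variable binary ensemble (one target, one
designated unique source, six shared-only sources).  Per sample, every
variable is initialised i.i.d. Bernoulli(0.5); a single *shared* coin
(probability ``p_shared``) then sets all eight variables to 1, and a single
*unique* coin (probability ``p_unique``) sets the target and the unique
source to 1.  This induces a shared dependency among all variables and one
extra unique dependency between target and unique source.

Information atoms for two sources S1, S2 about a target T satisfy

    I(T; S1, S2) = U1 + U2 + R + S
    I(T; S1)     = U1 + R
    I(T; S2)     = U2 + R

where U1/U2 are unique, R redundant and S synergistic information (bits).
Fixing a redundancy measure determines all four atoms.  The default measure
is the pointwise common change in surprisal (local co-information under the
pairwise maximum-entropy joint, sign-matched); minimum specific information
is available as a fallback, and is always used for redundancy over more than
two sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "PidGenConfig",
    "PidAtoms",
    "generate_pid_network_samples",
    "uncertainty_coefficient",
    "pid_atoms",
    "joint_pmf_from_columns",
    "unique_info_fraction",
    "shared_info_fraction",
    "fit_pairwise_logistic",
    "fit_network_l1",
    "DEFAULT_L1_PENALTY",
]

TARGET_COL = "target"
UNIQUE_COL = "unique_source"


@dataclass(frozen=True)
class PidGenConfig:
    p_unique: float
    p_shared: float
    n_sources: int = 7
    n_samples: int = 2000
    seed: int | None = None

    def __post_init__(self):
        for name in ("p_unique", "p_shared"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class PidAtoms:
    unique_1: float
    unique_2: float
    redundant: float
    synergistic: float

    def as_dict(self) -> dict:
        return {"unique_1": self.unique_1, "unique_2": self.unique_2,
                "redundant": self.redundant, "synergistic": self.synergistic}


def generate_pid_network_samples(cfg: PidGenConfig) -> pd.DataFrame:
    """Sample the toy network; columns: target, unique_source, shared_1.. ."""
    rng = np.random.default_rng(cfg.seed)
    n_vars = cfg.n_sources + 1
    x = (rng.random((cfg.n_samples, n_vars)) < 0.5).astype(np.int8)
    shared_fires = rng.random(cfg.n_samples) < cfg.p_shared
    x[shared_fires, :] = 1
    unique_fires = rng.random(cfg.n_samples) < cfg.p_unique
    x[unique_fires, 0] = 1  # target
    x[unique_fires, 1] = 1  # unique source
    cols = [TARGET_COL, UNIQUE_COL] + [f"shared_{k}" for k in range(1, cfg.n_sources)]
    return pd.DataFrame(x, columns=cols)


# ---------------------------------------------------------------------------
# entropy / mutual-information helpers (plug-in, log base 2)

def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-np.sum(xlogy(p, p)) / np.log(2))


def uncertainty_coefficient(source_col, target_col) -> float:
    """Normalised mutual information (H(T) - H(T|S)) / H(T), plug-in."""
    s = np.asarray(source_col)
    t = np.asarray(target_col)
    if len(s) != len(t):
        raise ValueError("columns must have equal length")
    h_t = _entropy_from_counts(np.bincount(t))
    if h_t == 0:
        raise ValueError("target entropy is zero; coefficient undefined")
    # H(T|S) = H(S,T) - H(S)
    joint = pd.crosstab(s, t).to_numpy().ravel()
    h_st = _entropy_from_counts(joint[joint > 0])
    h_s = _entropy_from_counts(np.bincount(s))
    return (h_t - (h_st - h_s)) / h_t


def joint_pmf_from_columns(s1, s2, t) -> np.ndarray:
    """Empirical joint pmf over (S1, S2, T) as a 3-D array."""
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    t = np.asarray(t)
    dims = (s1.max() + 1, s2.max() + 1, t.max() + 1)
    pmf = np.zeros(dims)
    np.add.at(pmf, (s1, s2, t), 1.0)
    return pmf / pmf.sum()


def _mi(joint: np.ndarray, axes_keep: tuple) -> float:
    """I(T; S_axes) in bits from a joint pmf with T on the last axis."""
    all_axes = tuple(range(joint.ndim - 1))
    marg = joint.sum(axis=tuple(a for a in all_axes if a not in axes_keep))
    # marg now has shape (kept sources..., T)
    p_t = joint.sum(axis=all_axes)
    p_s = marg.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = marg / (p_s[..., None] * p_t)
        terms = xlogy(marg, np.where(marg > 0, ratio, 1.0))
    return float(terms.sum() / np.log(2))


def _ipf_pairwise_maxent(joint: np.ndarray, n_iter: int = 300,
                         tol: float = 1e-12) -> np.ndarray:
    """Max-entropy joint over (S1,S2,T) matching all three pairwise marginals."""
    m12 = joint.sum(axis=2)
    m1t = joint.sum(axis=1)
    m2t = joint.sum(axis=0)
    q = np.full_like(joint, 1.0 / joint.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(n_iter):
            prev = q.copy()
            cur = q.sum(axis=2)
            q *= np.where(cur > 0, m12 / np.where(cur > 0, cur, 1.0), 0.0)[:, :, None]
            cur = q.sum(axis=1)
            q *= np.where(cur > 0, m1t / np.where(cur > 0, cur, 1.0), 0.0)[:, None, :]
            cur = q.sum(axis=0)
            q *= np.where(cur > 0, m2t / np.where(cur > 0, cur, 1.0), 0.0)[None, :, :]
            if np.abs(q - prev).max() < tol:
                break
    return q


def _redundancy_ccs(joint: np.ndarray) -> float:
    """Pointwise common change in surprisal under the pairwise max-ent joint.

    A configuration contributes its local co-information when the local
    informations i(s1;t), i(s2;t) and the co-information all share one sign.
    """
    q = _ipf_pairwise_maxent(joint)
    p_t = q.sum(axis=(0, 1))
    p_1t = q.sum(axis=1)
    p_2t = q.sum(axis=0)
    p_1 = q.sum(axis=(1, 2))
    p_2 = q.sum(axis=(0, 2))
    p_12 = q.sum(axis=2)
    red = 0.0
    n1, n2, nt = q.shape
    for a in range(n1):
        for b in range(n2):
            for c in range(nt):
                pabc = q[a, b, c]
                if pabc <= 0:
                    continue
                i1 = np.log2(p_1t[a, c] / (p_1[a] * p_t[c]))
                i2 = np.log2(p_2t[b, c] / (p_2[b] * p_t[c]))
                i12 = np.log2(pabc / (p_12[a, b] * p_t[c]))
                co = i1 + i2 - i12
                if np.sign(i1) == np.sign(i2) == np.sign(co) != 0:
                    red += pabc * co
    return float(red)


def _specific_information(joint: np.ndarray, source_axes: tuple) -> np.ndarray:
    """I(T=t; S) for each t: E_{s|t}[ log2 p(t|s)/p(t) ]."""
    all_axes = tuple(range(joint.ndim - 1))
    drop = tuple(a for a in all_axes if a not in source_axes)
    marg = joint.sum(axis=drop) if drop else joint  # (sources..., T)
    p_t = joint.sum(axis=all_axes)
    p_s = marg.sum(axis=-1)
    nt = marg.shape[-1]
    out = np.zeros(nt)
    for t in range(nt):
        p_st = marg[..., t]
        if p_t[t] == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            cond_s_given_t = p_st / p_t[t]
            ratio = np.where(p_st > 0, (p_st / np.where(p_s > 0, p_s, 1.0)) / p_t[t], 1.0)
            out[t] = float(np.sum(xlogy(cond_s_given_t, ratio)) / np.log(2))
    return out


def _redundancy_min(joint: np.ndarray, source_axes_list: list[tuple]) -> float:
    """Minimum specific information (Williams-Beer I_min) over source groups."""
    p_t = joint.sum(axis=tuple(range(joint.ndim - 1)))
    spec = np.array([_specific_information(joint, axes) for axes in source_axes_list])
    return float(np.sum(p_t * spec.min(axis=0)))


def pid_atoms(joint_pmf: np.ndarray, measure: str = "ccs") -> PidAtoms:
    """Decompose I(T; S1, S2) into unique/redundant/synergistic atoms.

    ``joint_pmf`` is a 3-D array over (S1, S2, T) summing to 1.  ``measure``
    selects the redundancy: "ccs" (pointwise common change in surprisal,
    default) or "min" (minimum specific information).
    """
    joint = np.asarray(joint_pmf, dtype=float)
    if joint.ndim != 3:
        raise ValueError("joint pmf must be 3-D over (S1, S2, T)")
    if np.any(joint < 0) or abs(joint.sum() - 1.0) > 1e-8:
        raise ValueError("joint pmf must be nonnegative and sum to 1")
    if measure == "ccs":
        red = _redundancy_ccs(joint)
    elif measure == "min":
        red = _redundancy_min(joint, [(0,), (1,)])
    else:
        raise ValueError("measure must be 'ccs' or 'min'")
    i1 = _mi(joint, (0,))
    i2 = _mi(joint, (1,))
    i12 = _mi(joint, (0, 1))
    u1 = i1 - red
    u2 = i2 - red
    syn = i12 - u1 - u2 - red
    return PidAtoms(u1, u2, red, syn)


def unique_info_fraction(table: pd.DataFrame, measure: str = "ccs",
                         other_source: str | None = None) -> float:
    """Unique information of the unique source about the target / H(target).

    The second PID source defaults to the first shared-only source column
    (all shared sources are exchangeable by construction).
    """
    t = table[TARGET_COL].to_numpy()
    h_t = _entropy_from_counts(np.bincount(t))
    if h_t == 0:
        raise ValueError("degenerate target: zero entropy")
    if other_source is None:
        other_source = next(c for c in table.columns
                            if c not in (TARGET_COL, UNIQUE_COL))
    joint = joint_pmf_from_columns(table[UNIQUE_COL], table[other_source], t)
    return pid_atoms(joint, measure=measure).unique_1 / h_t


def shared_info_fraction(table: pd.DataFrame, subset_size: int = 3,
                         n_repeats: int = 100, seed: int | None = None) -> float:
    """Mean redundant information about the target from random source subsets,
    normalised by H(target).

    Subsets are drawn from the shared-only sources; redundancy over a subset
    uses minimum specific information (defined for any number of sources).
    """
    shared_cols = [c for c in table.columns if c.startswith("shared_")]
    if subset_size > len(shared_cols):
        raise ValueError("subset_size exceeds number of shared sources")
    t = table[TARGET_COL].to_numpy()
    h_t = _entropy_from_counts(np.bincount(t))
    if h_t == 0:
        raise ValueError("degenerate target: zero entropy")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_repeats):
        subset = rng.choice(shared_cols, size=subset_size, replace=False)
        cols = [np.asarray(table[c]) for c in subset]
        dims = tuple(int(c.max()) + 1 for c in cols) + (int(t.max()) + 1,)
        pmf = np.zeros(dims)
        np.add.at(pmf, tuple(cols) + (t,), 1.0)
        pmf /= pmf.sum()
        red = _redundancy_min(pmf, [(k,) for k in range(subset_size)])
        vals.append(red / h_t)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# regression fits

def fit_pairwise_logistic(source_col, target_col) -> float:
    """Maximum-likelihood univariate logistic slope of target on source.

    Complete separation is handled by refitting with a small L2 jitter
    (1e-6) and a warning.
    """
    import statsmodels.api as sm

    x = np.asarray(source_col, dtype=float)
    y = np.asarray(target_col, dtype=float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("columns must be non-constant")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0)
        if np.isfinite(res.params[1]) and abs(res.params[1]) < 1e3:
            return float(res.params[1])
        raise RuntimeError("diverged")
    except Exception:
        warnings.warn("logistic fit separated or diverged; "
                      "refitting with L2 jitter 1e-6")
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(penalty="l2", C=1.0 / (len(y) * 1e-6),
                                 solver="lbfgs", max_iter=1000)
        clf.fit(x.reshape(-1, 1), y)
        return float(clf.coef_[0, 0])


# Per-observation L1 penalty used for toy-network coefficient maps: the
# smallest grid value (0.005..0.05 step 0.005) that keeps every true
# coefficient nonzero in the strong-unique / weak-shared regime.
DEFAULT_L1_PENALTY = 0.005


def fit_network_l1(sources: pd.DataFrame, target_col,
                   penalty: float = DEFAULT_L1_PENALTY) -> pd.Series:
    """L1-penalised multivariate logistic coefficients of target on sources.

    ``penalty`` is the per-observation L1 weight applied to every slope (the
    intercept is unpenalised).  Returns a Series indexed by source column.
    """
    import statsmodels.api as sm

    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    X = sm.add_constant(sources.to_numpy(dtype=float))
    y = np.asarray(target_col, dtype=float)
    alpha = np.full(X.shape[1], penalty * len(y))
    alpha[0] = 0.0
    res = sm.Logit(y, X).fit_regularized(method="l1", alpha=alpha, disp=0,
                                         acc=1e-8, maxiter=500)
    return pd.Series(np.asarray(res.params[1:]), index=list(sources.columns))
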