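"""Binned-and-sliced data tables and their plumbing.

Spike data are discretised into fixed-width bins per population, clipped to a
small number of activity levels, and lagged so that each row holds the current
bin (lag 0) together with the preceding ``n_lags`` bins for every population.
Rows slide one bin at a time and never straddle trial boundaries.  Tables also
carry the shuffling and bootstrapping primitives used to build null
distributions, and simple selection rules for session-style metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spiking import SpikeData

__all__ = [
    "BinnedSlicedTable",
    "bin_and_slice",
    "time_shuffle",
    "bootstrap_rows",
    "classify_waveform",
    "select_window",
    "select_sessions",
]


@dataclass
class BinnedSlicedTable:
    """Rows of discretised population activity across lagged time slices.

    Columns are population-major: for each population, slices ordered from the
    most negative lag up to lag 0.  ``lags_ms`` are the slice offsets, e.g.
    ``[-2.4, -1.2, 0.0]``.
    """

    values: np.ndarray  # (n_rows, n_pops * n_slices) small ints
    populations: list[str]
    lags_ms: list[float]
    levels: int
    bin_ms: float
    provenance: pd.DataFrame | None = None  # columns (trial, bin_index)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.populations) * len(self.lags_ms):
            raise ValueError("column count != n_populations * n_slices")
        if len(self.values) and (self.values.min() < 0
                                 or self.values.max() >= self.levels):
            raise ValueError(f"values must be in [0, {self.levels})")
        if 0.0 not in self.lags_ms:
            raise ValueError("lag 0 must be present")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_slices(self) -> int:
        return len(self.lags_ms)

    def column_labels(self) -> list[tuple[str, float]]:
        return [(p, lag) for p in self.populations for lag in self.lags_ms]

    def column_index(self, population: str, lag_ms: float) -> int:
        return self.column_labels().index((population, lag_ms))

    def lag0_columns(self) -> list[int]:
        return [i for i, (_, lag) in enumerate(self.column_labels()) if lag == 0.0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{p}@{lag:g}" for p, lag in self.column_labels()]
        return pd.DataFrame(self.values, columns=cols)

    # --- I/O: CSV or Parquet with a JSON sidecar holding the metadata ---

    def _sidecar(self) -> dict:
        return {"populations": self.populations, "lags_ms": self.lags_ms,
                "levels": self.levels, "bin_ms": self.bin_ms}

    def save(self, path) -> None:
        path = Path(path)
        df = self.to_dataframe()
        if path.suffix == ".parquet":
            df.to_parquet(path, index=False)
        else:
            df.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self._sidecar()))

    @classmethod
    def load(cls, path) -> "BinnedSlicedTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if path.suffix == ".parquet":
            df = pd.read_parquet(path)
        else:
            df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=np.int8), meta["populations"],
                   [float(x) for x in meta["lags_ms"]], int(meta["levels"]),
                   float(meta["bin_ms"]))

    def replace_values(self, values: np.ndarray) -> "BinnedSlicedTable":
        return BinnedSlicedTable(values, self.populations, self.lags_ms,
                                 self.levels, self.bin_ms, self.provenance)


def bin_and_slice(spikes: SpikeData, bin_ms: float, n_lags: int,
                  levels: int = 3) -> BinnedSlicedTable:
    """Bin pooled population activity and lag it into a sliced table.

    Counts are clipped to the requested number of levels (3-level: 0/1/>=2;
    2-level: any spike -> 1).  Row ``t`` of a trial holds slices
    ``t-n_lags .. t``; the first ``n_lags`` bins of each trial produce no row,
    and trials shorter than ``n_lags + 1`` bins are skipped with a warning.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    pops = spikes.populations
    n_bins = int(np.floor(spikes.duration_ms / bin_ms))
    n_slices = n_lags + 1
    lags_ms = [-(n_lags - k) * bin_ms for k in range(n_slices)]

    df = spikes.spikes
    pop_of = df["unit"].map(spikes.unit_populations)
    pop_idx = pop_of.map({p: i for i, p in enumerate(pops)}).to_numpy()
    bin_idx = np.floor(df["time_ms"].to_numpy() / bin_ms).astype(np.int64)
    trial_idx = df["trial"].to_numpy()

    rows = []
    prov_trials, prov_bins = [], []
    if n_bins < n_slices:
        warnings.warn("trials shorter than n_lags + 1 bins; no rows produced")
    for trial in range(spikes.n_trials):
        sel = trial_idx == trial
        counts = np.zeros((n_bins, len(pops)), dtype=np.int64)
        ok = sel & (bin_idx < n_bins)
        np.add.at(counts, (bin_idx[ok], pop_idx[ok]), 1)
        counts = np.clip(counts, 0, levels - 1)
        if n_bins < n_slices:
            continue
        n_rows = n_bins - n_lags
        # stack slices population-major: (pop, lag) columns
        block = np.empty((n_rows, len(pops) * n_slices), dtype=np.int8)
        for pi in range(len(pops)):
            for k in range(n_slices):
                block[:, pi * n_slices + k] = counts[k:k + n_rows, pi]
        rows.append(block)
        prov_trials.append(np.full(n_rows, trial))
        prov_bins.append(np.arange(n_lags, n_bins))
    if rows:
        values = np.concatenate(rows, axis=0)
        prov = pd.DataFrame({"trial": np.concatenate(prov_trials),
                             "bin_index": np.concatenate(prov_bins)})
    else:
        values = np.empty((0, len(pops) * n_slices), dtype=np.int8)
        prov = pd.DataFrame({"trial": [], "bin_index": []})
    return BinnedSlicedTable(values, pops, lags_ms, levels, bin_ms, prov)


def time_shuffle(table: BinnedSlicedTable, seed: int | None = None) -> BinnedSlicedTable:
    """Destroy temporal structure while preserving marginals.

    Step 1: within each row, permute each population's slice values across its
    lags.  Step 2: independently permute every column across rows.
    """
    rng = np.random.default_rng(seed)
    v = table.values.copy()
    n_rows = v.shape[0]
    s = table.n_slices
    for pi in range(len(table.populations)):
        block = v[:, pi * s:(pi + 1) * s]
        order = np.argsort(rng.random((n_rows, s)), axis=1)
        v[:, pi * s:(pi + 1) * s] = np.take_along_axis(block, order, axis=1)
    for col in range(v.shape[1]):
        v[:, col] = v[rng.permutation(n_rows), col]
    return table.replace_values(v)


def bootstrap_rows(table: BinnedSlicedTable, size: int,
                   seed: int | None = None) -> BinnedSlicedTable:
    """Resample ``size`` rows with replacement."""
    if size < 1:
        raise ValueError("size must be >= 1")
    if table.n_rows == 0:
        raise ValueError("cannot bootstrap an empty table")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, table.n_rows, size=size)
    out = table.replace_values(table.values[idx])
    out.provenance = None
    return out


# Putative E/I split from extracellular waveform width.  The 225 us boundary
# itself is assigned to narrow.
WAVEFORM_THRESHOLD_US = 225.0


def classify_waveform(peak_to_trough_us: float) -> str:
    if peak_to_trough_us <= 0:
        raise ValueError("peak-to-trough duration must be > 0")
    return "broad" if peak_to_trough_us > WAVEFORM_THRESHOLD_US else "narrow"


def select_window(spikes: SpikeData, start_ms: float = 60.0,
                  end_ms: float = 260.0) -> SpikeData:
    """Keep spikes in [start, end), re-referenced to the window start."""
    if start_ms >= end_ms:
        raise ValueError("start_ms must be < end_ms")
    df = spikes.spikes
    sel = (df["time_ms"] >= start_ms) & (df["time_ms"] < end_ms)
    out = df[sel].copy()
    out["time_ms"] = out["time_ms"] - start_ms
    return SpikeData(out.reset_index(drop=True), dict(spikes.unit_populations),
                     spikes.n_trials, end_ms - start_ms)


def select_sessions(session_metadata: pd.DataFrame, mode: str = "layerwise",
                    layers: tuple = ("sup", "inp", "deep")) -> list:
    """Filter sessions by unit coverage.

    ``session_metadata`` has columns (session, population, n_units) where
    population labels are "<layer>" for layerwise data or "<layer>_<class>"
    for layer+class data.  ``layerwise`` keeps sessions with >= 1 unit in each
    layer; ``layer_class`` keeps sessions with >= 1 unit in >= 2 of the 6
    layer-class populations.
    """
    if mode not in ("layerwise", "layer_class"):
        raise ValueError("mode must be 'layerwise' or 'layer_class'")
    kept = []
    for session, grp in session_metadata.groupby("session"):
        grp = grp[grp["n_units"] > 0]
        pops = set(grp["population"])
        if mode == "layerwise":
            covered = {p.split("_")[0] for p in pops}
            if all(layer in covered for layer in layers):
                kept.append(session)
        else:
            if len(pops) >= 2:
                kept.append(session)
    return kept
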