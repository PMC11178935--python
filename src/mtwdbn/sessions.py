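"""Synthetic session fixtures with known ground truth.

Produces "session-like" two-condition datasets so the whole pipeline —
binning, structure learning, shuffle nulls, modulation indices, phase
analysis — can be exercised end-to-end without any recorded data: spiking
data from networks whose connectivity differs between conditions in a known
way, and oscillation-locked event trains with a known preferred phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spiking import NetworkSpec, SpikeData, simulate_network

__all__ = ["SessionFixture", "make_modulated_session", "make_phase_locked_events"]


@dataclass
class SessionFixture:
    spikes: dict  # condition ("A"/"B") -> SpikeData
    specs: dict  # condition -> NetworkSpec
    ground_truth: dict  # condition -> set of population edges
    expected_modulation_sign: dict  # (cause_pop, effect_pop) -> -1/0/+1
    lfp: dict = field(default_factory=dict)  # optional per-trial traces
    events: dict = field(default_factory=dict)


def make_modulated_session(base_spec: NetworkSpec, edge_weight_changes: dict,
                           n_trials: int = 200, duration_ms: float = 200.0,
                           dt_ms: float = 0.1,
                           seed: int | None = None) -> SessionFixture:
    """Two-condition session: A uses the base weights, B the modified ones.

    ``edge_weight_changes`` maps (presynaptic index, postsynaptic index) to
    the new weight in condition B; each change must target an existing
    nonzero synapse.  The expected modulation sign of the corresponding
    population edge is the sign of the weight change (A minus B convention:
    an increase in A relative to B is positive).
    """
    rng = np.random.default_rng(seed)
    w_b = base_spec.weights.copy()
    expected: dict = {}
    for (j, i), new_w in edge_weight_changes.items():
        if base_spec.weights[i, j] == 0:
            raise ValueError(f"no existing synapse {j} -> {i}")
        old_w = base_spec.weights[i, j]
        w_b[i, j] = new_w
        cause = base_spec.neurons[j].population
        effect = base_spec.neurons[i].population
        expected[(cause, effect)] = int(np.sign(old_w - new_w))
    spec_b = NetworkSpec(base_spec.neurons, w_b, base_spec.external_input,
                         set(base_spec.ground_truth), base_spec.gain)
    for edge in base_spec.ground_truth:
        expected.setdefault(edge, 0)
    spikes = {
        "A": simulate_network(base_spec, n_trials, duration_ms, dt_ms,
                              seed=int(rng.integers(2**31))),
        "B": simulate_network(spec_b, n_trials, duration_ms, dt_ms,
                              seed=int(rng.integers(2**31))),
    }
    return SessionFixture(
        spikes=spikes,
        specs={"A": base_spec, "B": spec_b},
        ground_truth={"A": set(base_spec.ground_truth),
                      "B": set(spec_b.ground_truth)},
        expected_modulation_sign=expected,
    )


def make_phase_locked_events(oscillation_freq: float = 10.0, fs: float = 1000.0,
                             locking_phase: float = 0.0,
                             concentration: float = 5.0, n_events: int = 200,
                             duration_ms: float = 10000.0,
                             noise_sd: float = 0.1,
                             seed: int | None = None):
    """Sinusoid-plus-noise LFP and events von-Mises-locked to a phase.

    Event phases are drawn von Mises around ``locking_phase`` (uniform at
    concentration 0) and mapped to times within uniformly chosen oscillation
    cycles.  Phase convention: 0 at the cosine peak.  Returns (lfp, fs,
    event_times_ms).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_ms * fs / 1000.0))
    t_s = np.arange(n_samples) / fs
    lfp = np.cos(2 * np.pi * oscillation_freq * t_s)
    lfp = lfp + noise_sd * rng.standard_normal(n_samples)
    if concentration == 0:
        phases = rng.uniform(-np.pi, np.pi, size=n_events)
    else:
        phases = rng.vonmises(locking_phase, concentration, size=n_events)
    period_ms = 1000.0 / oscillation_freq
    n_cycles = int(np.floor(duration_ms / period_ms))
    # keep events away from the filter edges
    cycles = rng.integers(1, max(n_cycles - 1, 2), size=n_events)
    # cos(2*pi*f*t) has phase phi at t = phi / (2*pi*f) within a cycle
    frac = np.mod(phases, 2 * np.pi) / (2 * np.pi)
    times = (cycles + frac) * period_ms
    times = times[times < duration_ms]
    return lfp, fs, np.sort(times)
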