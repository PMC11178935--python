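"""Toy-network generation, information measures and regression fits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mtwdbn import pid


def exact_joint(p_unique, p_shared, variables=("unique", "shared", "target")):
    """Enumeration oracle: exact joint pmf over (unique source, one shared
    source, target) by summing over the three init bits and both coins."""
    pmf = np.zeros((2, 2, 2))
    for iu, ish, it in itertools.product((0, 1), repeat=3):
        for shared_coin in (0, 1):
            p_sc = p_shared if shared_coin else 1 - p_shared
            for unique_coin in (0, 1):
                p_uc = p_unique if unique_coin else 1 - p_unique
                u, s, t = iu, ish, it
                if shared_coin:
                    u = s = t = 1
                if unique_coin:
                    u = t = 1
                pmf[u, s, t] += 0.125 * p_sc * p_uc
    return pmf


def entropy_bits(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestGenerator:
    def test_shared_prob_one_forces_all_ones(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.3, 1.0, n_samples=200, seed=1))
        assert (t.to_numpy() == 1).all()

    def test_unique_prob_one_forces_target_and_unique(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(1.0, 0.0, n_samples=4000, seed=2))
        assert (t[pid.TARGET_COL] == 1).all()
        assert (t[pid.UNIQUE_COL] == 1).all()
        frac = t["shared_1"].mean()
        assert abs(frac - 0.5) < 0.05  # untouched sources stay Bernoulli(1/2)

    def test_target_rate_matches_enumeration(self):
        cfg = pid.PidGenConfig(0.4, 0.1, n_samples=2000, seed=3)
        t = pid.generate_pid_network_samples(cfg)
        expected = 1 - 0.5 * (1 - 0.1) * (1 - 0.4)
        se = np.sqrt(expected * (1 - expected) / cfg.n_samples)
        assert abs(t[pid.TARGET_COL].mean() - expected) < 4 * se

    def test_empirical_joint_matches_enumeration(self):
        cfg = pid.PidGenConfig(0.3, 0.2, n_samples=40000, seed=4)
        t = pid.generate_pid_network_samples(cfg)
        emp = pid.joint_pmf_from_columns(t[pid.UNIQUE_COL], t["shared_1"],
                                         t[pid.TARGET_COL])
        assert np.abs(emp - exact_joint(0.3, 0.2)).max() < 0.01

    def test_determinism_and_validation(self):
        a = pid.generate_pid_network_samples(pid.PidGenConfig(0.2, 0.2, seed=7))
        b = pid.generate_pid_network_samples(pid.PidGenConfig(0.2, 0.2, seed=7))
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            pid.PidGenConfig(1.2, 0.1)
        with pytest.raises(ValueError):
            pid.PidGenConfig(0.1, -0.1)


class TestUncertaintyCoefficient:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        u = pid.uncertainty_coefficient(rng.integers(0, 2, 20000),
                                        rng.integers(0, 2, 20000))
        assert 0 <= u < 0.001

    def test_identical_is_one(self):
        x = np.random.default_rng(1).integers(0, 2, 500)
        assert pid.uncertainty_coefficient(x, x) == pytest.approx(1.0)

    def test_degenerate_target_raises(self):
        with pytest.raises(ValueError):
            pid.uncertainty_coefficient(np.array([0, 1, 0]), np.array([1, 1, 1]))

    def test_matches_exact_joint(self):
        # closed form from the enumerated joint at (p_unique=.4, p_shared=0)
        joint = exact_joint(0.4, 0.0)
        p_ut = joint.sum(axis=1)
        h_t = entropy_bits(joint.sum(axis=(0, 1)))
        h_u = entropy_bits(joint.sum(axis=(1, 2)))
        h_ut = entropy_bits(p_ut.ravel())
        expected = (h_t - (h_ut - h_u)) / h_t
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.4, 0.0, n_samples=100000, seed=5))
        u = pid.uncertainty_coefficient(t[pid.UNIQUE_COL], t[pid.TARGET_COL])
        assert u == pytest.approx(expected, abs=0.01)


def _copy_case():
    p = np.zeros((2, 2, 2))
    for s1 in (0, 1):
        for s2 in (0, 1):
            p[s1, s2, s1] = 0.25
    return p


def _redundant_case():
    p = np.zeros((2, 2, 2))
    p[0, 0, 0] = p[1, 1, 1] = 0.5
    return p


def _xor_case():
    p = np.zeros((2, 2, 2))
    for s1 in (0, 1):
        for s2 in (0, 1):
            p[s1, s2, s1 ^ s2] = 0.25
    return p


class TestPidAtoms:
    @pytest.mark.parametrize("measure", ["ccs", "min"])
    @pytest.mark.parametrize("pmf,expected", [
        (_copy_case(), dict(unique_1=1, unique_2=0, redundant=0, synergistic=0)),
        (_redundant_case(), dict(unique_1=0, unique_2=0, redundant=1, synergistic=0)),
        (_xor_case(), dict(unique_1=0, unique_2=0, redundant=0, synergistic=1)),
    ])
    def test_canonical_cases_exact(self, measure, pmf, expected):
        atoms = pid.pid_atoms(pmf, measure=measure)
        for key, val in expected.items():
            assert getattr(atoms, key) == pytest.approx(val, abs=1e-9)

    @pytest.mark.parametrize("measure", ["ccs", "min"])
    def test_sum_rules_on_generator_joints(self, measure):
        for pu, ps in [(0.1, 0.1), (0.4, 0.1), (0.1, 0.4), (0.3, 0.3)]:
            joint = exact_joint(pu, ps)
            atoms = pid.pid_atoms(joint, measure=measure)
            i1 = entropy_bits(joint.sum(axis=(1, 2))) + \
                entropy_bits(joint.sum(axis=(0, 1))) - \
                entropy_bits(joint.sum(axis=1).ravel())
            i12 = entropy_bits(joint.sum(axis=2).ravel()) + \
                entropy_bits(joint.sum(axis=(0, 1))) - entropy_bits(joint.ravel())
            assert atoms.unique_1 + atoms.redundant == pytest.approx(i1, abs=1e-9)
            assert (atoms.unique_1 + atoms.unique_2 + atoms.redundant
                    + atoms.synergistic) == pytest.approx(i12, abs=1e-9)
            if measure == "min":
                # minimum specific information guarantees nonnegative atoms;
                # the pointwise common-surprisal measure does not in general
                for v in atoms.as_dict().values():
                    assert v > -1e-9

    def test_invalid_pmf_rejected(self):
        with pytest.raises(ValueError):
            pid.pid_atoms(np.full((2, 2, 2), 0.25))
        with pytest.raises(ValueError):
            pid.pid_atoms(np.ones((2, 2)))


class TestInformationFractions:
    def test_unique_fraction_zero_without_unique_channel(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.0, 0.2, n_samples=5000, seed=6))
        assert pid.unique_info_fraction(t) < 0.01

    def test_unique_fraction_increases_with_p_unique(self):
        vals = []
        for k, pu in enumerate([0.1, 0.2, 0.3, 0.4]):
            t = pid.generate_pid_network_samples(
                pid.PidGenConfig(pu, 0.1, n_samples=5000, seed=10 + k))
            vals.append(pid.unique_info_fraction(t))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_unique_fraction_matches_enumeration(self):
        joint = exact_joint(0.4, 0.1)
        h_t = entropy_bits(joint.sum(axis=(0, 1)))
        expected = pid.pid_atoms(joint).unique_1 / h_t
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.4, 0.1, n_samples=100000, seed=11))
        assert pid.unique_info_fraction(t) == pytest.approx(expected, abs=0.01)

    def test_shared_fraction_zero_without_shared_channel(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.2, 0.0, n_samples=5000, seed=12))
        assert pid.shared_info_fraction(t, n_repeats=10, seed=0) < 0.01

    def test_shared_fraction_increases_with_p_shared(self):
        vals = []
        for k, ps in enumerate([0.1, 0.2, 0.3, 0.4]):
            t = pid.generate_pid_network_samples(
                pid.PidGenConfig(0.1, ps, n_samples=5000, seed=20 + k))
            vals.append(pid.shared_info_fraction(t, n_repeats=20, seed=1))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_subset_size_validation(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.1, 0.1, n_sources=3, n_samples=100, seed=0))
        with pytest.raises(ValueError):
            pid.shared_info_fraction(t, subset_size=5)


class TestRegressionFits:
    def test_pairwise_slope_independent_near_zero(self):
        rng = np.random.default_rng(2)
        slope = pid.fit_pairwise_logistic(rng.integers(0, 2, 20000),
                                          rng.integers(0, 2, 20000))
        assert abs(slope) < 0.1

    def test_pairwise_slope_equals_log_odds_ratio(self):
        # for a binary predictor the logistic MLE slope is the log OR
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.3, 0.2, n_samples=2000, seed=13))
        x = t[pid.UNIQUE_COL].to_numpy()
        y = t[pid.TARGET_COL].to_numpy()
        n = np.array([[np.sum((x == i) & (y == j)) for j in (0, 1)]
                      for i in (0, 1)], dtype=float)
        log_or = np.log(n[1, 1] * n[0, 0] / (n[1, 0] * n[0, 1]))
        assert pid.fit_pairwise_logistic(x, y) == pytest.approx(log_or, abs=1e-4)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            pid.fit_pairwise_logistic(np.ones(100), np.random.default_rng(0)
                                      .integers(0, 2, 100))

    def test_l1_full_shrinkage(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.4, 0.1, n_samples=2000, seed=14))
        c = pid.fit_network_l1(t.drop(columns=[pid.TARGET_COL]),
                               t[pid.TARGET_COL], penalty=5.0)
        assert np.abs(c.to_numpy()).max() < 1e-6

    def test_l1_negative_penalty_rejected(self):
        t = pid.generate_pid_network_samples(
            pid.PidGenConfig(0.4, 0.1, n_samples=200, seed=15))
        with pytest.raises(ValueError):
            pid.fit_network_l1(t.drop(columns=[pid.TARGET_COL]),
                               t[pid.TARGET_COL], penalty=-0.1)

    def test_l1_unique_coefficient_tracks_unique_parameter(self):
        # Monte-Carlo refits across seeds put the (0.4, 0.1) / (0.0, 0.4)
        # coefficient ratio at ~2.3; without a unique channel the unique
        # source is just one of seven exchangeable shared sources.
        c_lo, c_hi = [], []
        for s in range(3):
            lo = pid.generate_pid_network_samples(
                pid.PidGenConfig(0.0, 0.4, n_samples=2000, seed=100 + s))
            hi = pid.generate_pid_network_samples(
                pid.PidGenConfig(0.4, 0.1, n_samples=2000, seed=200 + s))
            c_lo.append(pid.fit_network_l1(lo.drop(columns=[pid.TARGET_COL]),
                                           lo[pid.TARGET_COL])[pid.UNIQUE_COL])
            c_hi.append(pid.fit_network_l1(hi.drop(columns=[pid.TARGET_COL]),
                                           hi[pid.TARGET_COL])[pid.UNIQUE_COL])
        assert np.mean(c_hi) > 1.8 * abs(np.mean(c_lo))
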