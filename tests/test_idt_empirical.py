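"""Conditioned ensembles, decay curves, regression estimator, aggregation."""

import numpy as np
import pytest

from idtnet import (
    DynamicsParams,
    aggregate_by_degree,
    conditioned_ensemble,
    equilibrium_samples,
    estimate_idt,
    mi_decay_curve,
    mi_decay_curves,
    noise_floor,
)
from idtnet.fixtures import (
    single_update_transition_matrix,
    state_index,
    total_variation,
    two_spin_chain,
)
from idtnet.idt_empirical import _degree_bins
from idtnet.netgen import build_configuration_graph, sample_power_law_degrees


def two_spin_exact_lag_distributions(params, reference, tau_max):
    """Lag-tau conditional state distributions from transition-matrix powers."""
    net = two_spin_chain()
    m_sweep = np.linalg.matrix_power(
        single_update_transition_matrix(net, params), net.n_units
    )
    a0 = state_index(reference)
    start = np.zeros(4)
    start[a0] = 1.0
    out = [start]
    for _ in range(tau_max):
        out.append(out[-1] @ m_sweep)
    return np.array(out)


class TestConditionedEnsemble:
    def test_lag_zero_equals_reference(self, two_spin):
        params = DynamicsParams(2.0, rule="metropolis", seed=0)
        ens = conditioned_ensemble(two_spin, params, 200, 3, 50)
        assert np.all(ens.samples[:, 0, :] == ens.reference_state)

    def test_same_seed_identical(self, triangle):
        params = DynamicsParams(2.0, seed=8)
        a = conditioned_ensemble(triangle, params, 150, 4, 20)
        b = conditioned_ensemble(triangle, params, 150, 4, 20)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.reference_state, b.reference_state)

    def test_lag_conditionals_match_matrix_powers(self, two_spin):
        params = DynamicsParams(2.0, rule="glauber", seed=1)
        n_series, tau_max = 20_000, 6
        ens = conditioned_ensemble(two_spin, params, n_series, tau_max, 200)
        exact = two_spin_exact_lag_distributions(params, ens.reference_state, tau_max)
        for tau in range(tau_max + 1):
            counts = np.zeros(4)
            idx = (ens.samples[:, tau, 0] == 1) * 1 + (ens.samples[:, tau, 1] == 1) * 2
            for v in range(4):
                counts[v] = np.sum(idx == v)
            assert total_variation(counts / n_series, exact[tau]) < 0.03

    def test_floors_enforced(self, two_spin):
        params = DynamicsParams(2.0, seed=0)
        with pytest.raises(ValueError, match="n_series"):
            conditioned_ensemble(two_spin, params, 10, 3, 50)
        with pytest.raises(ValueError, match="burn_in"):
            conditioned_ensemble(two_spin, params, 200, 3, 0)


class TestMIDecayCurve:
    def test_lag_zero_recovers_prior_entropy(self, two_spin):
        params = DynamicsParams(2.0, seed=2)
        prior = equilibrium_samples(two_spin, params, 4000, 100, 1)
        ens = conditioned_ensemble(two_spin, params, 500, 4, 100)
        curve = mi_decay_curve(ens, 0, prior)
        assert curve.info_bits[0] == pytest.approx(curve.prior_entropy_bits, abs=1e-12)

    def test_matches_exact_curve_from_matrix_powers(self, two_spin):
        params = DynamicsParams(2.0, rule="glauber", seed=3)
        tau_max = 6
        prior = equilibrium_samples(two_spin, params, 30_000, 200, 1)
        ens = conditioned_ensemble(two_spin, params, 30_000, tau_max, 200)
        exact = two_spin_exact_lag_distributions(params, ens.reference_state, tau_max)
        curve = mi_decay_curve(ens, 0, prior)
        # exact conditional entropy of unit 0: marginalize lag distributions
        from idtnet.infotheory import binary_entropy

        p_prior_up = (prior[:, 0] == 1).mean()
        for tau in range(tau_max + 1):
            p_up = exact[tau][1] + exact[tau][3]  # states with bit 0 set
            expected = binary_entropy(p_prior_up) - binary_entropy(p_up)
            assert curve.info_bits[tau] == pytest.approx(max(0, expected), abs=0.02)

    def test_vectorized_curves_agree_with_single(self, triangle):
        params = DynamicsParams(2.0, seed=4)
        prior = equilibrium_samples(triangle, params, 2000, 100, 1)
        ens = conditioned_ensemble(triangle, params, 400, 5, 100)
        info, h_prior = mi_decay_curves(ens, prior)
        for unit in range(3):
            curve = mi_decay_curve(ens, unit, prior)
            np.testing.assert_allclose(info[:, unit], curve.info_bits, atol=1e-12)
            assert h_prior[unit] == pytest.approx(curve.prior_entropy_bits)

    def test_info_decays_on_mixing_chain(self, two_spin):
        params = DynamicsParams(20.0, seed=5)  # hot: mixes in ~1 sweep
        prior = equilibrium_samples(two_spin, params, 5000, 100, 1)
        ens = conditioned_ensemble(two_spin, params, 5000, 8, 100)
        info, _ = mi_decay_curves(ens, prior)
        assert info[0].min() > 0.9
        assert info[-1].max() < 0.02


class TestEstimateIDT:
    def test_exact_exponential_closed_form(self):
        lags = np.arange(0, 12)
        info = 2.0 ** (-lags.astype(float))
        est = estimate_idt((lags, info), epsilon_bits=2.0**-5)
        assert est.d_sweeps == pytest.approx(5.0, abs=1e-9)
        assert est.reliable

    def test_curve_below_epsilon_gives_zero(self):
        lags = np.arange(0, 8)
        info = np.full(8, 1e-4)
        est = estimate_idt((lags, info), epsilon_bits=0.01)
        assert est.d_sweeps == 0.0

    def test_scale_equivariance(self):
        # multiplying the curve by c shifts d by log2(c)/|slope| exactly
        lags = np.arange(0, 15)
        info = 2.0 ** (-0.5 * lags.astype(float))
        base = estimate_idt((lags, info), 2.0**-6)
        scaled = estimate_idt((lags, 4.0 * info), 2.0**-6)
        assert scaled.d_sweeps - base.d_sweeps == pytest.approx(
            np.log2(4.0) / 0.5, abs=1e-9
        )

    def test_noisy_exponential_recovery_within_five_percent(self):
        # known decay 0.5 bit-halvings per sweep; multiplicative noise
        rng = np.random.default_rng(6)
        lags = np.arange(0, 20)
        errors = []
        truth = (np.log2(1.0) - np.log2(0.01)) / 0.5
        for _ in range(300):
            info = 2.0 ** (-0.5 * lags + rng.normal(0, 0.15, lags.size))
            est = estimate_idt((lags, info), 0.01)
            errors.append(abs(est.d_sweeps - truth) / truth)
        assert np.median(errors) < 0.05

    def test_flat_curve_flagged_unreliable(self):
        lags = np.arange(0, 10)
        info = np.full(10, 0.5)
        est = estimate_idt((lags, info), 0.01)
        assert not est.reliable and np.isnan(est.d_sweeps)

    def test_fast_crossing_bridged_and_flagged(self):
        # drops under the floor after one lag: interpolated, flagged
        lags = np.arange(0, 6)
        info = np.array([1.0, 1e-4, 0.0, 0.0, 0.0, 0.0])
        est = estimate_idt((lags, info), 0.01, noise_floor_bits=1e-3)
        assert not est.reliable
        assert 0.0 < est.d_sweeps < 1.0


class TestAggregateByDegree:
    def test_identical_values_zero_sem(self):
        df = aggregate_by_degree([2.0, 2.0, 2.0], [1, 1, 1])
        assert df.loc[0, "sem_d_sweeps"] == 0.0

    def test_single_unit_bin_suppresses_sem(self):
        df = aggregate_by_degree([1.0, 2.0, 3.0], [1, 1, 2])
        row = df[df["degree_bin_low"] == 2].iloc[0]
        assert np.isnan(row["sem_d_sweeps"])
        assert row["mean_d_sweeps"] == 3.0

    def test_log_bins_above_exact_range(self):
        bins = _degree_bins(100, exact_max=20, bins_per_decade=4)
        exact = [b for b in bins if b[0] == b[1] and b[0] <= 20]
        assert len(exact) == 20
        assert bins[-1][1] == 100
        lows = [lo for lo, hi in bins]
        highs = [hi for lo, hi in bins]
        assert all(l2 == h1 + 1 for h1, l2 in zip(highs[:-1], lows[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_by_degree([], [])


class TestNoiseFloor:
    def test_floor_scales_down_with_series(self, rng):
        prior = np.where(rng.random((4000, 5)) < 0.5, 1, -1).astype(np.int8)
        low = noise_floor(prior, 500, np.random.default_rng(0)).mean()
        high = noise_floor(prior, 50_000, np.random.default_rng(0)).mean()
        assert high < low

    def test_floor_below_default_epsilon_for_symmetric_units(self, rng):
        prior = np.where(rng.random((4000, 8)) < 0.5, 1, -1).astype(np.int8)
        floor = noise_floor(prior, 5000, np.random.default_rng(1))
        assert np.all(floor < 0.01)


class TestDecayCurveMonotonicity:
    def test_average_over_references_non_increasing_within_noise(self):
        """Pooled over several reference states, info(tau) should not rise."""
        rng = np.random.default_rng(9)
        deg = sample_power_law_degrees(40, gamma=1.6, seed=9)
        net = build_configuration_graph(deg, seed=9)
        params = DynamicsParams(6.0, rule="metropolis")
        curves = []
        for _ in range(6):
            prior = equilibrium_samples(net, params, 1500, 150, 1, rng)
            ens = conditioned_ensemble(net, params, 800, 8, 150, rng)
            info, _ = mi_decay_curves(ens, prior)
            curves.append(info.mean(axis=1))
        pooled = np.mean(curves, axis=0)
        sem = np.std(curves, axis=0, ddof=1) / np.sqrt(len(curves))
        rises = np.diff(pooled)
        tol = 2 * np.hypot(sem[:-1], sem[1:])
        assert np.all(rises <= tol)
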