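"""Spike-phase synchrony, rates, spectra, and group comparisons."""

import numpy as np
import pytest

from bgspike.metrics import (
    compare_sync_groups, mean_firing_rate, population_oscillation_frequency,
    spike_phases, sync_order_parameter, sync_series,
)
from bgspike.raster import SpikeRaster


def regular_raster(n_neurons, period, duration, offsets=None):
    offsets = np.zeros(n_neurons) if offsets is None else offsets
    ids, times = [], []
    for j in range(n_neurons):
        t = np.arange(offsets[j], duration, period)
        ids.append(np.full(t.size, j))
        times.append(t)
    return SpikeRaster(
        np.concatenate(ids), np.concatenate(times), n_neurons, duration
    )


class TestSpikePhases:
    def test_phase_zero_at_spike_and_pi_at_midpoint(self):
        r = regular_raster(1, 100.0, 1000.0)
        field = spike_phases(r, [100.0, 150.0])
        assert field.valid.all()
        assert field.phases[0, 0] == pytest.approx(0.0)
        assert field.phases[0, 1] == pytest.approx(np.pi)

    def test_invalid_outside_bracketing_spikes(self):
        r = SpikeRaster(np.array([0, 0]), np.array([400.0, 600.0]), 2, 1000.0)
        field = spike_phases(r, [100.0, 500.0, 700.0])
        assert field.valid[0].tolist() == [False, True, False]
        assert not field.valid[1].any()  # silent neuron never valid

    def test_matches_brute_force_search_oracle(self, random_raster):
        q = np.linspace(50, 950, 19)
        field = spike_phases(random_raster, q)
        trains = random_raster.spike_trains()
        for j, train in enumerate(trains):
            for qi, t in enumerate(q):
                bracket = None
                for k in range(len(train) - 1):
                    if train[k] <= t < train[k + 1]:
                        bracket = k
                        break
                if bracket is None:
                    assert not field.valid[j, qi]
                else:
                    expected = (
                        2 * np.pi * (t - train[bracket])
                        / (train[bracket + 1] - train[bracket])
                    )
                    assert field.valid[j, qi]
                    assert field.phases[j, qi] == pytest.approx(expected)


class TestOrderParameter:
    def test_identical_phases_give_unity(self):
        r = regular_raster(20, 50.0, 1000.0)
        series = sync_series(r, 100.0, 900.0)
        assert series.mean() == pytest.approx(1.0)

    def test_antiphase_groups_cancel(self):
        offsets = np.array([0.0] * 10 + [25.0] * 10)
        r = regular_raster(20, 50.0, 1000.0, offsets)
        series = sync_series(r, 100.0, 900.0)
        assert series.mean() == pytest.approx(0.0, abs=1e-9)

    def test_uniform_random_phases_scale_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(0)
        n = 2500
        offsets = rng.uniform(0, 50.0, n)
        r = regular_raster(n, 50.0, 500.0, offsets)
        series = sync_series(r, 100.0, 400.0)
        assert series.mean() < 3.0 / np.sqrt(n)

    def test_invariant_to_relabeling_and_time_translation(
        self, random_raster
    ):
        base = sync_series(random_raster, 200.0, 800.0).mean()
        perm = np.random.default_rng(1).permutation(random_raster.n_neurons)
        relabeled = SpikeRaster(
            perm[random_raster.neuron_ids], random_raster.times,
            random_raster.n_neurons, random_raster.duration,
        )
        assert sync_series(relabeled, 200.0, 800.0).mean() == pytest.approx(
            base
        )
        shifted = SpikeRaster(
            random_raster.neuron_ids, random_raster.times + 100.0,
            random_raster.n_neurons, random_raster.duration + 100.0,
        )
        assert sync_series(shifted, 300.0, 900.0).mean() == pytest.approx(
            base
        )

    def test_no_valid_neurons_flagged_not_zero(self):
        r = SpikeRaster(np.array([0]), np.array([500.0]), 1, 1000.0)
        series = sync_series(r, 0.0, 100.0)
        assert np.isnan(series.R).all()
        assert np.isnan(series.mean())


class TestFiringRate:
    def test_simple_counts(self):
        r = SpikeRaster(
            np.zeros(10), np.linspace(50, 950, 10), 1, 1000.0
        )
        assert mean_firing_rate(r) == pytest.approx(10.0)
        empty = SpikeRaster(np.array([]), np.array([]), 5, 1000.0)
        assert mean_firing_rate(empty) == 0.0

    def test_additive_over_disjoint_windows(self, random_raster):
        T = random_raster.duration
        whole = mean_firing_rate(random_raster, (0, T))
        a = mean_firing_rate(random_raster, (0, T / 2))
        b = mean_firing_rate(random_raster, (T / 2, T))
        assert whole == pytest.approx((a + b) / 2)

    def test_rejects_degenerate_window(self, random_raster):
        with pytest.raises(ValueError):
            mean_firing_rate(random_raster, (100.0, 100.0))


class TestOscillationFrequency:
    @pytest.mark.parametrize("f_mod,tol", [(10.0, 1.0), (4.0, 0.5)])
    def test_detects_sinusoidal_rate_modulation(self, f_mod, tol):
        rng = np.random.default_rng(5)
        duration, n = 4000.0, 200
        t = np.arange(0, duration, 1.0)
        rate = 20.0 * (1 + 0.8 * np.sin(2 * np.pi * f_mod * t / 1000.0))
        p = rate / 1000.0
        ids, times = [], []
        for j in range(n):
            mask = rng.random(t.size) < p
            times.append(t[mask])
            ids.append(np.full(mask.sum(), j))
        r = SpikeRaster(
            np.concatenate(ids), np.concatenate(times), n, duration
        )
        f = population_oscillation_frequency(r)
        assert f == pytest.approx(f_mod, abs=tol)

    def test_homogeneous_poisson_has_no_peak(self):
        rng = np.random.default_rng(6)
        duration, n = 3000.0, 100
        counts = rng.poisson(20.0 * duration / 1000.0, n)
        ids = np.repeat(np.arange(n), counts)
        times = rng.uniform(0, duration, counts.sum())
        r = SpikeRaster(ids, times, n, duration)
        assert population_oscillation_frequency(r) is None

    def test_requires_a_second_of_data(self):
        short = SpikeRaster(
            np.array([0, 0]), np.array([10.0, 20.0]), 1, 500.0
        )
        with pytest.raises(ValueError):
            population_oscillation_frequency(short)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        a = np.array([0.5, 0.6, 0.7, 0.5])
        res = compare_sync_groups(a, a)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_shifted_gaussians_highly_significant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 0.1, 30)
        b = rng.normal(1.0, 0.1, 30)
        assert compare_sync_groups(a, b).p_value < 1e-6

    def test_matches_permutation_oracle_on_small_groups(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.0, 8)
        res = compare_sync_groups(a, b)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        count = 0
        n_perm = 5000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            diff = abs(pooled[:8].mean() - pooled[8:].mean())
            count += diff >= observed
        p_perm = count / n_perm
        assert res.p_value == pytest.approx(p_perm, abs=0.05)

    def test_degenerate_groups_flagged(self):
        res = compare_sync_groups([1.0, 1.0], [1.0, 1.0])
        assert res.degenerate
        with pytest.raises(ValueError):
            compare_sync_groups([1.0], [1.0, 2.0])
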