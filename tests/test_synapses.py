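"""Gating kinetics, receptor currents, Mg block, lateral kernels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgspike import synapses as syn
from bgspike.params import CD21, R_G, R_S
from bgspike.synapses import (
    AMPA, GABA, NMDA, SynapseState, build_lateral_kernel, da_scaled_weight,
    lateral_current, lateral_radius, mg_block, receptor_current,
    striatal_gain, update_gating,
)


class TestGating:
    def test_exponential_decay_without_input(self):
        s = SynapseState.zeros((1,), AMPA)
        s.h[:] = 1.0
        zero = np.zeros(1)
        # Euler decay over tau*ln2 should roughly halve h
        n = int(round(6 * np.log(2) / 0.01))
        for _ in range(n):
            update_gating(s, zero, 0.01)
        assert s.h[0] == pytest.approx(0.5, rel=0.01)

    def test_single_spike_deposits_dt_over_tau(self):
        s = SynapseState.zeros((1,), AMPA)  # tau = 6
        update_gating(s, np.ones(1), 0.1)
        assert s.h[0] == pytest.approx(1.0 / 60.0)

    def test_saturating_impulse_sets_gate_to_one(self):
        s = SynapseState.zeros((1,), GABA, impulse="saturating")
        update_gating(s, np.ones(1), 1.0)
        assert s.h[0] == 1.0
        update_gating(s, np.zeros(1), 1.0)
        assert s.h[0] == pytest.approx(0.75)  # decay 1 - dt/tau, tau=4

    def test_poisson_stationary_mean_matches_event_driven_oracle(self):
        # event-driven: h(t) = sum over spikes of (dt/tau) exp(-(t-ti)/tau);
        # stationary mean = rate * dt_impulse_area / 1  => rate(1/ms)*1ms
        rng = np.random.default_rng(3)
        dt, tau, rate_hz, T = 0.1, 6.0, 40.0, 20_000.0
        p = rate_hz * dt / 1000.0
        spikes = rng.random(int(T / dt)) < p
        s = SynapseState.zeros((1,), AMPA)
        total = 0.0
        for k in range(spikes.size):
            update_gating(s, np.array([spikes[k]], dtype=float), dt)
            total += s.h[0]
        sim_mean = total / spikes.size
        # independent oracle: superpose exact exponential kernels
        t_sp = np.flatnonzero(spikes) * dt
        grid = np.arange(0, T, 50.0)
        h_oracle = np.zeros_like(grid)
        for i, t in enumerate(grid):
            past = t - t_sp[t_sp <= t]
            h_oracle[i] = np.sum((dt / tau) * np.exp(-past / tau))
        assert sim_mean == pytest.approx(h_oracle.mean(), rel=0.05)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_gating_stays_bounded_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        s = SynapseState.zeros((8,), GABA)
        for _ in range(200):
            update_gating(s, (rng.random(8) < 0.3).astype(float), 1.0)
            assert np.all(s.h >= 0.0) and np.all(s.h <= 1.0)


class TestReceptorCurrents:
    def test_zero_at_reversal_potential(self):
        s = SynapseState.zeros((1,), GABA, W=1.0)
        s.h[:] = 1.0
        I = receptor_current(s, np.array([GABA.E_rev]))
        assert I[0] == 0.0

    def test_gaba_inhibitory_above_reversal(self):
        s = SynapseState.zeros((1,), GABA, W=1.0)
        s.h[:] = 1.0
        assert receptor_current(s, np.array([-50.0]))[0] == pytest.approx(-10.0)

    def test_ampa_drives_depolarization(self):
        s = SynapseState.zeros((1,), AMPA, W=2.0)
        s.h[:] = 0.5
        assert receptor_current(s, np.array([-60.0]))[0] == pytest.approx(60.0)

    def test_nmda_current_is_mg_blocked(self):
        s = SynapseState.zeros((1,), NMDA, W=1.0)
        s.h[:] = 1.0
        V = np.array([-65.0])
        expected = (NMDA.E_rev - V) * mg_block(V)
        assert receptor_current(s, V)[0] == pytest.approx(expected[0])


class TestMgBlock:
    def test_known_values(self):
        assert mg_block(0.0) == pytest.approx(3.57 / 4.57, rel=1e-6)
        assert mg_block(-65.0) == pytest.approx(0.0595, abs=0.001)

    def test_monotone_in_voltage_and_bounded(self):
        v = np.linspace(-100, 60, 200)
        b = mg_block(v)
        assert np.all(np.diff(b) > 0)
        assert np.all((b > 0) & (b < 1))

    def test_requires_positive_mg(self):
        with pytest.raises(ValueError):
            mg_block(0.0, mg=0.0)


class TestDopamineGains:
    def test_stn_gpe_weight_attenuation(self):
        assert da_scaled_weight(20.0, 0.5) == pytest.approx(19.0)
        assert da_scaled_weight(1.0, 0.9) == pytest.approx(0.91)
        assert da_scaled_weight(7.0, 0.0) == pytest.approx(7.0)

    def test_striatal_gain_sigmoid_midpoints(self):
        assert striatal_gain(0.0, "D2") == pytest.approx(3.75)
        assert striatal_gain(1.0, "D1") == pytest.approx(5.0)

    def test_striatal_gain_directions(self):
        assert striatal_gain(0.9, "D1") > striatal_gain(0.1, "D1")
        assert striatal_gain(0.9, "D2") < striatal_gain(0.1, "D2")

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            striatal_gain(0.5, "D3")


class TestLateralKernels:
    def test_stencil_sizes_match_published_neighborhoods(self):
        k_stn = build_lateral_kernel("STN", 0.5)
        k_gpe = build_lateral_kernel("GPe", 0.5)
        assert k_stn.weights.shape == (5, 5)
        assert k_gpe.weights.shape == (11, 11)

    def test_self_term_excluded_and_gaussian_at_unit_distance(self):
        k = build_lateral_kernel("STN", 0.5)
        c = k.weights.shape[0] // 2
        assert k.weights[c, c] == 0.0
        expected = k.amplitude * np.exp(-1.0 / k.effective_radius**2)
        assert k.weights[c, c + 1] == pytest.approx(expected)
        # reflection symmetry of the stencil
        np.testing.assert_allclose(k.weights, k.weights[::-1, :])
        np.testing.assert_allclose(k.weights, k.weights[:, ::-1])

    def test_stn_kernel_shrinks_with_dopamine_under_default_mapping(self):
        low = build_lateral_kernel("STN", 0.1).total_weight()
        high = build_lateral_kernel("STN", 0.9).total_weight()
        assert low > high

    def test_gpe_kernel_grows_with_dopamine_under_default_mapping(self):
        low = build_lateral_kernel("GPe", 0.1).total_weight()
        high = build_lateral_kernel("GPe", 0.9).total_weight()
        assert high > low

    def test_as_printed_mapping_matches_published_formulas(self):
        assert lateral_radius("STN", 0.5, "as_printed") == pytest.approx(
            R_S * CD21 * 0.5
        )
        assert lateral_radius("GPe", 0.5, "as_printed") == pytest.approx(
            R_G * (1 - CD21 * 0.5)
        )

    def test_unknown_mapping_rejected(self):
        with pytest.raises(ValueError, match="unknown radius mapping"):
            lateral_radius("STN", 0.5, "bogus")


class TestLateralCurrent:
    def test_silent_field_gives_zero_current(self):
        k = build_lateral_kernel("STN", 0.5)
        h = np.zeros((7, 7))
        V = np.full((7, 7), -60.0)
        assert np.all(lateral_current(k, h, V, AMPA) == 0.0)

    def test_impulse_response_is_kernel_shaped(self):
        k = build_lateral_kernel("STN", 0.5)
        h = np.zeros((7, 7))
        h[3, 3] = 1.0
        V = np.full((7, 7), -60.0)
        I = lateral_current(k, h, V, AMPA)
        expected = np.zeros((7, 7))
        expected[1:6, 1:6] = k.weights * (AMPA.E_rev + 60.0)
        np.testing.assert_allclose(I, expected)

    @pytest.mark.parametrize("receptor", [AMPA, NMDA, GABA])
    def test_matches_brute_force_double_sum(self, receptor):
        """Stencil convolution equals the explicit double loop (oracle)."""
        rng = np.random.default_rng(7)
        nucleus = "GPe" if receptor is GABA else "STN"
        k = build_lateral_kernel(nucleus, 0.3)
        n = 7
        h = rng.random((n, n))
        V = rng.uniform(-80, -40, (n, n))
        half = k.weights.shape[0] // 2
        brute = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                acc = 0.0
                for p in range(n):
                    for q in range(n):
                        di, dj = p - i, q - j
                        if abs(di) <= half and abs(dj) <= half:
                            acc += k.weights[half + di, half + dj] * h[p, q]
                brute[i, j] = acc * (receptor.E_rev - V[i, j])
                if receptor.kind == "NMDA":
                    brute[i, j] *= mg_block(V[i, j])
        np.testing.assert_allclose(
            lateral_current(k, h, V, receptor), brute, rtol=1e-10
        )
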