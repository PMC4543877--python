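"""Hopf oscillator dynamics, phase coupling and network integration."""

import dataclasses

import numpy as np
import pytest

from antcpg.pattern_formation import fit_fourier, sine_pattern
from antcpg.rhythm_core import (
    OSCILLATOR_NAMES,
    CouplingEdge,
    NetworkSpec,
    NumericalBlowUpError,
    OscillatorParams,
    OscillatorState,
    coupling_pair,
    default_network,
    drive_signal,
    hopf_derivatives,
    network_from_dict,
    network_to_dict,
    relax_radius,
    resample_amplitudes,
    simulate_network,
)

HS = OscillatorParams(v=1.45, mu=39.0, C=-60.0, gamma=20.0, gamma_c=20.0)


def _sine_patterns(n=5):
    return [sine_pattern() for _ in range(n)]


class TestHopfDerivatives:
    def test_radius_fixed_point(self):
        state = dataclasses.replace(OscillatorState.initial(HS), r=39.0)
        dr, _, _ = hopf_derivatives(state, HS)
        assert dr == 0.0

    def test_coupling_vanishes_at_the_phase_bias(self):
        """When theta_j - theta_i equals phi_ij the sine argument is zero and
        the oscillator runs at its intrinsic frequency."""
        state = OscillatorState.initial(HS, theta=0.3)
        neighbors = [(0.3 + np.pi / 9, 20.0, np.pi / 9)]
        _, dth, _ = hopf_derivatives(state, HS, neighbors)
        assert dth == pytest.approx(2 * np.pi * 1.45, abs=1e-12)

    def test_literal_radial_rate_value(self):
        """Direct substitution: gamma=20, mu=39, r=1 gives 30,400 deg/s."""
        state = dataclasses.replace(OscillatorState.initial(HS), r=1.0)
        dr, _, _ = hopf_derivatives(state, HS, radial_mode="literal")
        assert dr == pytest.approx(20.0 * (39.0**2 - 1.0) * 1.0)

    def test_offset_relaxation(self):
        state = dataclasses.replace(OscillatorState.initial(HS), c=0.0)
        _, _, dc = hopf_derivatives(state, HS)
        assert dc == pytest.approx(20.0 * (-60.0))

    def test_non_finite_state_raises(self):
        state = dataclasses.replace(OscillatorState.initial(HS), r=np.nan)
        with pytest.raises(NumericalBlowUpError):
            hopf_derivatives(state, HS)


class TestDriveSignal:
    def test_zero_pattern_returns_offset(self):
        zero = fit_fourier(np.full(256, 5.0))  # constant series -> F == 0
        state = OscillatorState.initial(HS)
        assert drive_signal(state, zero) == pytest.approx(HS.C)

    def test_offset_plus_amplitude_at_pattern_peak(self):
        """c=-60, amplitude 39, F=1  ->  x = -21 deg."""
        state = dataclasses.replace(
            OscillatorState.initial(HS), r=39.0, theta=np.pi / 2, amp_upper=39.0
        )
        assert drive_signal(state, sine_pattern()) == pytest.approx(-21.0)

    def test_pure_sine_range_is_twice_mu(self):
        """Noise off, the drive spans C +/- mu over a cycle."""
        spec = NetworkSpec(oscillators=(HS,), edges=(), init="aligned")
        traj = simulate_network(spec, [sine_pattern()], duration=5.0, seed=0)
        x = traj.x[400:, 0]  # past the offset/radius transient
        assert np.max(x) - np.min(x) == pytest.approx(2 * 39.0, abs=0.05)
        assert np.max(x) == pytest.approx(-60.0 + 39.0, abs=0.05)


class TestResampling:
    def test_deterministic_limit(self, rng):
        state = OscillatorState.initial(HS)
        out = resample_amplitudes(state, HS, rng)
        assert out.amp_upper == HS.mu and out.amp_lower == HS.mu
        assert out.v_eff == HS.v

    def test_draw_statistics_match_table_sds(self):
        """Intact HS: mu=39, U=8, L=9 -> long-run draw SDs of ~8 and ~9 deg."""
        params = OscillatorParams(v=1.45, mu=39.0, C=-60.0, U=8.0, L_sd=9.0)
        rng = np.random.default_rng(11)
        state = OscillatorState.initial(params)
        ups, los = [], []
        for _ in range(2000):
            state = resample_amplitudes(state, params, rng)
            ups.append(state.amp_upper)
            los.append(state.amp_lower)
        assert np.std(ups) == pytest.approx(8.0, rel=0.08)
        assert np.std(los) == pytest.approx(9.0, rel=0.08)
        assert np.mean(ups) == pytest.approx(39.0, rel=0.02)

    def test_truncation_at_zero(self):
        params = OscillatorParams(v=1.45, mu=1.0, C=0.0, U=50.0)
        rng = np.random.default_rng(0)
        draws = [
            resample_amplitudes(OscillatorState.initial(params), params, rng).amp_upper
            for _ in range(200)
        ]
        assert min(draws) == 0.0  # truncated, never negative

    def test_same_seed_same_draws(self):
        params = OscillatorParams(v=1.45, mu=39.0, C=-60.0, U=8.0, L_sd=9.0, v_sd=0.05)
        state = OscillatorState.initial(params)
        a = resample_amplitudes(state, params, np.random.default_rng(5))
        b = resample_amplitudes(state, params, np.random.default_rng(5))
        assert a == b


class TestRadialDynamics:
    @pytest.mark.parametrize("r0", [1.0, 5.0, 20.0, 100.0, 350.0])
    def test_convergence_to_mu_from_any_positive_start(self, r0):
        assert relax_radius(HS, r0=r0) == pytest.approx(39.0, abs=1e-6)

    def test_fast_convergence_window(self):
        """|r - mu| < 1% of mu well within a second (rate 2*gamma = 40/s)."""
        spec = NetworkSpec(oscillators=(HS,), edges=(), init="aligned")
        traj = simulate_network(spec, _sine_patterns(1), duration=1.0, seed=0)
        k = int(0.5 / spec.dt)
        assert np.all(np.abs(traj.r[k:, 0] - 39.0) < 0.01 * 39.0)

    def test_literal_mode_blows_up_at_default_step(self):
        """The degree-scaled radial equation is stiff: gamma*mu^2 ~ 3e4/s
        cannot be integrated with fixed 5 ms steps and must trip the
        blow-up guard of the network integrator."""
        spec = NetworkSpec(
            oscillators=(HS,), edges=(), radial_mode="literal", init="aligned"
        )
        with pytest.raises(NumericalBlowUpError):
            simulate_network(spec, _sine_patterns(1), duration=1.0, seed=0)

    def test_literal_mode_converges_at_fine_step(self):
        assert relax_radius(HS, r0=1.0, dt=2e-6, radial_mode="literal", max_time=0.5) == pytest.approx(39.0, abs=1e-6)


class TestPhaseCoupling:
    def test_uncoupled_phase_advance_per_step(self):
        """One 5 ms step of a 1 Hz oscillator advances theta by 2*pi*0.005."""
        params = OscillatorParams(v=1.0, mu=10.0, C=0.0)
        spec = NetworkSpec(oscillators=(params,), edges=(), init="aligned")
        traj = simulate_network(spec, _sine_patterns(1), duration=0.005, seed=0)
        assert traj.theta[1, 0] - traj.theta[0, 0] == pytest.approx(
            2 * np.pi * 0.005, rel=1e-12
        )

    def test_two_oscillator_pair_locks_at_the_bias(self):
        """Symmetric coupling (w, phi)/(w, -phi), equal v: the steady phase
        difference equals phi to 1e-6 rad (analytic fixed point of
        sin(delta - phi) = 0)."""
        p = OscillatorParams(v=1.45, mu=10.0, C=0.0)
        spec = NetworkSpec(
            oscillators=(p, p), edges=coupling_pair(0, 1, 20.0, np.pi / 9)
        )
        traj = simulate_network(spec, _sine_patterns(2), duration=10.0, seed=42)
        delta = traj.theta[-1, 1] - traj.theta[-1, 0]
        delta = np.angle(np.exp(1j * delta))
        assert delta == pytest.approx(np.pi / 9, abs=1e-6)

    def test_chain_composition_equal_frequencies(self):
        """With equal intrinsic frequencies, every steady pairwise phase
        difference equals the summed biases along the connecting path."""
        p = OscillatorParams(v=1.45, mu=10.0, C=0.0)
        biases = (-np.pi / 9, -np.pi / 3, 4 * np.pi / 3, np.pi / 9)
        weights = (20.0, 1.0, 1.0, 20.0)
        edges = []
        for k, (w, phi) in enumerate(zip(weights, biases)):
            edges.extend(coupling_pair(k, k + 1, w, phi))
        spec = NetworkSpec(oscillators=(p,) * 5, edges=tuple(edges))
        traj = simulate_network(spec, _sine_patterns(), duration=30.0, seed=7)
        th = traj.theta[-1]
        cum = np.concatenate([[0.0], np.cumsum(biases)])
        for i in range(5):
            for j in range(5):
                expect = cum[j] - cum[i]
                got = np.angle(np.exp(1j * (th[j] - th[i] - expect)))
                assert abs(got) < 1e-6, (i, j)

    def test_default_network_left_right_antiphase(self):
        """Noise off, the left and right HS oscillators settle 180 deg apart
        (composition of the biases through the neck); the neck's slower
        intrinsic frequency shifts both neck edges symmetrically so the
        composition is preserved."""
        spec = default_network("intact", stochastic=False)
        traj = simulate_network(spec, _sine_patterns(), duration=30.0, seed=1)
        d = traj.theta[-2000:, 3] - traj.theta[-2000:, 1]
        mean_deg = np.rad2deg(np.angle(np.mean(np.exp(1j * d))))
        assert abs(abs(mean_deg) - 180.0) < 0.1

    def test_default_network_sp_leads_hs(self):
        """Noise off, theta_SP - theta_HS settles near the 20 deg bias (plus
        the small symmetric frequency-compromise shift)."""
        spec = default_network("intact", stochastic=False)
        traj = simulate_network(spec, _sine_patterns(), duration=30.0, seed=1)
        d = np.rad2deg(
            np.angle(np.mean(np.exp(1j * (traj.theta[-2000:, 4] - traj.theta[-2000:, 3]))))
        )
        assert d == pytest.approx(20.72, abs=0.1)

    def test_frequency_entrainment(self):
        """All oscillators of the locked noise-free network share one mean
        cycle frequency despite different intrinsic frequencies."""
        spec = default_network("intact", stochastic=False)
        traj = simulate_network(spec, _sine_patterns(), duration=40.0, seed=2)
        k0 = 6000  # the slowest (weak-edge) locking mode needs ~30 s to die
        span = traj.time[-1] - traj.time[k0]
        freqs = (traj.theta[-1] - traj.theta[k0]) / (2 * np.pi * span)
        assert np.ptp(freqs) < 1e-6
        assert np.mean(freqs) == pytest.approx((4 * 1.45 + 1.25) / 5, abs=1e-3)


class TestNetworkInfrastructure:
    def test_edges_must_be_antisymmetric(self):
        p = OscillatorParams(v=1.45, mu=10.0, C=0.0)
        bad = (
            CouplingEdge(source=1, target=0, weight=20.0, phase_bias=0.5),
            CouplingEdge(source=0, target=1, weight=20.0, phase_bias=0.5),
        )
        with pytest.raises(ValueError, match="antisymmetric"):
            NetworkSpec(oscillators=(p, p), edges=bad)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            OscillatorParams(v=1.45, mu=39.0, C=0.0, gamma=-1.0)
        with pytest.raises(ValueError):
            OscillatorParams(v=1.45, mu=-5.0, C=0.0)
        with pytest.raises(ValueError):
            CouplingEdge(source=0, target=1, weight=-2.0, phase_bias=0.0)

    def test_default_coupling_parameters(self):
        """The default chain carries the published weights and biases."""
        spec = default_network()
        lut = {(e.source, e.target): e for e in spec.edges}
        assert lut[(1, 0)].weight == 20.0
        assert lut[(1, 0)].phase_bias == pytest.approx(-np.pi / 9)
        assert lut[(2, 1)].phase_bias == pytest.approx(-np.pi / 3)
        assert lut[(3, 2)].phase_bias == pytest.approx(4 * np.pi / 3)
        assert lut[(4, 3)].phase_bias == pytest.approx(np.pi / 9)
        assert lut[(2, 1)].weight == 1.0
        # offsets sign-inverted on the right side
        assert spec.oscillators[1].C == -spec.oscillators[3].C == -60.0
        assert spec.oscillators[0].C == -spec.oscillators[4].C == 22.0

    def test_bit_identical_trajectories_for_equal_seeds(self):
        spec = default_network("intact")
        pats = _sine_patterns()
        a = simulate_network(spec, pats, duration=5.0, seed=99)
        b = simulate_network(spec, pats, duration=5.0, seed=99)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.x, b.x)
        c = simulate_network(spec, pats, duration=5.0, seed=100)
        assert not np.array_equal(c.theta, a.theta)

    def test_trajectory_csv_columns(self, tmp_path):
        spec = default_network("intact")
        traj = simulate_network(spec, _sine_patterns(), duration=1.0, seed=0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert "time_s" in df.columns
        for name in OSCILLATOR_NAMES:
            for prefix in ("r", "theta_wrapped", "c", "x"):
                assert f"{prefix}_{name}" in df.columns

    def test_config_dict_round_trip(self):
        spec = default_network("ablated", stochastic=True)
        back = network_from_dict(network_to_dict(spec))
        assert back == spec
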