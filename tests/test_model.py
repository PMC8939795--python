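"""Core circuit model: activation, afferent drive, integration, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from cbgtloop.circuit import (
    CircuitGraph,
    PopulationSpec,
    POP_INDEX,
    SOURCE_INDEX,
    SOURCES,
    compile_circuit,
    default_circuit,
)
from cbgtloop.simulate import (
    DivergenceError,
    SimulationConfig,
    afferent_drive,
    draw_noise,
    neural_mass_step,
    sigmoid_rate,
    simulate,
)


class TestSigmoid:
    @pytest.mark.parametrize("slope", [0.1, 1.0, 2.0, 10.0])
    def test_midpoint_is_half(self, slope):
        assert sigmoid_rate(0.0, slope) == pytest.approx(0.5)

    def test_scalar_value(self):
        # independent evaluation: 1/(1+e^-2) for v=1, R=2
        assert sigmoid_rate(1.0, 2.0) == pytest.approx(0.880797, abs=1e-6)

    def test_saturation_limits(self):
        assert sigmoid_rate(1e3, 1.0) == pytest.approx(1.0)
        assert sigmoid_rate(-1e3, 1.0) == pytest.approx(0.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            sigmoid_rate(np.nan, 1.0)
        with pytest.raises(ValueError):
            sigmoid_rate(0.0, -1.0)

    @given(
        v=st.floats(-8, 8),
        dv=st.floats(1e-3, 4),
        slope=st.floats(0.05, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, v, dv, slope):
        assert sigmoid_rate(v + dv, slope) > sigmoid_rate(v, slope)


def _two_source_circuit(weight=2.0, delay=0.02, slope=1.0):
    """Minimal valid circuit with a single active M2 -> STN connection."""
    pops = [
        PopulationSpec(pid, "inhibitory" if pid in ("M2.II", "STR", "GPe", "GPi")
                       else "excitatory", 0.01, 10.0, slope, 0.0)
        for pid in POP_INDEX
    ]
    w = np.zeros((6, 6))
    d = np.zeros((6, 6))
    w[SOURCE_INDEX["STN"], SOURCE_INDEX["M2"]] = weight
    d[SOURCE_INDEX["STN"], SOURCE_INDEX["M2"]] = delay
    return CircuitGraph(pops, w, d, [])


class TestAfferentDrive:
    def test_no_connections_gives_zero(self):
        circ = _two_source_circuit(weight=0.0, delay=0.0)
        hist = np.random.default_rng(0).standard_normal((9, 100))
        assert afferent_drive(circ, hist, 0.05, SOURCE_INDEX["STN"], 5e-4) == 0.0

    def test_single_connection_half_activation(self):
        # presynaptic source at v = 0 -> S(v) = 0.5; weight 2 -> drive 1
        circ = _two_source_circuit(weight=2.0, delay=0.02)
        hist = np.zeros((9, 100))
        drive = afferent_drive(circ, hist, 0.05, SOURCE_INDEX["STN"], 5e-4)
        assert drive == pytest.approx(1.0)

    def test_uses_delayed_value_not_current(self):
        circ = _two_source_circuit(weight=2.0, delay=0.02, slope=1.0)
        dt = 5e-4
        hist = np.zeros((9, 100))
        src = POP_INDEX["M2.DP"]
        hist[src, -1] = 5.0  # current value must not be read
        d0 = afferent_drive(circ, hist, 0.05, SOURCE_INDEX["STN"], dt)
        assert d0 == pytest.approx(1.0)
        hist[src, -1 - 40] = 5.0  # exactly 20 ms back at dt = 0.5 ms
        d1 = afferent_drive(circ, hist, 0.05, SOURCE_INDEX["STN"], dt)
        assert d1 == pytest.approx(2.0 * sigmoid_rate(5.0, 1.0))

    def test_delay_shift_identity(self):
        # shifting the source history by k steps and the delay by the same
        # amount leaves the drive unchanged
        dt = 5e-4
        rng = np.random.default_rng(1)
        base = rng.standard_normal(200)
        for k in (10, 25):
            circ_a = _two_source_circuit(weight=1.5, delay=0.02)
            circ_b = _two_source_circuit(weight=1.5, delay=0.02 + k * dt)
            hist_a = np.zeros((9, 200))
            hist_b = np.zeros((9, 200))
            src = POP_INDEX["M2.DP"]
            hist_a[src] = base
            hist_b[src] = np.r_[base[k:], np.zeros(k)]  # advance by k steps
            da = afferent_drive(circ_a, hist_a, 0.1, SOURCE_INDEX["STN"], dt)
            db = afferent_drive(circ_b, hist_b, 0.1, SOURCE_INDEX["STN"], dt)
            assert da == pytest.approx(db)

    def test_short_history_raises(self):
        circ = _two_source_circuit(weight=1.0, delay=0.02)
        with pytest.raises(ValueError):
            afferent_drive(circ, np.zeros((9, 10)), 0.0, SOURCE_INDEX["STN"], 5e-4)

    def test_sign_flip_of_inhibitory_source(self):
        # flipping the source's sign flips its contribution exactly
        circ = _two_source_circuit(weight=3.0, delay=0.02)
        hist = np.zeros((9, 100))
        hist[POP_INDEX["M2.DP"], 10] = 1.0
        d_pos = afferent_drive(circ, hist, 0.05, SOURCE_INDEX["STN"], 5e-4)
        circ.inter_weights[SOURCE_INDEX["STN"], SOURCE_INDEX["M2"]] *= -1
        d_neg = sum(
            compile_circuit(circ).conn_weight
        )  # sanity: weight actually flipped
        assert d_neg == pytest.approx(-3.0)
        # bypass sign validation by negating on the compiled view
        comp = compile_circuit(_two_source_circuit(weight=3.0, delay=0.02))
        comp.conn_weight[:] *= -1
        d_flipped = afferent_drive(comp, hist, 0.05, SOURCE_INDEX["STN"], 5e-4)
        assert d_flipped == pytest.approx(-d_pos)


class TestNeuralMassStep:
    def test_origin_is_fixed_point(self, circuit):
        comp = compile_circuit(circuit)
        state = np.zeros(18)
        out = neural_mass_step(state, np.zeros(9), np.zeros(9), 5e-4, comp)
        assert np.all(out == 0.0)

    def test_constant_drive_converges_to_H_tau_p(self, circuit):
        # steady state of v'' = (H/tau) p - (2/tau) v' - v/tau^2 is H*tau*p
        comp = compile_circuit(circuit)
        p0 = np.full(9, 0.7)
        state = np.zeros(18)
        for _ in range(40000):
            state = neural_mass_step(state, p0, np.zeros(9), 5e-4, comp)
        expected = comp.gain * comp.tau * p0
        assert np.allclose(state[:9], expected, rtol=1e-3)

    def test_identical_seeds_identical_trajectories(self, circuit):
        cfg = SimulationConfig(duration=4.0, seed=11)
        a = simulate(circuit, cfg)
        b = simulate(circuit, cfg)
        assert np.array_equal(a.data, b.data)


class TestSimulate:
    def test_zero_weights_zero_noise_gives_zero_output(self):
        circ = _two_source_circuit(weight=0.0, delay=0.0)
        ts = simulate(circ, SimulationConfig(duration=4.0, seed=0))
        assert np.allclose(ts.data, 0.0)

    def test_divergence_names_population(self):
        circ = _two_source_circuit(weight=2.0, delay=0.02)
        circ.population("STN").gain = 1e9  # absurd gain pushes past the guard
        with pytest.raises(DivergenceError) as err:
            simulate(circ, SimulationConfig(duration=4.0, seed=0))
        assert err.value.population == "STN"

    def test_output_rate_and_labels(self, short_run):
        assert short_run.fs == 250.0
        assert short_run.labels == list(SOURCES)
        assert short_run.n_samples == 32 * 250
        assert np.all(np.isfinite(short_run.data))

    def test_default_circuit_beta_peak(self, long_run):
        # the tuned default produces a dominant STN peak inside 14-30 Hz
        x = long_run.channel("STN")
        x = x - x.mean()
        f, p = signal.welch(x, fs=long_run.fs, nperseg=250, noverlap=0,
                            window="hann")
        sel = (f >= 4) & (f <= 48)
        peak = f[sel][np.argmax(p[sel])]
        assert 14.0 <= peak <= 30.0

    def test_delay_buffer_shift(self, circuit):
        # lengthening the cortico-striatal delay shifts the M2->STR
        # cross-correlation peak by exactly that amount (same noise)
        extra = 0.04  # 10 output samples
        t, f = SOURCE_INDEX["STR"], SOURCE_INDEX["M2"]
        c2 = circuit.copy()
        c2.inter_delays[t, f] += extra
        cfg = SimulationConfig(duration=32.0, seed=5)
        a = simulate(circuit, cfg)
        b = simulate(c2, cfg)

        def peak_lag(ts):
            x = ts.channel("M2") - ts.channel("M2").mean()
            y = ts.channel("STR") - ts.channel("STR").mean()
            cc = signal.correlate(y, x, mode="full")
            lags = signal.correlation_lags(y.size, x.size)
            keep = (lags >= 0) & (lags < 125)
            return lags[keep][np.argmax(cc[keep])] / ts.fs

        shift = peak_lag(b) - peak_lag(a)
        assert shift == pytest.approx(extra, abs=1.0 / 250.0)

    def test_noise_variance_scaling(self):
        # with all couplings removed, output variance of a noise-driven
        # population scales linearly with noise_sd^2
        def var_at(sd, seeds=range(20)):
            circ = _two_source_circuit(weight=0.0, delay=0.0)
            for pid in ("M2.MP", "STR", "GPe", "STN", "GPi", "Thal"):
                circ.population(pid).noise_sd = sd
            v = [
                simulate(circ, SimulationConfig(duration=8.0, seed=s))
                .channel("STN").var()
                for s in seeds
            ]
            return np.mean(v)

        ratio = var_at(0.2) / var_at(0.1)
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_step_size_convergence(self, circuit):
        # halving dt changes the beta band power of a fixed-seed run by < 5%;
        # both runs see the same continuous-time noise realization (coarse
        # increments are the aggregated fine ones)
        fine_cfg = SimulationConfig(duration=64.0, seed=3, dt=2.5e-4)
        n_fine = int(round((fine_cfg.burn_in + fine_cfg.duration) / fine_cfg.dt))
        fine_noise = draw_noise(fine_cfg, n_fine)
        coarse_noise = (fine_noise[:, 0::2] + fine_noise[:, 1::2]) / np.sqrt(2.0)

        def beta_power(dt, noise):
            cfg = SimulationConfig(duration=64.0, seed=3, dt=dt)
            ts = simulate(circuit, cfg, noise=noise)
            x = ts.channel("STN")
            x = x - x.mean()
            f, p = signal.welch(x, fs=ts.fs, nperseg=250, noverlap=0,
                                window="hann")
            return p[(f >= 14) & (f <= 30)].sum()

        p1 = beta_power(5e-4, coarse_noise)
        p2 = beta_power(2.5e-4, fine_noise)
        assert abs(p2 - p1) / p1 < 0.05


class TestCircuitValidation:
    def test_default_circuit_valid_and_noise_placement(self, circuit):
        noisy = {p.id for p in circuit.populations if p.noise_sd > 0}
        assert noisy == {"M2.MP", "STR", "GPe", "STN", "GPi", "Thal"}

    def test_sparsity_violation_rejected(self, circuit):
        bad = circuit.copy()
        bad.inter_weights[SOURCE_INDEX["M2"], SOURCE_INDEX["STR"]] = -1.0
        bad.inter_delays[SOURCE_INDEX["M2"], SOURCE_INDEX["STR"]] = 0.01
        with pytest.raises(ValueError, match="sparsity"):
            bad.validate()

    def test_missing_delay_rejected(self, circuit):
        bad = circuit.copy()
        bad.inter_delays[SOURCE_INDEX["STN"], SOURCE_INDEX["M2"]] = 0.0
        with pytest.raises(ValueError, match="delay"):
            bad.validate()

    def test_inhibitory_sign_enforced(self, circuit):
        bad = circuit.copy()
        bad.inter_weights[SOURCE_INDEX["STN"], SOURCE_INDEX["GPe"]] = 2.0
        with pytest.raises(ValueError, match="inhibitory"):
            bad.validate()

    def test_yaml_round_trip(self, circuit, tmp_path):
        path = tmp_path / "circ.yaml"
        circuit.to_yaml(path)
        loaded = CircuitGraph.from_yaml(path)
        assert np.allclose(loaded.inter_weights, circuit.inter_weights)
        assert np.allclose(loaded.inter_delays, circuit.inter_delays)
        assert loaded.intra_cortical == circuit.intra_cortical
        a = simulate(circuit, SimulationConfig(duration=2.0, seed=1))
        b = simulate(loaded, SimulationConfig(duration=2.0, seed=1))
        assert np.array_equal(a.data, b.data)
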