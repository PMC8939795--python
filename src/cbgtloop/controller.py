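"""On-line phase-locked stimulation of the cortical superficial layer.

The controller senses the STN population voltage (at the 250 Hz observation
rate), tracks the phase of its lower-beta rhythm with a zero-crossing
estimator, and — when the band-limited envelope exceeds a baseline-derived
threshold and the refractory criterion is met — injects a sinusoidal voltage
``A sin(phi_sense + dphi_shift)`` into the superficial pyramidal population
for a fixed stimulation epoch.

Phase tracking emulates a hardware approach: every update interval the past
``history_window`` seconds of the sense signal are zero-padded, band-pass
filtered (zero-phase 4th-order Butterworth) and Hilbert-transformed; the
phase is extrapolated from the last positive zero-crossing assuming a fixed
frequency (18 Hz).  Envelope gating is read ``gating_delay`` before the
window end to avoid the unstable filter edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .bursts import BETA1, band_filter
from .circuit import POP_INDEX, CircuitGraph
from .simulate import SimulationConfig, TimeSeriesSet, draw_noise, simulate

TWO_PI = 2.0 * math.pi


@dataclass
class ControllerConfig:
    """Settings of the closed-loop phase-locked stimulator."""

    sense_source: str = "STN"
    stim_population: str = "M2.SP"
    band: tuple[float, float] = BETA1
    filter_order: int = 4
    update_interval: float = 0.025  # s between phase/gate updates
    history_window: float = 3.0     # s of sense data per update
    pad: float = 1.0                # s zero-padding each side before filtering
    gating_delay: float = 0.025     # s lag of the envelope read-out
    threshold_percentile: float = 75.0
    stim_duration: float = 0.5      # s of stimulation per delivery
    refractory: float = 0.5         # s without stimulation required after an epoch
    assumed_freq: float = 18.0      # Hz used for phase extrapolation
    amplitude_ratio: float = 0.25   # fraction of the intrinsic noise SD
    phase_shift: float = 0.0        # target phase shift, radians

    def __post_init__(self) -> None:
        if self.update_interval > self.stim_duration:
            raise ValueError("update_interval must not exceed stim_duration")
        if self.history_window < 3.0 / self.band[0]:
            raise ValueError("history_window must span several band periods")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")


@dataclass
class StimulationRecord:
    """Trace of controller decisions and the delivered waveform."""

    stim_onsets: np.ndarray        # s, relative to the retained data start
    waveform: np.ndarray           # injected voltage at the output rate
    fs: float
    phase_estimates: np.ndarray    # per update: estimated sense phase (rad)
    update_times: np.ndarray       # per update: s
    gate_log: np.ndarray           # per update: [envelope crit, refractory crit]
    config: ControllerConfig | None = None

    def __post_init__(self) -> None:
        if self.stim_onsets.size > 1:
            gaps = np.diff(self.stim_onsets)
            min_gap = self.config.stim_duration + self.config.refractory if self.config else 0.0
            if np.any(gaps < min_gap - 1e-9):
                raise ValueError("stimulation onsets violate the refractory contract")

    def stim_epochs(self, duration: float | None = None) -> list[tuple[float, float]]:
        d = duration if duration is not None else (
            self.config.stim_duration if self.config else 0.5
        )
        return [(float(t), float(t) + d) for t in self.stim_onsets]


class PhaseUnavailable(Exception):
    """No positive zero-crossing found in the analysis window."""


def estimate_phase_zero_crossing(
    window: np.ndarray,
    fs: float,
    cfg: ControllerConfig,
):
    """Zero-crossing phase/envelope estimate from one sense window.

    Returns ``(t_crossing, gated_envelope)`` where ``t_crossing`` is the time
    (in seconds, relative to the window start) of the most recent positive
    zero-crossing of the band-passed signal occurring before
    ``window end - gating_delay``; the phase at a later time ``t`` is
    ``2 pi assumed_freq (t - t_crossing)``.  The envelope is read
    ``gating_delay`` before the window end.  Raises :class:`PhaseUnavailable`
    when the window holds no positive crossing.
    """
    window = np.asarray(window, dtype=float)
    npad = int(round(cfg.pad * fs))
    padded = np.concatenate([np.zeros(npad), window - window.mean(), np.zeros(npad)])
    xf = band_filter(padded, fs, cfg.band, cfg.filter_order)
    env = np.abs(signal.hilbert(xf))
    xf = xf[npad: npad + window.size]
    env = env[npad: npad + window.size]
    delay_n = int(round(cfg.gating_delay * fs))
    gate_idx = max(window.size - 1 - delay_n, 0)
    gated_envelope = float(env[gate_idx])
    # most recent positive-going zero-crossing at or before the gate index
    seg = xf[: gate_idx + 1]
    pos = np.flatnonzero((seg[:-1] <= 0) & (seg[1:] > 0))
    if pos.size == 0:
        raise PhaseUnavailable("no positive zero-crossing in window")
    i = int(pos[-1])
    frac = -seg[i] / (seg[i + 1] - seg[i])  # linear interpolation of the crossing
    t_crossing = (i + frac) / fs
    return t_crossing, gated_envelope


def phase_at(t: float, t_crossing: float, assumed_freq: float) -> float:
    """Extrapolated sine phase at ``t`` (rad, wrapped), phi = 0 at the crossing."""
    return float(np.angle(np.exp(1j * TWO_PI * assumed_freq * (t - t_crossing))))


def gate(
    envelope: float,
    threshold: float,
    last_onset: float,
    now: float,
    cfg: ControllerConfig,
) -> bool:
    """Stimulation criteria: envelope strictly above threshold (A) and no
    stimulation within the previous stim epoch + refractory period (B)."""
    crit_a = envelope > threshold
    crit_b = (now - last_onset) >= cfg.stim_duration + cfg.refractory
    return bool(crit_a and crit_b)


def stim_waveform(
    phase_now: np.ndarray | float, amplitude: float, cfg: ControllerConfig, crit: bool
):
    """``A sin(phi + dphi_shift)`` when the gating criteria hold, else zero."""
    if not crit:
        return np.zeros_like(np.asarray(phase_now, dtype=float))
    return amplitude * np.sin(np.asarray(phase_now, dtype=float) + cfg.phase_shift)


class PhaseLockedController:
    """Closed-loop controller driven by :func:`cbgtloop.simulate.simulate`.

    ``mode`` selects the control policy: ``"phaselock"`` (zero-crossing
    tracked phase), ``"fixed"`` (gated 18 Hz sinusoid with a fixed random
    starting phase, no phase tracking) or ``"playback"`` (replay of a
    recorded waveform, ignoring the gating).
    """

    def __init__(
        self,
        cfg: ControllerConfig,
        threshold: float,
        mode: str = "phaselock",
        playback: np.ndarray | None = None,
        fixed_phase: float = 0.0,
    ):
        if mode not in ("phaselock", "fixed", "playback"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "playback" and playback is None:
            raise ValueError("playback mode needs a recorded waveform")
        self.cfg = cfg
        self.threshold = threshold
        self.mode = mode
        self.playback = playback
        self.fixed_phase = fixed_phase
        self._reset()

    def _reset(self) -> None:
        self.amplitude = 0.0
        self.last_onset = -np.inf
        self.stim_until = -np.inf
        self.t_crossing = None
        self.onsets: list[float] = []
        self.phase_log: list[float] = []
        self.time_log: list[float] = []
        self.gate_log: list[tuple[bool, bool]] = []
        self.fs_sense = None
        self._burn = 0.0

    # -- hooks used by simulate() ------------------------------------------
    def bind(self, circuit: CircuitGraph, config: SimulationConfig) -> None:
        self._reset()
        self.stim_pop_index = POP_INDEX[self.cfg.stim_population]
        from .circuit import SOURCE_INDEX, SOURCE_OUTPUT_POP

        # sense the observed population voltage of the sensing source
        sense_pop = circuit.observation_map[self.cfg.sense_source]
        self.sense_pop_index = POP_INDEX[sense_pop]
        self.amplitude = self.cfg.amplitude_ratio * circuit.noise_reference_sd(
            self.cfg.stim_population
        )
        self.fs_sense = config.out_rate
        self._burn = config.burn_in

    def update(self, sense: np.ndarray, t_now: float, n_steps: int, dt: float) -> np.ndarray:
        """Waveform for the next ``n_steps`` integration steps from ``t_now``."""
        cfg = self.cfg
        t_chunk = t_now + np.arange(n_steps) * dt
        out = np.zeros(n_steps)

        if self.mode == "playback":
            # replay waveform indexed from the end of burn-in
            idx = np.round((t_chunk - self._burn) / dt).astype(int)
            ok = (idx >= 0) & (idx < self.playback.size)
            out[ok] = self.playback[idx[ok]]
            return out

        win_n = int(round(cfg.history_window * self.fs_sense))
        if sense.size < win_n:
            return out
        window = sense[-win_n:]
        try:
            t_cross_rel, env = estimate_phase_zero_crossing(window, self.fs_sense, cfg)
            phase_ok = True
            # absolute time of the crossing
            window_start = t_now - (win_n - 1) / self.fs_sense
            self.t_crossing = window_start + t_cross_rel
        except PhaseUnavailable:
            env = 0.0
            phase_ok = False

        in_stim = t_now < self.stim_until
        crit_a = env > self.threshold
        crit_b = (t_now - self.last_onset) >= cfg.stim_duration + cfg.refractory
        if not in_stim and phase_ok and crit_a and crit_b:
            self.last_onset = t_now
            self.stim_until = t_now + cfg.stim_duration
            self.onsets.append(t_now)
            in_stim = True
        self.gate_log.append((crit_a, crit_b))
        self.time_log.append(t_now)

        if phase_ok and self.t_crossing is not None:
            self.phase_log.append(phase_at(t_now, self.t_crossing, cfg.assumed_freq))
        else:
            self.phase_log.append(np.nan)

        if in_stim:
            active = t_chunk < self.stim_until
            if self.mode == "phaselock" and phase_ok:
                phases = TWO_PI * cfg.assumed_freq * (t_chunk - self.t_crossing)
                out[active] = self.amplitude * np.sin(
                    phases[active] + cfg.phase_shift
                )
            elif self.mode == "fixed":
                out[active] = self.amplitude * np.sin(
                    TWO_PI * cfg.assumed_freq * t_chunk[active] + self.fixed_phase
                )
        return out

    def finalize(self, uex: np.ndarray, dt: float, config: SimulationConfig) -> StimulationRecord:
        """Build the StimulationRecord, times relative to the retained data."""
        dec = config.decimation
        wave = uex[int(round(config.burn_in / dt))::dec]
        onsets = np.array([t - config.burn_in for t in self.onsets])
        keep = onsets >= 0
        return StimulationRecord(
            stim_onsets=onsets[keep],
            waveform=wave,
            fs=config.out_rate,
            phase_estimates=np.array(self.phase_log),
            update_times=np.array(self.time_log) - config.burn_in,
            gate_log=np.array(self.gate_log, dtype=bool),
            config=replace(self.cfg),
        )


def baseline_threshold(
    circuit: CircuitGraph, sim_cfg: SimulationConfig, cfg: ControllerConfig
) -> tuple[float, TimeSeriesSet]:
    """Envelope threshold from the unstimulated baseline run.

    The baseline run uses the identical noise realization (same seed); the
    threshold is the ``threshold_percentile`` of the band-limited Hilbert
    envelope of the sensed signal.
    """
    from .bursts import bandpass_hilbert, percentile_threshold

    ts = simulate(circuit, sim_cfg)
    x = ts.channel(cfg.sense_source)
    env = bandpass_hilbert(x - x.mean(), ts.fs, cfg.band, cfg.filter_order).amp
    return percentile_threshold(env, cfg.threshold_percentile), ts


def sweep_phases(n_bins: int = 12) -> np.ndarray:
    """Target phase shifts from -pi to +pi in ``n_bins`` 30-degree bins."""
    return -np.pi + TWO_PI * np.arange(n_bins) / n_bins


def run_phase_sweep(
    circuit: CircuitGraph,
    sim_cfg: SimulationConfig,
    cfg: ControllerConfig,
    n_bins: int = 12,
):
    """Stimulated runs at ``n_bins`` equally spaced target phases.

    All conditions and the baseline share one noise realization
    (``sim_cfg.seed``); the gate threshold comes from the baseline envelope.
    Returns ``(baseline TimeSeriesSet, {phase: (TimeSeriesSet, record)})``.
    """
    threshold, baseline = baseline_threshold(circuit, sim_cfg, cfg)
    out = {}
    for phi in sweep_phases(n_bins):
        c = replace(cfg, phase_shift=float(phi))
        ctl = PhaseLockedController(c, threshold)
        ts, rec = simulate(circuit, sim_cfg, controller=ctl)
        out[float(phi)] = (ts, rec)
    return baseline, out


def control_policy_run(
    circuit: CircuitGraph,
    sim_cfg: SimulationConfig,
    cfg: ControllerConfig,
    mode: str,
    playback_record: StimulationRecord | None = None,
    threshold: float | None = None,
    fixed_phase: float = 0.0,
):
    """Non-phase-specific control policies: gated fixed-frequency or playback.

    ``fixed`` injects an 18 Hz sinusoid under the usual gating but without
    phase tracking; ``playback`` replays a recorded waveform into a run with
    a different noise realization (records longer than the run are truncated
    with a warning).
    """
    import warnings

    if mode == "playback":
        if playback_record is None:
            raise ValueError("playback requires a source StimulationRecord")
        n_out = int(round(sim_cfg.duration * sim_cfg.out_rate))
        wave = playback_record.waveform
        if wave.size > n_out:
            warnings.warn("playback record longer than the run; truncating",
                          stacklevel=2)
            wave = wave[:n_out]
        # upsample to integration rate by zero-order hold
        dec = sim_cfg.decimation
        wave_int = np.repeat(wave, dec)
        ctl = PhaseLockedController(cfg, threshold=np.inf, mode="playback",
                                    playback=wave_int)
    elif mode == "fixed":
        if threshold is None:
            threshold, _ = baseline_threshold(circuit, sim_cfg, cfg)
        ctl = PhaseLockedController(cfg, threshold, mode="fixed",
                                    fixed_phase=fixed_phase)
    else:
        raise ValueError("mode must be 'fixed' or 'playback'")
    return simulate(circuit, sim_cfg, controller=ctl)


def _epoch_band_power(x: np.ndarray, fs: float, epochs, band) -> float:
    """Mean band power over a set of (start, stop) second epochs.

    Epochs truncated by the end of the signal are dropped so every retained
    epoch has the full stimulation duration (duration matching).
    """
    segs = []
    for a, b in epochs:
        i, j = int(round(a * fs)), int(round(b * fs))
        if j <= x.size:
            segs.append(x[i:j])
    if not segs:
        return np.nan
    n = min(len(s) for s in segs)
    arr = np.array([s[:n] - s[:n].mean() for s in segs])
    freqs, p = signal.periodogram(arr, fs=fs, window="hann", detrend=False, axis=-1)
    pm = p.mean(axis=0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(pm[sel], freqs[sel]))


def _epoch_coherence(x, y, fs, epochs, band) -> float:
    segs = [(int(round(a * fs)), int(round(b * fs))) for a, b in epochs]
    segs = [(i, j) for i, j in segs if j <= x.size]
    if not segs:
        return np.nan
    n = min(j - i for i, j in segs)
    xs = np.array([x[i:i + n] for i, _ in segs])
    ys = np.array([y[i:i + n] for i, _ in segs])
    w = np.hanning(n)
    X = np.fft.rfft((xs - xs.mean(1, keepdims=True)) * w, axis=1)
    Y = np.fft.rfft((ys - ys.mean(1, keepdims=True)) * w, axis=1)
    Sxx = np.mean(np.abs(X) ** 2, 0)
    Syy = np.mean(np.abs(Y) ** 2, 0)
    Sxy = np.mean(X * np.conj(Y), 0)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(Sxx * Syy > 0, np.abs(Sxy) ** 2 / (Sxx * Syy), 0.0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(c[sel].mean())


def amplitude_response_curves(
    sweep: dict,
    baseline: TimeSeriesSet,
    signals: tuple[str, ...] = ("STN", "M2"),
    bands: dict | None = None,
    coherence_pair: tuple[str, str] = ("M2", "STN"),
):
    """Band-limited amplitude response curves across the phase sweep.

    For every target phase, the percentage change of band power inside
    stimulation epochs relative to the identical (duration-matched) epochs
    of the unstimulated baseline, plus the change in mean M2<->STN coherence.
    Phases with no delivered stimulation yield missing (NaN) entries.
    Returns a tidy DataFrame (phase_deg, signal, band, pct_change).
    """
    import pandas as pd

    from .bursts import BETA1, BETA2

    bands = bands or {"beta1": BETA1, "beta2": BETA2}
    rows = []
    fs = baseline.fs
    for phi, (ts, rec) in sorted(sweep.items()):
        epochs = rec.stim_epochs()
        deg = math.degrees(phi)
        for sig in signals:
            for bname, band in bands.items():
                if not epochs:
                    rows.append({"phase_deg": deg, "signal": sig, "band": bname,
                                 "pct_change": np.nan, "n_epochs": 0})
                    continue
                p_stim = _epoch_band_power(ts.channel(sig), fs, epochs, band)
                p_base = _epoch_band_power(baseline.channel(sig), fs, epochs, band)
                rows.append({
                    "phase_deg": deg, "signal": sig, "band": bname,
                    "pct_change": 100.0 * (p_stim - p_base) / p_base,
                    "n_epochs": len(epochs),
                })
        for bname, band in bands.items():
            if not epochs:
                rows.append({"phase_deg": deg, "signal": "coh:" + ":".join(coherence_pair),
                             "band": bname, "pct_change": np.nan, "n_epochs": 0})
                continue
            c_stim = _epoch_coherence(ts.channel(coherence_pair[0]),
                                      ts.channel(coherence_pair[1]), fs, epochs, band)
            c_base = _epoch_coherence(baseline.channel(coherence_pair[0]),
                                      baseline.channel(coherence_pair[1]), fs, epochs, band)
            rows.append({"phase_deg": deg,
                         "signal": "coh:" + ":".join(coherence_pair),
                         "band": bname,
                         "pct_change": 100.0 * (c_stim - c_base) / c_base,
                         "n_epochs": len(epochs)})
    return pd.DataFrame(rows)
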