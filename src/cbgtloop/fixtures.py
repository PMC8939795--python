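"""Synthetic fixtures with known ground truth for the analysis operations.

Every generator returns both the signal and the quantity the corresponding
analysis should recover: bursty band-limited oscillations carry their true
burst intervals; coupled pairs carry their analytic phase-locking value and
phase lag; ABC targets are features simulated from the model at known
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, special

from .bursts import BETA1, BurstSet
from .simulate import TimeSeriesSet


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture."""

    kind: str = "bursty_oscillation"  # bursty_oscillation | coupled_pair | abc_target
    fs: float = 250.0
    duration: float = 30.0
    band: tuple[float, float] = BETA1
    burst_rate: float = 0.5     # bursts per second (expected)
    burst_len: float = 0.3      # s per burst
    snr_db: float = 10.0        # burst carrier power over background noise power
    plv_target: float = 0.8
    phase_lag: float = 0.0      # radians, channel 1 leads channel 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 2 * self.band[1]:
            raise ValueError("fs must be at least twice the band's upper edge")
        if not 0.0 <= self.plv_target <= 1.0:
            raise ValueError("plv_target must lie in [0, 1]")


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude background noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_bursty_oscillation(spec: FixtureSpec) -> tuple[TimeSeriesSet, BurstSet]:
    """Amplitude-modulated in-band sinusoid plus 1/f noise, with true bursts.

    The carrier sits at the band centre; the envelope is a small baseline
    plus boxcar-smoothed burst epochs at random non-overlapping onsets; the
    carrier-to-noise ratio during bursts is ``snr_db``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    f0 = 0.5 * (spec.band[0] + spec.band[1])
    carrier = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))

    n_bursts = rng.poisson(spec.burst_rate * spec.duration)
    burst_n = int(round(spec.burst_len * spec.fs))
    gap = int(round(0.2 * spec.fs))
    env = np.zeros(n)
    intervals = []
    occupied = np.zeros(n, dtype=bool)
    for _ in range(n_bursts):
        for _attempt in range(50):
            s = int(rng.integers(0, max(n - burst_n, 1)))
            lo = max(0, s - gap)
            hi = min(n, s + burst_n + gap)
            if not occupied[lo:hi].any():
                env[s: s + burst_n] = 1.0
                occupied[lo:hi] = True
                intervals.append((s / spec.fs, (s + burst_n) / spec.fs))
                break
    smooth_n = max(int(round(0.02 * spec.fs)), 1)
    env = np.convolve(env, np.ones(smooth_n) / smooth_n, mode="same")
    baseline = 0.1
    amp = baseline + env
    noise_sd = 1.0 / np.sqrt(2.0) * 10 ** (-spec.snr_db / 20.0)
    x = amp * carrier + noise_sd * _pink_noise(n, rng)
    intervals.sort()
    ts = TimeSeriesSet(x[None, :], ["synthetic"], spec.fs,
                       {"kind": "bursty_oscillation", "seed": spec.seed,
                        "f0": f0, "baseline": baseline})
    truth = BurstSet(intervals, spec.band, threshold_value=baseline,
                     min_duration=0.0, fs=spec.fs)
    return ts, truth


def kappa_for_plv(plv_target: float) -> float:
    """Von Mises concentration with mean resultant I1(k)/I0(k) = plv."""
    if plv_target <= 0:
        return 0.0
    if plv_target >= 1:
        return np.inf

    def f(k):
        # exponentially scaled Bessel ratio avoids overflow at large kappa
        return special.i1e(k) / special.i0e(k) - plv_target

    return float(optimize.brentq(f, 1e-6, 1e4))


def gen_coupled_pair(spec: FixtureSpec) -> tuple[TimeSeriesSet, float]:
    """Two in-band oscillations with a known PLV and phase lag.

    Channel 1 carries a slowly frequency-wandering in-band phase process;
    channel 2 repeats it shifted by ``phase_lag`` plus von Mises jitter
    whose concentration solves ``I1(k)/I0(k) = plv_target``.  Returns the
    signals and the analytic PLV.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    f0 = 0.5 * (spec.band[0] + spec.band[1])
    # smooth frequency jitter keeps the pair inside the band
    fj = rng.standard_normal(n)
    fj = signal.sosfiltfilt(signal.butter(2, 1.0, fs=spec.fs, output="sos"), fj)
    fj = 0.1 * (spec.band[1] - spec.band[0]) * fj / max(fj.std(), 1e-12)
    phase1 = 2 * np.pi * np.cumsum(f0 + fj) / spec.fs
    kappa = kappa_for_plv(spec.plv_target)
    if np.isinf(kappa):
        jitter = np.zeros(n)
    else:
        # temporally correlated jitter with an exact von Mises marginal
        # (Gaussian copula): white jitter would be removed by the band-pass
        # used in measurement, inflating the observed PLV above its target
        from scipy import stats as sps

        u = rng.standard_normal(n)
        sos_lp = signal.butter(2, 2.0, fs=spec.fs, output="sos")
        u = signal.sosfiltfilt(sos_lp, u)
        u /= max(u.std(), 1e-12)
        grades = np.clip(sps.norm.cdf(u), 1e-6, 1 - 1e-6)
        if kappa == 0.0:
            jitter = (grades - 0.5) * 2 * np.pi
        else:
            # von Mises quantile function tabulated once and interpolated
            qgrid = np.linspace(1e-6, 1 - 1e-6, 1024)
            jitter = np.interp(grades, qgrid, sps.vonmises.ppf(qgrid, kappa))
    phase2 = phase1 - spec.phase_lag + jitter
    data = np.vstack([np.sin(phase1), np.sin(phase2)])
    ts = TimeSeriesSet(data, ["A", "B"], spec.fs,
                       {"kind": "coupled_pair", "seed": spec.seed,
                        "plv_target": spec.plv_target,
                        "phase_lag": spec.phase_lag})
    return ts, spec.plv_target


def gen_abc_target(
    circuit,
    duration: float = 30.0,
    seed: int = 0,
    channels=("M2", "STN"),
    pairs=(("M2", "STN"),),
):
    """Feature target simulated from the model at known parameters."""
    from .abcfit import simulate_features

    return simulate_features(circuit, duration, seed, channels=channels, pairs=pairs)


def generate(spec: FixtureSpec, circuit=None):
    """Dispatch on ``spec.kind``."""
    if spec.kind == "bursty_oscillation":
        return gen_bursty_oscillation(spec)
    if spec.kind == "coupled_pair":
        return gen_coupled_pair(spec)
    if spec.kind == "abc_target":
        if circuit is None:
            from .circuit import default_circuit

            circuit = default_circuit()
        return gen_abc_target(circuit, duration=spec.duration, seed=spec.seed)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
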