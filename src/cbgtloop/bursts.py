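"""Beta-burst detection and within-burst phase-synchronization analytics.

Bursts are defined on the Hilbert envelope of the band-passed (zero-phase,
4th-order Butterworth) sensing signal: intervals where the envelope exceeds a
percentile threshold (default 75th, linear-interpolated) for longer than one
cycle of the band's lower cut-off.  "Within-burst" always means network-wide
samples inside the STN burst windows.  Phase-locking value (PLV) is the
magnitude of the mean unit phasor of a phase difference; relative phase
stability (RPS) is the mean absolute rate of change of the wrapped phase
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

BETA1 = (14.0, 21.0)
BETA2 = (21.0, 30.0)
BETA = (14.0, 30.0)


@dataclass
class AnalyticSignal:
    """Envelope and wrapped phase of a band-limited signal."""

    amp: np.ndarray
    phase: np.ndarray
    fs: float
    band: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        if np.any(self.amp < 0):
            raise ValueError("envelope must be non-negative")


@dataclass
class BurstSet:
    """Suprathreshold intervals on a band-limited envelope."""

    intervals: list[tuple[float, float]]  # (onset, offset) seconds
    band: tuple[float, float]
    threshold_value: float
    min_duration: float
    fs: float

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for on, off in self.intervals:
            if off <= on:
                raise ValueError("burst offsets must exceed onsets")
            if off - on < self.min_duration - 0.5 / self.fs:
                raise ValueError("burst shorter than the minimum duration")
            if on < prev_off:
                raise ValueError("bursts must be disjoint and sorted")
            prev_off = off

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def durations(self) -> np.ndarray:
        return np.array([off - on for on, off in self.intervals])

    def sample_mask(self, n_samples: int) -> np.ndarray:
        """Boolean in-burst mask over a signal of ``n_samples`` at ``fs``."""
        mask = np.zeros(n_samples, dtype=bool)
        for on, off in self.intervals:
            mask[int(round(on * self.fs)): int(round(off * self.fs))] = True
        return mask


@dataclass
class PLVMatrix:
    values: np.ndarray  # (n, n), symmetric, diagonal 1
    band: tuple[float, float]
    labels: list[str]
    n_bursts: int
    significance: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("PLV values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


def band_filter(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4):
    """Zero-phase 4th-order Butterworth band-pass."""
    if band[1] >= fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2} Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def bandpass_hilbert(
    x: np.ndarray, fs: float, band: tuple[float, float], order: int = 4, source: str = ""
) -> AnalyticSignal:
    """Envelope and phase from the analytic signal of the band-passed input."""
    xf = band_filter(np.asarray(x, dtype=float), fs, band, order)
    h = signal.hilbert(xf)
    return AnalyticSignal(np.abs(h), np.angle(h), fs, tuple(band), source)


def percentile_threshold(env: np.ndarray, pct: float) -> float:
    """Linear-interpolation percentile of the full envelope."""
    return float(np.percentile(env, pct, method="linear"))


def detect_bursts(
    env: AnalyticSignal | np.ndarray,
    pct: float = 75.0,
    band: tuple[float, float] | None = None,
    fs: float | None = None,
    threshold: float | None = None,
) -> BurstSet:
    """Suprathreshold envelope runs lasting at least one cycle of ``band[0]``.

    ``threshold`` overrides the percentile rule (used when thresholds come
    from a different, e.g. baseline, recording).
    """
    if isinstance(env, AnalyticSignal):
        fs = env.fs
        band = band or env.band
        env = env.amp
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    if band is None or fs is None:
        raise ValueError("band and fs are required with a bare envelope")
    if threshold is None:
        threshold = percentile_threshold(env, pct)
    min_dur = 1.0 / band[0]
    above = env > threshold
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[~above[edges]] + 1
    stops = edges[above[edges]] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, env.size]
    intervals = [
        (s / fs, e / fs)
        for s, e in zip(starts, stops)
        if (e - s) / fs >= min_dur
    ]
    return BurstSet(intervals, tuple(band), float(threshold), min_dur, fs)


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value of two phase traces."""
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def phase_difference(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    """Wrap-safe phase difference ``angle(e^{i a} e^{-i b})``."""
    return np.angle(np.exp(1j * (np.asarray(phase_a) - np.asarray(phase_b))))


def analytic_phases(ts, band: tuple[float, float]) -> np.ndarray:
    """(n_channels, n_samples) phase array for all channels of a TimeSeriesSet."""
    return np.array(
        [bandpass_hilbert(ch, ts.fs, band).phase for ch in ts.data]
    )


def within_burst_plv(ts, bursts: BurstSet, band: tuple[float, float]) -> PLVMatrix:
    """PLV over concatenated within-burst samples for every channel pair."""
    if len(bursts) == 0:
        raise ValueError("no bursts supplied")
    mask = bursts.sample_mask(ts.n_samples)
    if not mask.any():
        raise ValueError("burst windows contain no samples")
    ph = analytic_phases(ts, band)[:, mask]
    n = ph.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = plv(ph[i], ph[j])
    return PLVMatrix(out, tuple(band), list(ts.labels), len(bursts))


def _free_starts(bursts: BurstSet, n_samples: int) -> dict[int, np.ndarray]:
    """Valid out-of-burst start indices per distinct segment length."""
    free = (~bursts.sample_mask(n_samples)).astype(int)
    cum = np.concatenate([[0], np.cumsum(free)])
    lengths = np.unique(np.round(bursts.durations * bursts.fs).astype(int))
    table = {}
    for L in lengths:
        # a start s is valid when all L samples from s are outside bursts
        ok = np.flatnonzero(cum[L:] - cum[:-L] == L)
        if ok.size == 0:
            raise ValueError(
                f"insufficient out-of-burst data: need a free run of {L} samples "
                f"({L / bursts.fs:.3f} s), none available"
            )
        table[int(L)] = ok
    return table


def _draw_out_of_burst_segments(
    bursts: BurstSet,
    n_samples: int,
    rng: np.random.Generator,
    starts_table: dict[int, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Random out-of-burst index segments matched in number and duration."""
    if starts_table is None:
        starts_table = _free_starts(bursts, n_samples)
    lengths = np.round(bursts.durations * bursts.fs).astype(int)
    segments = []
    for L in lengths:
        s = int(rng.choice(starts_table[int(L)]))
        segments.append(np.arange(s, s + L))
    return segments


def plv_surrogate_null(
    ts,
    bursts: BurstSet,
    band: tuple[float, float],
    n_perm: int = 500,
    pct: float = 95.0,
    seed: int | np.random.Generator = 0,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pair surrogate significance threshold for within-burst PLV.

    Each permutation draws out-of-burst segments matched in number and
    duration to the real bursts, shuffles the segment correspondence between
    the two channels of every pair (segment k of A against segment K of B,
    truncated to the shorter), and recomputes the PLV.  The returned matrix
    holds the ``pct`` percentile of the resulting null distribution — of the
    PLV itself, or of ``|PLV - reference|`` when a reference matrix (e.g. the
    fitted model's PLV) is given.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(bursts) == 0:
        raise ValueError("no bursts supplied")
    phasors = np.exp(1j * analytic_phases(ts, band))
    n_ch = phasors.shape[0]
    starts = _free_starts(bursts, ts.n_samples)
    null = np.zeros((n_perm, n_ch, n_ch))
    for p in range(n_perm):
        segs = _draw_out_of_burst_segments(bursts, ts.n_samples, rng, starts)
        order = rng.permutation(len(segs))
        # concatenated index pairs, truncated pairwise to the shorter segment
        idx_a, idx_b = [], []
        for k, K in enumerate(order):
            L = min(segs[k].size, segs[K].size)
            idx_a.append(segs[k][:L])
            idx_b.append(segs[K][:L])
        ia = np.concatenate(idx_a)
        ib = np.concatenate(idx_b)
        za = phasors[:, ia]
        zb = phasors[:, ib]
        mat = np.abs(za @ zb.conj().T) / ia.size
        iu = np.triu_indices(n_ch, k=1)
        mat[(iu[1], iu[0])] = mat[iu]  # symmetrise (A/B roles mirrored)
        np.fill_diagonal(mat, 1.0)
        null[p] = mat if reference is None else np.abs(mat - reference)
    return np.percentile(null, pct, axis=0)


def time_resolved_phase(
    ts,
    pair: tuple[str, str],
    bursts: BurstSet,
    band: tuple[float, float],
    win: float = 0.2,
    overlap: float = 0.95,
    span: float | None = None,
):
    """Onset-locked phase-difference and PLV traces across bursts.

    Sliding windows of ``win`` seconds with ``overlap`` fractional overlap
    are anchored at each burst onset (t = 0).  Per window the circular mean
    of the instantaneous phase difference is taken; traces report the
    across-burst circular mean (centred so the t = 0 value maps to 0°),
    circular SEM, and the across-burst PLV of the window means.  Bursts
    shorter than one window are excluded (count reported).
    """
    from .circstats import circular_mean_sd

    fs = ts.fs
    hop = win * (1.0 - overlap)  # may be a non-integer number of samples;
    # window starts are rounded individually so the mean hop is exact
    hop_f = hop * fs
    win_n = int(round(win * fs))
    pa = bandpass_hilbert(ts.channel(pair[0]), fs, band).phase
    pb = bandpass_hilbert(ts.channel(pair[1]), fs, band).phase
    dphi = phase_difference(pa, pb)
    if span is None:
        span = float(np.max(bursts.durations))
    n_win = max(1, int(np.floor((span * fs - win_n) / hop_f)) + 1)
    times = np.arange(n_win) * hop + win / 2

    rows, excluded = [], 0
    for on, off in bursts.intervals:
        s = int(round(on * fs))
        if (off - on) < win:
            excluded += 1
            continue
        row = np.full(n_win, np.nan + 1j * np.nan, dtype=complex)
        for w in range(n_win):
            a = s + int(round(w * hop_f))
            b = a + win_n
            if b > int(round(off * fs)) or b > dphi.size:
                break
            row[w] = np.mean(np.exp(1j * dphi[a:b]))
        rows.append(row)
    if not rows:
        raise ValueError("no burst longer than one analysis window")
    R = np.array(rows)
    valid = ~np.isnan(R.real)
    n_eff = valid.sum(axis=0)
    mean_z = np.where(n_eff > 0, np.nansum(R / np.abs(R), axis=0), np.nan)
    mean_phase = np.angle(mean_z)
    plv_trace = np.abs(mean_z) / np.maximum(n_eff, 1)
    # circular SEM per window
    sem = np.full(n_win, np.nan)
    for w in range(n_win):
        ang = np.angle(R[valid[:, w], w])
        if ang.size > 1:
            _, sd = circular_mean_sd(ang)
            sem[w] = sd / np.sqrt(ang.size)
    centred = phase_difference(mean_phase, np.full(n_win, mean_phase[0]))
    return {
        "times": times,
        "phase": centred,
        "phase_raw": mean_phase,
        "sem": sem,
        "plv": plv_trace,
        "n_bursts": n_eff,
        "excluded": excluded,
    }


def relative_phase_stability(
    phase_diff: np.ndarray,
    fs: float,
    window: tuple[float, float] = (0.0, 0.5),
) -> float:
    """Mean |d/dt| of the wrapped phase difference over ``window`` (rad/s)."""
    phase_diff = np.asarray(phase_diff, dtype=float)
    a = int(round(window[0] * fs))
    b = min(int(round(window[1] * fs)) + 1, phase_diff.size)
    if b - a < 2:
        raise ValueError("phase trace does not cover the analysis window")
    seg = phase_diff[a:b]
    dstep = np.angle(np.exp(1j * np.diff(seg)))  # circular finite difference
    return float(np.mean(np.abs(dstep)) * fs)


def burst_power_rps_correlation(
    ts,
    bursts: BurstSet,
    band: tuple[float, float],
    pair: tuple[str, str] = ("M2", "STN"),
    sense: str = "STN",
    rps_window: tuple[float, float] = (0.0, 0.5),
):
    """Per-burst (power, RPS) pairs with Pearson r and two-sided p.

    Burst power is the mean squared band-limited envelope of the sensing
    channel inside the burst; RPS is computed on the burst-onset-anchored
    phase difference of ``pair``.
    """
    if len(bursts) < 3:
        raise ValueError("at least 3 bursts required")
    fs = ts.fs
    env = bandpass_hilbert(ts.channel(sense), fs, band).amp
    pa = bandpass_hilbert(ts.channel(pair[0]), fs, band).phase
    pb = bandpass_hilbert(ts.channel(pair[1]), fs, band).phase
    dphi = phase_difference(pa, pb)
    powers, rps_vals = [], []
    for on, off in bursts.intervals:
        s, e = int(round(on * fs)), int(round(off * fs))
        stop = min(e, s + int(round(rps_window[1] * fs)) + 1, dphi.size)
        if stop - s < 2:
            continue
        powers.append(float(np.mean(env[s:e] ** 2)))
        seg = dphi[s:stop]
        d = np.angle(np.exp(1j * np.diff(seg)))
        rps_vals.append(float(np.mean(np.abs(d)) * fs))
    powers, rps_vals = np.array(powers), np.array(rps_vals)
    if powers.std() == 0 or rps_vals.std() == 0:
        return {"power": powers, "rps": rps_vals, "r": np.nan, "p": np.nan,
                "slope": np.nan, "intercept": np.nan}
    r, p = stats.pearsonr(powers, rps_vals)
    slope, intercept = np.polyfit(powers, rps_vals, 1)
    return {"power": powers, "rps": rps_vals, "r": float(r), "p": float(p),
            "slope": float(slope), "intercept": float(intercept)}
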