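"""Summary spectral features: Welch spectra, 1/f flattening, coherence,
non-parametric directionality (NPD) and sum-of-Gaussians smoothing.

These are the statistics the fitting routine matches between simulated and
target data: per-source power spectra (Welch periodograms over 1-s Hann
epochs), pairwise magnitude-squared coherence, and a lag-domain decomposition
of coherency into forward / reverse / zero-lag directional components after
MMSE prewhitening.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal


@dataclass
class FeatureSet:
    """Spectral summary features of a multichannel recording on one grid."""

    freqs: np.ndarray
    psd: dict[str, np.ndarray]
    coh: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    npd: dict[tuple[str, str], dict[str, np.ndarray]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.freqs.size
        for k, v in self.psd.items():
            if v.size != n:
                raise ValueError(f"psd[{k}] not on the common frequency grid")
        for k, v in self.coh.items():
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-6):
                raise ValueError(f"coherence[{k}] outside [0, 1]")

    def feature_vector(self, freq_range: tuple[float, float] = (4.0, 48.0)) -> np.ndarray:
        """Concatenated psd + NPD features restricted to ``freq_range``."""
        sel = (self.freqs >= freq_range[0]) & (self.freqs <= freq_range[1])
        parts = [self.psd[k][sel] for k in sorted(self.psd)]
        for k in sorted(self.npd):
            d = self.npd[k]
            parts.extend([d["forward"][sel], d["reverse"][sel]])
        return np.concatenate(parts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch, v in self.psd.items():
            rows.append(pd.DataFrame({"freq": self.freqs, "channel": ch,
                                      "feature": "psd", "value": v}))
        for (a, b), v in self.coh.items():
            rows.append(pd.DataFrame({"freq": self.freqs, "channel": f"{a}:{b}",
                                      "feature": "coh", "value": v}))
        for (a, b), d in self.npd.items():
            for comp in ("forward", "reverse", "zero_lag"):
                rows.append(pd.DataFrame({"freq": self.freqs,
                                          "channel": f"{a}:{b}",
                                          "feature": f"npd_{comp}",
                                          "value": d[comp]}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureSet":
        df = pd.read_csv(path)
        freqs = np.sort(df["freq"].unique())
        psd, coh, npd = {}, {}, {}
        for (ch, feat), g in df.groupby(["channel", "feature"]):
            v = g.sort_values("freq")["value"].to_numpy()
            if feat == "psd":
                psd[ch] = v
            elif feat == "coh":
                coh[tuple(ch.split(":"))] = v
            elif feat.startswith("npd_"):
                npd.setdefault(tuple(ch.split(":")), {})[feat[4:]] = v
        return cls(freqs, psd, coh, npd)


def preprocess(ts, artifact_z: float = 6.0, band=(4.0, 100.0)) -> np.ndarray:
    """Standardised 1-s epochs: mean-subtract, zero-lag FIR band-pass,
    z-score, epoch, reject epochs containing |z| > ``artifact_z``.

    Returns an ``(n_epochs, fs)`` array.
    """
    fs = int(round(ts.fs))
    data = np.atleast_2d(ts.data if hasattr(ts, "data") else ts)
    n = data.shape[1]
    if n < fs:
        raise ValueError("need at least one second of data")
    numtaps = min(2 * fs + 1, (n - 1) // 3 * 2 - 1)
    numtaps = max(numtaps | 1, 31)  # odd, with a sane floor
    high = min(band[1], fs / 2 * 0.99)
    fir = signal.firwin(numtaps, [band[0], high], pass_zero=False, fs=fs)
    epochs_all = []
    for x in data:
        x = x - x.mean()
        x = signal.filtfilt(fir, 1.0, x)
        x = (x - x.mean()) / x.std() if x.std() > 0 else x
        n_ep = x.size // fs
        ep = x[: n_ep * fs].reshape(n_ep, fs)
        keep = np.max(np.abs(ep), axis=1) <= artifact_z
        epochs_all.append(ep[keep])
    return epochs_all[0] if data.shape[0] == 1 else epochs_all


def welch_psd(epochs: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean Hann-windowed periodogram over non-overlapping 1-s epochs.

    ``epochs`` is ``(n_epochs, n_per_epoch)``; resolution is ``fs / n``
    (1 Hz for 1-s epochs).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need at least one epoch")
    freqs, p = signal.periodogram(
        epochs, fs=fs, window="hann", detrend=False, axis=-1
    )
    return freqs, p.mean(axis=0)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Integrated power over a frequency band (trapezoidal)."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))


def flatten_1f(
    freqs: np.ndarray, psd: np.ndarray, fit_range: tuple[float, float] = (4.0, 48.0)
) -> np.ndarray:
    """Remove the 1/f background by log-log linear regression.

    A line is fit to ``log10(psd)`` vs ``log10(f)`` over ``fit_range`` and
    subtracted across the whole grid; the result is the residual log10 power
    (peaks survive, background near zero).  The zero-frequency bin, where the
    log is undefined, is returned as zero residual.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    if np.any(psd[sel] <= 0):
        raise ValueError("psd must be strictly positive over the fit range")
    slope, intercept = np.polyfit(np.log10(freqs[sel]), np.log10(psd[sel]), 1)
    out = np.zeros_like(psd)
    pos = (freqs > 0) & (psd > 0)
    out[pos] = np.log10(psd[pos]) - (intercept + slope * np.log10(freqs[pos]))
    return out


def coherence(
    x: np.ndarray, y: np.ndarray, fs: float, nperseg: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence with 1-s non-overlapping Hann segments."""
    nperseg = nperseg or int(round(fs))
    f, c = signal.coherence(x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=0)
    return f, c


def npd(
    x: np.ndarray, y: np.ndarray, fs: float, segment_len: int | None = None
) -> dict[str, np.ndarray]:
    """Non-parametric directionality: forward / reverse / zero-lag spectra.

    The coherency ``gamma(f) = Sxy / sqrt(Sxx Syy)`` (an MMSE prewhitened
    cross-spectrum) is transformed to the lag domain; its energy is split
    over positive lags (x leads y: forward), negative lags (reverse) and zero
    lag, and each part is transformed back to give three non-negative
    directional spectra.  Their frequency-integrated sum reconstructs the
    integrated squared coherency (Parseval).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    segment_len = segment_len or int(round(fs))
    if x.size < 2 * segment_len:
        raise ValueError("signals too short for the requested segment length")
    n_seg = x.size // segment_len
    xs = x[: n_seg * segment_len].reshape(n_seg, segment_len)
    ys = y[: n_seg * segment_len].reshape(n_seg, segment_len)
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    w = np.hanning(segment_len)
    X = np.fft.fft(xs * w, axis=1)
    Y = np.fft.fft(ys * w, axis=1)
    Sxx = np.mean(np.abs(X) ** 2, axis=0)
    Syy = np.mean(np.abs(Y) ** 2, axis=0)
    Sxy = np.mean(X * np.conj(Y), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(Sxx * Syy > 0, Sxy / np.sqrt(Sxx * Syy), 0.0)
    rho = np.fft.ifft(gamma)  # lag-domain correlation of the prewhitened pair
    n = segment_len
    lags_pos = np.zeros(n, dtype=complex)  # x -> y
    lags_neg = np.zeros(n, dtype=complex)
    lags_zero = np.zeros(n, dtype=complex)
    # lower ifft indices hold y-leading lags, the upper half x-leading ones;
    # for even n the ambiguous +-n/2 lag is split evenly so that swapping the
    # pair maps forward <-> reverse exactly
    half = n // 2
    lags_zero[0] = rho[0]
    lags_neg[1:half] = rho[1:half]
    lags_pos[half + 1:] = rho[half + 1:]
    if n % 2 == 0:
        lags_neg[half] = 0.5 * rho[half]
        lags_pos[half] = 0.5 * rho[half]
    fwd = np.abs(np.fft.fft(lags_pos)) ** 2
    rev = np.abs(np.fft.fft(lags_neg)) ** 2
    zer = np.abs(np.fft.fft(lags_zero)) ** 2
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / fs))
    keep = slice(0, n // 2 + 1)  # one-sided grid including the Nyquist bin
    return {
        "freqs": freqs[keep],
        "forward": fwd[keep],
        "reverse": rev[keep],
        "zero_lag": zer[keep],
        "coherence_sq": np.abs(gamma[keep]) ** 2,
    }


def _gauss_sum(f, *params):
    out = np.zeros_like(f, dtype=float)
    for a, mu, sd in zip(params[::3], params[1::3], params[2::3]):
        out += a * np.exp(-0.5 * ((f - mu) / sd) ** 2)
    return out


def gaussfit_smooth(
    freqs: np.ndarray, curve: np.ndarray, max_order: int = 3
) -> tuple[np.ndarray, int, np.ndarray]:
    """Smooth a feature curve with the adjusted-R2-best sum of <= 3 Gaussians.

    Returns ``(smoothed, order, params)`` with ``params`` the flat
    ``(amplitude, centre, width)`` triples of the selected model.  If a fit
    fails to converge the next-lower order is used (with a warning).
    """
    freqs = np.asarray(freqs, float)
    curve = np.asarray(curve, float)
    span = freqs[-1] - freqs[0]
    best = None
    n = curve.size
    amp0 = max(curve.max() - curve.min(), 1e-12)
    for order in range(1, max_order + 1):
        # seed centres at distinct residual peaks of the previous fit
        resid = curve - (best[0] if best else 0.0)
        pk, _ = signal.find_peaks(resid, distance=max(n // (2 * max_order), 1))
        pk = pk[np.argsort(resid[pk])[::-1]]
        centres = list(freqs[pk[:order]])
        while len(centres) < order:
            centres.append(float(freqs[np.argmax(resid)]))
        p0, lo, hi = [], [], []
        for c in centres:
            p0 += [amp0, float(c), span / 8]
            lo += [-2 * amp0, freqs[0], span / max(n, 2)]
            hi += [2 * amp0, freqs[-1], span]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                params, _ = optimize.curve_fit(
                    _gauss_sum, freqs, curve, p0=p0, bounds=(lo, hi), maxfev=20000
                )
        except (RuntimeError, ValueError):
            warnings.warn(
                f"{order}-Gaussian fit failed to converge; keeping order "
                f"{best[1] if best else 0}",
                stacklevel=2,
            )
            break
        fit = _gauss_sum(freqs, *params)
        ss_res = np.sum((curve - fit) ** 2)
        ss_tot = np.sum((curve - curve.mean()) ** 2)
        k = 3 * order
        if ss_tot == 0:
            adj = 1.0
        else:
            r2 = 1 - ss_res / ss_tot
            adj = 1 - (1 - r2) * (n - 1) / max(n - k - 1, 1)
        # lower order wins ties: once a fit is numerically perfect, adjusted
        # R2 differences between orders are float noise
        if best is None or adj > best[2] + 1e-9:
            best = (fit, order, adj, params)
    if best is None:
        raise RuntimeError("no Gaussian fit converged")
    return best[0], best[1], best[3]


def compute_features(
    ts,
    channels: list[str] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    artifact_z: float = 6.0,
    flatten: bool = True,
    fit_range: tuple[float, float] = (4.0, 48.0),
) -> FeatureSet:
    """Full per-channel PSD + per-pair NPD FeatureSet of a recording.

    Channels are preprocessed (band-pass, z-score, artifact rejection is
    applied per channel for spectra; NPD uses the continuous standardised
    signals).  With ``flatten`` the 1/f background is removed from every PSD
    — applied symmetrically to simulated and target data when used as a
    fitting distance.
    """
    channels = channels or list(ts.labels)
    fs = ts.fs
    psd = {}
    freqs = None
    for ch in channels:
        sub = _single(ts, ch)
        epochs = preprocess(sub, artifact_z=artifact_z)
        freqs, p = welch_psd(epochs, fs)
        psd[ch] = flatten_1f(freqs, p, fit_range) if flatten else p
    zts = ts.zscored()
    coh_d, npd_d = {}, {}
    if pairs is None:
        pairs = list(itertools.combinations(channels, 2))
    for a, b in pairs:
        f, c = coherence(zts.channel(a), zts.channel(b), fs)
        coh_d[(a, b)] = c
        d = npd(zts.channel(a), zts.channel(b), fs)
        npd_d[(a, b)] = {k: d[k] for k in ("forward", "reverse", "zero_lag")}
    return FeatureSet(freqs, psd, coh_d, npd_d,
                      meta={"flattened": flatten, "fs": fs})


def _single(ts, ch: str):
    from .simulate import TimeSeriesSet

    return TimeSeriesSet(ts.channel(ch)[None, :], [ch], ts.fs, dict(ts.meta))
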