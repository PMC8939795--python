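"""Discrete network states, spectral fingerprints and pooled-R2 recovery.

Network states scale the weight of one STN input pathway: the hyperdirect
(HD, cortex -> STN) or pallido-subthalamic (PS, GPe -> STN) projection.
*Down* states fix the weight at 30% of the fitted value; *Up* states are
calibrated by bisection until STN broadband beta (14-30 Hz) power doubles
relative to the unmodulated circuit.

A *spectral fingerprint* summarises a recording by (a) the concatenated
per-source Welch spectra computed within STN beta bursts, truncated to
2-48 Hz and normalised to unit variance per source, and (b) the matrices of
pairwise within-burst phase-locking values in the lower and upper beta
bands.  Fingerprints are compared with a pooled R2: one minus the mean,
over feature blocks, of the normalised squared error — 1 is a perfect
match and negative values are worse than a flat line through the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import signal

from .bursts import BETA, BETA1, BETA2, BurstSet, bandpass_hilbert, detect_bursts, within_burst_plv
from .circuit import HD_EDGE, PS_EDGE, CircuitGraph, SOURCES
from .simulate import SimulationConfig, TimeSeriesSet, simulate

PATHWAY_EDGES = {"HD": HD_EDGE, "PS": PS_EDGE}


@dataclass
class NetworkState:
    """A named rescaling of one STN input pathway."""

    name: str
    pathway: str  # "HD" | "PS"
    multiplier: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAY_EDGES:
            raise ValueError("pathway must be 'HD' or 'PS'")
        if not self.multiplier > 0:
            raise ValueError("multiplier must be > 0")

    def apply(self, circuit: CircuitGraph) -> CircuitGraph:
        return circuit.scaled(PATHWAY_EDGES[self.pathway], self.multiplier)


def stn_beta_power(
    ts: TimeSeriesSet, band: tuple[float, float] = BETA, channel: str = "STN"
) -> float:
    """Welch band power of the (mean-subtracted) STN signal."""
    x = ts.channel(channel)
    x = x - x.mean()
    f, p = signal.welch(x, fs=ts.fs, nperseg=int(round(ts.fs)), noverlap=0,
                        window="hann")
    sel = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[sel], f[sel]))


def _mean_power_ratio(
    circuit: CircuitGraph,
    edge: tuple[int, int],
    multiplier: float,
    baseline_powers: dict[int, float],
    seeds,
    duration: float,
) -> float:
    ratios = []
    for s in seeds:
        ts = simulate(circuit.scaled(edge, multiplier),
                      SimulationConfig(duration=duration, seed=s))
        ratios.append(stn_beta_power(ts) / baseline_powers[s])
    return float(np.mean(ratios))


def define_state(
    circuit: CircuitGraph,
    pathway: str,
    mode: str,
    target_ratio: float = 2.0,
    tol: float = 0.05,
    seeds=(0, 1, 2),
    eval_duration: float = 60.0,
    down_multiplier: float = 0.30,
    bracket: tuple[float, float] = (1.0, 6.0),
    max_iter: int = 20,
) -> NetworkState:
    """Define an Up- or Down-regulated state of the HD or PS pathway.

    ``down`` fixes the multiplier at ``down_multiplier``.  ``up`` bisects the
    multiplier until the seed-averaged STN broadband beta power reaches
    ``target_ratio`` times the unmodulated power within ``tol`` (fractional),
    each evaluation simulating ``eval_duration`` seconds per seed.
    """
    if mode == "down":
        return NetworkState(f"{pathway}-Down", pathway, down_multiplier,
                            {"provenance": "fixed"})
    if mode != "up":
        raise ValueError("mode must be 'up' or 'down'")
    edge = PATHWAY_EDGES[pathway]
    base = {
        s: stn_beta_power(simulate(circuit, SimulationConfig(duration=eval_duration, seed=s)))
        for s in seeds
    }
    lo, hi = bracket
    r_lo = _mean_power_ratio(circuit, edge, lo, base, seeds, eval_duration)
    r_hi = _mean_power_ratio(circuit, edge, hi, base, seeds, eval_duration)
    if not (min(r_lo, r_hi) <= target_ratio <= max(r_lo, r_hi)):
        raise RuntimeError(
            f"calibration cannot bracket the target ratio {target_ratio}: "
            f"achieved {r_lo:.2f} at x{lo} and {r_hi:.2f} at x{hi}"
        )
    evals = [(lo, r_lo), (hi, r_hi)]
    mid, r_mid = lo, r_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = _mean_power_ratio(circuit, edge, mid, base, seeds, eval_duration)
        evals.append((mid, r_mid))
        if abs(r_mid - target_ratio) <= tol * target_ratio:
            break
        # power ratio increases with multiplier on both pathways
        if (r_mid < target_ratio) == (r_hi > r_lo):
            lo = mid
        else:
            hi = mid
    return NetworkState(
        f"{pathway}-Up",
        pathway,
        float(mid),
        {
            "provenance": "calibrated",
            "target_ratio": target_ratio,
            "achieved_ratio": float(r_mid),
            "tolerance": tol,
            "seeds": list(seeds),
            "eval_duration": eval_duration,
            "n_evals": len(evals),
        },
    )


def default_states(circuit: CircuitGraph, **kwargs) -> list[NetworkState]:
    """The four canonical states: HD-Up/Down and PS-Up/Down."""
    return [
        define_state(circuit, "HD", "up", **kwargs),
        define_state(circuit, "HD", "down"),
        define_state(circuit, "PS", "up", **kwargs),
        define_state(circuit, "PS", "down"),
    ]


# -- fingerprints -----------------------------------------------------------

FULL_MASK = {"spectra_sources": list(SOURCES), "plv_sources": list(SOURCES)}
#: preset for comparisons against empirical features: hidden nodes (GPi,
#: thalamus) are excluded from the spectra and PLV is restricted to the
#: basal ganglia
EMPIRICAL_MASK = {
    "spectra_sources": ["M2", "STR", "GPe", "STN"],
    "plv_sources": ["STR", "GPe", "STN", "GPi"],
}


@dataclass
class Fingerprint:
    """Concatenated unit-variance within-burst spectra + PLV matrices."""

    spectra: np.ndarray          # concatenated per-source blocks
    spectra_freqs: np.ndarray
    spectra_sources: list[str]
    plv: dict                    # band name -> PLVMatrix values (n, n)
    plv_sources: list[str]
    masks: dict = field(default_factory=lambda: dict(FULL_MASK))

    @property
    def block_len(self) -> int:
        return self.spectra_freqs.size

    def spectra_block(self, source: str) -> np.ndarray:
        i = self.spectra_sources.index(source)
        return self.spectra[i * self.block_len: (i + 1) * self.block_len]

    def plv_vector(self) -> np.ndarray:
        """Upper-triangle PLV entries of both bands, concatenated."""
        parts = []
        for band in sorted(self.plv):
            v = self.plv[band]
            iu = np.triu_indices(v.shape[0], k=1)
            parts.append(v[iu])
        return np.concatenate(parts)


def _within_burst_epochs(x: np.ndarray, fs: float, windows, nperseg: int):
    """1-s (nperseg) epochs drawn from inside the given windows."""
    epochs = []
    for a, b in windows:
        i, j = int(round(a * fs)), int(round(b * fs))
        seg = x[i:j]
        for k in range(seg.size // nperseg):
            epochs.append(seg[k * nperseg: (k + 1) * nperseg])
    if not epochs:
        # bursts shorter than the segment: concatenate and re-segment
        cat = np.concatenate(
            [x[int(round(a * fs)): int(round(b * fs))] for a, b in windows]
        )
        if cat.size < nperseg:
            raise ValueError("not enough within-burst data for one Welch segment")
        n = cat.size // nperseg
        epochs = [cat[k * nperseg: (k + 1) * nperseg] for k in range(n)]
    return np.array(epochs)


def build_fingerprint(
    ts: TimeSeriesSet,
    bursts: BurstSet | None = None,
    windows=None,
    masks: dict | None = None,
    freq_range: tuple[float, float] = (2.0, 48.0),
    bands: dict | None = None,
) -> Fingerprint:
    """Fingerprint of a recording from its within-burst activity.

    ``windows`` (explicit (start, stop) epochs, e.g. stimulation epochs)
    overrides the burst intervals.  Spectra are per-source mean Hann
    periodograms over 1-s segments of within-window data, truncated to
    ``freq_range`` and normalised to unit variance per source block.
    """
    masks = masks or dict(FULL_MASK)
    bands = bands or {"beta1": BETA1, "beta2": BETA2}
    if windows is None:
        if bursts is None or len(bursts) == 0:
            raise ValueError("need bursts or explicit windows")
        windows = bursts.intervals
    fs = ts.fs
    nperseg = int(round(fs))
    blocks = []
    freqs = None
    for src in masks["spectra_sources"]:
        x = ts.channel(src)
        x = x - x.mean()
        epochs = _within_burst_epochs(x, fs, windows, nperseg)
        f, p = signal.periodogram(epochs, fs=fs, window="hann", detrend=False, axis=-1)
        pm = p.mean(axis=0)
        sel = (f >= freq_range[0]) & (f <= freq_range[1])
        freqs = f[sel]
        block = pm[sel]
        sd = block.std()
        if sd == 0:
            raise ValueError(f"constant spectral block for source {src}")
        blocks.append(block / sd)
    # PLV on the mask's sources, over within-window samples
    sub = TimeSeriesSet(
        np.array([ts.channel(s) for s in masks["plv_sources"]]),
        list(masks["plv_sources"]), fs, dict(ts.meta),
    )
    wb = BurstSet(
        [(a, b) for a, b in windows], BETA1, threshold_value=np.nan,
        min_duration=0.0, fs=fs,
    )
    plv_d = {
        name: within_burst_plv(sub, wb, band).values for name, band in bands.items()
    }
    return Fingerprint(
        spectra=np.concatenate(blocks),
        spectra_freqs=freqs,
        spectra_sources=list(masks["spectra_sources"]),
        plv=plv_d,
        plv_sources=list(masks["plv_sources"]),
        masks=masks,
    )


def pooled_r2(
    fp_state: Fingerprint,
    fp_stim: Fingerprint,
    feature_set: str = "combined",
) -> float:
    """Pooled R2 between a state fingerprint and a stimulation fingerprint.

    ``feature_set`` selects the blocks: ``"spectra"``, ``"plv"`` or
    ``"combined"`` (both blocks, N_f = 2).  Per block the squared error
    between the state and stimulation features is normalised by the
    stimulation features' variance about their own mean; the pooled value is
    one minus the block average, in (-inf, 1].
    """
    blocks = []
    if feature_set in ("spectra", "combined"):
        if fp_state.spectra_sources != fp_stim.spectra_sources or \
                fp_state.spectra_freqs.size != fp_stim.spectra_freqs.size:
            raise ValueError("fingerprint spectra masks/grids do not match")
        blocks.append(("spectra", fp_state.spectra, fp_stim.spectra))
    if feature_set in ("plv", "combined"):
        if fp_state.plv_sources != fp_stim.plv_sources:
            raise ValueError("fingerprint PLV masks do not match")
        blocks.append(("plv", fp_state.plv_vector(), fp_stim.plv_vector()))
    if not blocks:
        raise ValueError("feature_set must be 'spectra', 'plv' or 'combined'")
    terms = []
    for name, y_state, y_stim in blocks:
        denom = np.sum((y_stim - y_stim.mean()) ** 2)
        if denom == 0:
            raise ValueError(f"constant feature block {name!r}: R2 undefined")
        terms.append(np.sum((y_state - y_stim) ** 2) / denom)
    return float(1.0 - np.mean(terms))


def state_fingerprints(
    circuit: CircuitGraph,
    states: list[NetworkState],
    sim_cfg: SimulationConfig,
    masks: dict | None = None,
    burst_band: tuple[float, float] = BETA1,
    burst_pct: float = 75.0,
) -> dict[str, Fingerprint]:
    """Simulate each state and fingerprint its spontaneous burst activity.

    Burst thresholds are computed per state (state-specific percentile of
    the state's own envelope).
    """
    out = {}
    for st in states:
        ts = simulate(st.apply(circuit), sim_cfg)
        x = ts.channel("STN")
        env = bandpass_hilbert(x - x.mean(), ts.fs, burst_band)
        bursts = detect_bursts(env, pct=burst_pct)
        out[st.name] = build_fingerprint(ts, bursts, masks=masks)
    return out


def recovery_sweep(
    sweep: dict,
    state_fps: dict[str, Fingerprint],
    masks: dict | None = None,
    feature_sets=("spectra", "plv", "combined"),
    realign: bool = False,
) -> pd.DataFrame:
    """Pooled R2 of every sweep phase against every state fingerprint.

    ``sweep`` maps target phase (rad) to ``(TimeSeriesSet, StimulationRecord)``
    as returned by :func:`cbgtloop.controller.run_phase_sweep`; only data
    within delivered stimulation epochs enter the stimulation fingerprints.
    Returns a tidy frame (phase_deg, state, feature_set, r2); with
    ``realign`` the phase axis is rotated so the phase of maximum recovery
    (per state and feature set) maps to 0 degrees (reported in
    ``phase_aligned_deg``).
    """
    rows = []
    for phi in sorted(sweep):
        ts, rec = sweep[phi]
        epochs = [(a, b) for a, b in rec.stim_epochs() if b * ts.fs <= ts.n_samples]
        if not epochs:
            raise ValueError(
                f"no stimulation epochs delivered at phase {math.degrees(phi):.0f} deg"
            )
        fp = build_fingerprint(ts, windows=epochs, masks=masks)
        for sname, sfp in state_fps.items():
            for fset in feature_sets:
                rows.append({
                    "phase_deg": math.degrees(phi),
                    "state": sname,
                    "feature_set": fset,
                    "r2": pooled_r2(sfp, fp, fset),
                })
    df = pd.DataFrame(rows)
    if realign:
        aligned = []
        for (sname, fset), g in df.groupby(["state", "feature_set"]):
            best = g.loc[g["r2"].idxmax(), "phase_deg"]
            a = (g["phase_deg"] - best + 180.0) % 360.0 - 180.0
            aligned.append(pd.Series(a, index=g.index))
        df["phase_aligned_deg"] = pd.concat(aligned).sort_index()
    return df


def strength_phase_heatmap(
    circuit: CircuitGraph,
    pathway: str,
    strengths,
    state_fps: dict[str, Fingerprint],
    sim_cfg: SimulationConfig,
    ctrl_cfg,
    masks: dict | None = None,
    feature_sets=("spectra", "plv", "combined"),
    n_bins: int = 12,
) -> pd.DataFrame:
    """Pooled-R2 grid over (pathway strength, stimulation phase).

    For each multiplier in ``strengths`` (typically 0.30 up to the calibrated
    Up-state maximum) the full phase sweep is run on the rescaled circuit and
    scored against each state fingerprint.  Returns a tidy frame with a
    ``best_state`` flag marking the arg-max state per (strength, phase,
    feature set) cell.
    """
    from .controller import run_phase_sweep

    edge = PATHWAY_EDGES[pathway]
    frames = []
    for s in strengths:
        circ = circuit.scaled(edge, float(s))
        _, sweep = run_phase_sweep(circ, sim_cfg, ctrl_cfg, n_bins=n_bins)
        df = recovery_sweep(sweep, state_fps, masks=masks, feature_sets=feature_sets)
        df.insert(0, "strength", float(s))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    idx = out.groupby(["strength", "phase_deg", "feature_set"])["r2"].idxmax()
    out["best_state"] = False
    out.loc[idx, "best_state"] = True
    return out
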