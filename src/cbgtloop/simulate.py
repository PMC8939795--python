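"""Stochastic delay integration of the CBGT circuit.

The nine coupled second-order stochastic delay-differential equations are
separated into 18 first-order equations and advanced with the Euler-Maruyama
scheme at a fine step (default 0.5 ms).  The deterministic drift of each
population is

    dv/dt = z
    dz/dt = (H / tau) * p(t) - (2 / tau) * z - v / tau**2

with synaptic drive ``p`` the delayed sigmoid sum over afferents plus any
injected stimulation, while the stochastic input enters ``z`` as
``(H / tau) * C * sd * sqrt(dt) * xi``.  After integration a burn-in period is
discarded and the observed population voltages are decimated with a zero-phase
anti-alias filter to the output rate (250 Hz).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit
from scipy import signal

from .circuit import (
    POPULATIONS,
    SOURCES,
    CircuitGraph,
    CompiledCircuit,
    compile_circuit,
)

GUARD_BOUND = 1e5  # |v| beyond which a trajectory is declared divergent


class DivergenceError(RuntimeError):
    """Raised when a population voltage exceeds the stability guard."""

    def __init__(self, population: str, t: float):
        self.population = population
        self.t = t
        super().__init__(
            f"trajectory diverged: population {population} exceeded |v| = "
            f"{GUARD_BOUND:g} at t = {t:.3f} s"
        )


def sigmoid_rate(v, slope):
    """Population activation ``S(v) = 1 / (1 + exp(-slope * v))``.

    Maps mean membrane voltage to a normalised output rate in (0, 1);
    strictly increasing in ``v``.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite voltage passed to sigmoid_rate")
    if not np.all(np.asarray(slope) > 0):
        raise ValueError("sigmoid slope must be > 0")
    from scipy.special import expit  # numerically stable logistic

    out = expit(np.asarray(slope) * v)
    return out if out.ndim else float(out)


def afferent_drive(
    circuit: CircuitGraph | CompiledCircuit,
    history: np.ndarray,
    t: float,
    target: int,
    dt: float,
) -> float:
    """Total delayed input to one source at time ``t``.

    ``history`` is a (9, n) population-voltage buffer sampled at ``dt`` whose
    last column corresponds to time ``t``; only strictly delayed values
    (``t - D``) are read.  ``target`` indexes :data:`~cbgtloop.circuit.SOURCES`.
    """
    comp = circuit if isinstance(circuit, CompiledCircuit) else compile_circuit(circuit)
    from .circuit import POP_INDEX, SOURCE_INPUT_POP

    target_pop = POP_INDEX[SOURCE_INPUT_POP[SOURCES[target]]]
    steps = comp.delay_steps(dt)
    if np.any(comp.conn_target == target_pop) and history.shape[1] <= steps[
        comp.conn_target == target_pop
    ].max():
        raise ValueError("history buffer shorter than the maximum afferent delay")
    total = 0.0
    last = history.shape[1] - 1
    for c in range(comp.conn_target.size):
        if comp.conn_target[c] != target_pop:
            continue
        vd = history[comp.conn_source[c], last - steps[c]]
        total += comp.conn_weight[c] * sigmoid_rate(vd, comp.slope[comp.conn_source[c]])
    return total


def neural_mass_step(
    state: np.ndarray,
    drives: np.ndarray,
    noise_draw: np.ndarray,
    dt: float,
    comp: CompiledCircuit,
) -> np.ndarray:
    """One Euler-Maruyama step of all nine (v, vdot) pairs.

    ``state`` is the 18-vector ``[v_0..v_8, z_0..z_8]``; ``drives`` the
    per-population synaptic input (stimulation already included); and
    ``noise_draw`` standard-normal values scaled internally by
    ``C * sd * sqrt(dt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    v, z = state[:9].copy(), state[9:].copy()
    g = comp.gain / comp.tau
    acc = g * drives - (2.0 / comp.tau) * z - v / comp.tau**2
    z = z + dt * acc + g * comp.noise_scale * comp.noise_sd * math.sqrt(dt) * noise_draw
    v = v + dt * z
    return np.concatenate([v, z])


@njit(cache=True)
def _kernel(
    vhist,
    z,
    tau,
    gain,
    slope,
    noise_amp,  # C * sd, per population
    conn_t,
    conn_s,
    conn_w,
    conn_d,  # delay in steps
    noise,  # (9, n_steps) standard normals, column k used for step k
    uex,  # (n_steps,) injected stimulation voltage
    stim_pop,  # population index receiving uex (or -1)
    start,  # first step index to advance (vhist[:, start] is current state)
    n_steps,
    dt,
    guard,
):
    sqdt = math.sqrt(dt)
    n_conn = conn_t.size
    drive = np.zeros(9)
    for k in range(start, start + n_steps):
        for p in range(9):
            drive[p] = 0.0
        for c in range(n_conn):
            vd = vhist[conn_s[c], k - conn_d[c]]
            drive[conn_t[c]] += conn_w[c] / (1.0 + math.exp(-slope[conn_s[c]] * vd))
        if stim_pop >= 0:
            drive[stim_pop] += uex[k]
        for p in range(9):
            g = gain[p] / tau[p]
            acc = g * drive[p] - (2.0 / tau[p]) * z[p] - vhist[p, k] / (tau[p] * tau[p])
            z[p] = z[p] + dt * acc + g * noise_amp[p] * sqdt * noise[p, k]
            vnew = vhist[p, k] + dt * z[p]
            if abs(vnew) > guard or not math.isfinite(vnew):
                return p, k
            vhist[p, k + 1] = vnew
    return -1, start + n_steps


@dataclass
class SimulationConfig:
    """Integration settings.

    ``dt`` is the Euler-Maruyama step (s), ``duration`` the retained length
    (s) after ``burn_in`` is discarded, and ``out_rate`` the decimated
    observation rate in Hz.
    """

    duration: float
    seed: int = 0
    dt: float = 5e-4
    burn_in: float = 2.0
    out_rate: float = 250.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        steps_per_out = 1.0 / (self.dt * self.out_rate)
        if abs(steps_per_out - round(steps_per_out)) > 1e-9:
            raise ValueError("out_rate must divide the integration rate 1/dt")

    @property
    def decimation(self) -> int:
        return int(round(1.0 / (self.dt * self.out_rate)))


@dataclass
class TimeSeriesSet:
    """Labelled multichannel signals at a common sampling rate."""

    data: np.ndarray  # (n_channels, n_samples)
    labels: list[str]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in time series")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def zscored(self) -> "TimeSeriesSet":
        d = self.data - self.data.mean(axis=1, keepdims=True)
        sd = d.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return TimeSeriesSet(d / sd, list(self.labels), self.fs, dict(self.meta))


def _config_hash(circuit: CircuitGraph, config: SimulationConfig) -> str:
    comp = compile_circuit(circuit)
    payload = json.dumps(
        {
            "tau": comp.tau.tolist(),
            "gain": comp.gain.tolist(),
            "slope": comp.slope.tolist(),
            "noise_sd": comp.noise_sd.tolist(),
            "noise_scale": comp.noise_scale.tolist(),
            "conn": [
                comp.conn_target.tolist(),
                comp.conn_source.tolist(),
                comp.conn_weight.tolist(),
                comp.conn_delay.tolist(),
            ],
            "dt": config.dt,
            "duration": config.duration,
            "burn_in": config.burn_in,
            "out_rate": config.out_rate,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def draw_noise(config: SimulationConfig, n_steps: int) -> np.ndarray:
    """The reproducible standard-normal noise realization for a run."""
    rng = np.random.default_rng(config.seed)
    return rng.standard_normal((9, n_steps))


def simulate(
    circuit: CircuitGraph,
    config: SimulationConfig,
    controller=None,
    noise: Optional[np.ndarray] = None,
):
    """Integrate the circuit and return observed signals at ``out_rate``.

    When a controller is supplied the identical noise realization (same
    ``config.seed``) is re-used so the stimulated run differs from its
    baseline only through the injected waveform; the function then returns a
    ``(TimeSeriesSet, StimulationRecord)`` pair instead of a bare
    :class:`TimeSeriesSet`.
    """
    comp = compile_circuit(circuit)
    dt = config.dt
    delay_steps = comp.delay_steps(dt)
    nonzero_delays = comp.conn_delay[comp.conn_delay > 0]
    if nonzero_delays.size and dt > nonzero_delays.min() / 2:
        raise ValueError("dt must be at most half the smallest nonzero delay")
    pad = int(delay_steps.max()) + 1 if delay_steps.size else 1
    n_steps = int(round((config.burn_in + config.duration) / dt))
    total = pad + n_steps

    vhist = np.zeros((9, total + 1))
    z = np.zeros(9)
    if noise is None:
        noise = draw_noise(config, n_steps)
    noise_full = np.zeros((9, total))
    noise_full[:, pad:] = noise[:, :n_steps]
    noise_amp = comp.noise_scale * comp.noise_sd

    uex = np.zeros(total)
    stim_pop = -1
    if controller is None:
        p, k = _kernel(
            vhist, z, comp.tau, comp.gain, comp.slope, noise_amp,
            comp.conn_target, comp.conn_source, comp.conn_weight, delay_steps,
            noise_full, uex, stim_pop, pad, n_steps, dt, GUARD_BOUND,
        )
        if p >= 0:
            raise DivergenceError(POPULATIONS[p], (k - pad) * dt - config.burn_in)
        record = None
    else:
        controller.bind(circuit, config)
        stim_pop = controller.stim_pop_index
        sense_pop = controller.sense_pop_index
        dec = config.decimation
        chunk = int(round(controller.cfg.update_interval / dt))
        k0 = pad
        while k0 < pad + n_steps:
            n_adv = min(chunk, pad + n_steps - k0)
            t_now = (k0 - pad) * dt  # time since integration start (incl. burn-in)
            sense = vhist[sense_pop, pad:k0 + 1:dec]
            uex[k0:k0 + n_adv] = controller.update(sense, t_now, n_adv, dt)
            p, k = _kernel(
                vhist, z, comp.tau, comp.gain, comp.slope, noise_amp,
                comp.conn_target, comp.conn_source, comp.conn_weight, delay_steps,
                noise_full, uex, stim_pop, k0, n_adv, dt, GUARD_BOUND,
            )
            if p >= 0:
                raise DivergenceError(POPULATIONS[p], (k - pad) * dt - config.burn_in)
            k0 += n_adv
        record = controller.finalize(uex[pad:], dt, config)

    burn_steps = int(round(config.burn_in / dt))
    raw = vhist[:, pad + burn_steps + 1: pad + n_steps + 1]
    obs = raw[comp.observed_pops]
    dec = config.decimation
    if dec > 1:
        data = signal.decimate(obs, dec, ftype="fir", zero_phase=True)
    else:
        data = obs
    ts = TimeSeriesSet(
        data=data,
        labels=list(SOURCES),
        fs=config.out_rate,
        meta={
            "seed": config.seed,
            "dt": dt,
            "burn_in": config.burn_in,
            "config_hash": _config_hash(circuit, config),
            "stimulated": controller is not None,
        },
    )
    if controller is not None:
        return ts, record
    return ts
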