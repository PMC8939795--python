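"""Sequential Approximate Bayesian Computation for circuit parameters.

Likelihood-free fitting of the stochastic circuit model to spectral feature
targets (PSD + directional connectivity): per generation, every particle is
simulated and scored by the mean squared error between its features and the
target's; the best fraction survives, and the next generation resamples
survivors with a Gaussian perturbation kernel (in log space for positive
parameters).  The per-generation acceptance threshold decreases until the
relative improvement falls below a gradient tolerance.  Model comparison
uses the approximate marginal probability: the fraction of posterior draws
whose simulated features land within a common distance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .circuit import SOURCE_INDEX, CircuitGraph
from .features import FeatureSet, compute_features
from .simulate import DivergenceError, SimulationConfig, simulate


@dataclass
class ParameterSpec:
    """One fitted parameter: its circuit target and prior.

    ``target`` addresses the circuit: ``("inter_weight", to_source,
    from_source)``, ``("gain", population)`` or ``("tau", population)``.
    ``family`` is ``"lognormal"`` (median ``loc``, log-sd ``scale``; the
    sign of ``loc`` is preserved for inhibitory weights) or ``"uniform"``
    (bounds ``loc``, ``scale``), the latter used for delays.
    """

    name: str
    target: tuple
    family: str = "lognormal"
    loc: float = 1.0
    scale: float = 0.5
    bounds: tuple[float, float] | None = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal":
            mag = np.abs(self.loc) * np.exp(self.scale * rng.standard_normal(n))
            draw = np.sign(self.loc) * mag
        elif self.family == "uniform":
            draw = rng.uniform(self.loc, self.scale, size=n)
        else:
            raise ValueError(f"unknown prior family {self.family!r}")
        return self._clip(draw)

    def _clip(self, v: np.ndarray) -> np.ndarray:
        if self.bounds is not None:
            v = np.clip(v, self.bounds[0], self.bounds[1])
        return v

    def perturb(self, values: np.ndarray, sd: float, rng: np.random.Generator):
        if self.family == "lognormal":
            out = values * np.exp(sd * rng.standard_normal(values.shape))
        else:
            out = values + sd * rng.standard_normal(values.shape)
        return self._clip(out)

    def prior_iqr(self) -> tuple[float, float]:
        """Central 50% interval of the prior (for recovery checks)."""
        if self.family == "lognormal":
            q = 0.6744897501960817  # Phi^-1(0.75)
            lo = np.abs(self.loc) * np.exp(-q * self.scale)
            hi = np.abs(self.loc) * np.exp(q * self.scale)
            if self.loc < 0:
                lo, hi = -hi, -lo
            return float(lo), float(hi)
        span = self.scale - self.loc
        return self.loc + 0.25 * span, self.loc + 0.75 * span

    def apply(self, circuit: CircuitGraph, value: float) -> None:
        kind = self.target[0]
        if kind == "inter_weight":
            t, f = SOURCE_INDEX[self.target[1]], SOURCE_INDEX[self.target[2]]
            circuit.inter_weights[t, f] = value
        elif kind == "gain":
            circuit.population(self.target[1]).gain = value
        elif kind == "tau":
            circuit.population(self.target[1]).tau = value
        elif kind == "inter_delay":
            t, f = SOURCE_INDEX[self.target[1]], SOURCE_INDEX[self.target[2]]
            circuit.inter_delays[t, f] = value
        else:
            raise ValueError(f"unknown parameter target {kind!r}")


@dataclass
class PriorSpec:
    """Collection of fitted parameters with their priors."""

    params: list[ParameterSpec]

    def __post_init__(self) -> None:
        for p in self.params:
            if p.family == "lognormal" and p.loc == 0:
                raise ValueError(f"{p.name}: lognormal prior needs a nonzero centre")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.column_stack([p.sample(rng, n) for p in self.params])

    def build(self, circuit: CircuitGraph, theta: np.ndarray) -> CircuitGraph:
        out = circuit.copy()
        for p, v in zip(self.params, theta):
            p.apply(out, float(v))
        return out


def weight_prior(
    circuit: CircuitGraph,
    edges: list[tuple[str, str]],
    scale: float = 0.5,
) -> PriorSpec:
    """Log-normal priors (log-sd ``scale``) centred on the circuit's current
    weights for the given (to, from) source pairs."""
    params = []
    for to, frm in edges:
        w = circuit.inter_weights[SOURCE_INDEX[to], SOURCE_INDEX[frm]]
        params.append(ParameterSpec(
            name=f"w:{to}<-{frm}",
            target=("inter_weight", to, frm),
            family="lognormal",
            loc=float(w),
            scale=scale,
        ))
    return PriorSpec(params)


@dataclass
class AbcPosterior:
    """Accepted particles and the fitting trajectory."""

    particles: np.ndarray      # (n_survivors, n_params) of the final generation
    distances: np.ndarray      # matching distances
    names: list[str]
    schedule: list[float]      # per-generation acceptance thresholds
    map_estimate: dict[str, float]
    converged: bool
    history: list[dict] = field(default_factory=list)

    def marginal(self, name: str) -> np.ndarray:
        return self.particles[:, self.names.index(name)]


def feature_distance(fs_sim: FeatureSet, fs_target: FeatureSet) -> float:
    """Mean squared error over the concatenated (psd + NPD) feature vector."""
    if fs_sim.freqs.size != fs_target.freqs.size or not np.allclose(
        fs_sim.freqs, fs_target.freqs
    ):
        raise ValueError("feature sets are not on a common frequency grid")
    a = fs_sim.feature_vector()
    b = fs_target.feature_vector()
    return float(np.mean((a - b) ** 2))


def _mode_1d(x: np.ndarray) -> float:
    """Mode of a 1-D sample via a Gaussian KDE on a grid."""
    from scipy.stats import gaussian_kde

    if np.ptp(x) < 1e-12 * max(1.0, np.abs(x).max()):
        return float(x.mean())
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 256)
    return float(grid[np.argmax(kde(grid))])


def simulate_features(
    circuit: CircuitGraph,
    duration: float,
    seed: int,
    channels=("M2", "STN"),
    pairs=(("M2", "STN"),),
    flatten: bool = True,
) -> FeatureSet:
    """Convenience simulator -> FeatureSet pipeline used by the ABC loop."""
    ts = simulate(circuit, SimulationConfig(duration=duration, seed=seed))
    return compute_features(ts, channels=list(channels), pairs=list(pairs),
                            flatten=flatten)


def sequential_abc(
    simulator: Callable[[CircuitGraph, int], FeatureSet],
    target: FeatureSet,
    circuit: CircuitGraph,
    prior: PriorSpec,
    n_particles: int = 200,
    max_gens: int = 10,
    grad_tol: float = 0.05,
    survivor_fraction: float = 0.3,
    seed: int = 0,
) -> AbcPosterior:
    """Sequential rejection ABC with adaptive threshold reduction.

    ``simulator(circuit, seed) -> FeatureSet`` must be deterministic given
    its seed.  Per generation all particles are simulated and scored with
    :func:`feature_distance`; the best ``survivor_fraction`` survive and seed
    the next generation via resampling plus a Gaussian perturbation at half
    the survivors' standard deviation.  Iteration stops at ``max_gens`` or
    when the threshold improves by less than ``grad_tol`` (relative).
    """
    rng = np.random.default_rng(seed)
    n_keep = max(2, int(round(survivor_fraction * n_particles)))
    theta = prior.sample(rng, n_particles)
    schedule: list[float] = []
    history: list[dict] = []
    converged = False
    survivors = theta[:n_keep]
    dist_keep = np.full(n_keep, np.inf)

    for gen in range(max_gens):
        dists = np.full(n_particles, np.inf)
        for i in range(n_particles):
            cand = prior.build(circuit, theta[i])
            sim_seed = int(rng.integers(0, 2**31 - 1))
            try:
                fs = simulator(cand, sim_seed)
                dists[i] = feature_distance(fs, target)
            except (DivergenceError, ValueError):
                dists[i] = np.inf
        if not np.any(np.isfinite(dists)):
            raise RuntimeError(
                f"all {n_particles} particles diverged in generation {gen}"
            )
        # survivors compete with the fresh candidates, keeping their recorded
        # scores: the acceptance threshold can then never increase
        pool_theta = np.vstack([theta, survivors]) if gen else theta
        pool_dist = np.concatenate([dists, dist_keep]) if gen else dists
        order = np.argsort(pool_dist)
        keep = order[:n_keep]
        survivors, dist_keep = pool_theta[keep], pool_dist[keep]
        eps = float(dist_keep.max())
        history.append({
            "generation": gen,
            "threshold": eps,
            "best": float(dist_keep.min()),
            "survivor_sd": survivors.std(axis=0).tolist(),
        })
        if schedule and schedule[-1] > 0:
            if (schedule[-1] - eps) / schedule[-1] < grad_tol:
                schedule.append(eps)
                converged = True
                break
        schedule.append(eps)
        # resample + perturb
        idx = rng.integers(0, n_keep, size=n_particles)
        theta = survivors[idx].copy()
        sds = 0.5 * survivors.std(axis=0)
        for j, p in enumerate(prior.params):
            if p.family == "lognormal":
                with np.errstate(divide="ignore"):
                    log_sd = 0.5 * np.std(np.log(np.abs(survivors[:, j])))
                sd_j = max(log_sd, 1e-3)
            else:
                sd_j = max(sds[j], 1e-6)
            theta[:, j] = p.perturb(theta[:, j], sd_j, rng)

    map_est = {
        name: _mode_1d(survivors[:, j]) for j, name in enumerate(prior.names)
    }
    return AbcPosterior(
        particles=survivors,
        distances=dist_keep,
        names=prior.names,
        schedule=schedule,
        map_estimate=map_est,
        converged=converged,
        history=history,
    )


def model_evidence(
    posterior: AbcPosterior,
    simulator: Callable[[CircuitGraph, int], FeatureSet],
    target: FeatureSet,
    circuit: CircuitGraph,
    prior: PriorSpec,
    eps_star: float,
    n_draws: int = 50,
    seed: int = 0,
) -> float:
    """Approximate marginal probability of a model.

    Draws ``n_draws`` parameter sets from the posterior particles, simulates
    each, and returns the fraction whose distance to the target is below the
    common threshold ``eps_star``.
    """
    import warnings

    if n_draws < 20:
        warnings.warn("n_draws < 20 gives a noisy evidence estimate", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, posterior.particles.shape[0], size=n_draws)
    hits = 0
    for i in idx:
        cand = prior.build(circuit, posterior.particles[i])
        try:
            fs = simulator(cand, int(rng.integers(0, 2**31 - 1)))
            if feature_distance(fs, target) < eps_star:
                hits += 1
        except (DivergenceError, ValueError):
            pass
    return hits / n_draws
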