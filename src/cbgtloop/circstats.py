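"""Circular descriptive statistics and hypothesis tests.

Implements the circular mean/SD, the Rayleigh test of uniformity, the
Watson-Williams test for equality of mean directions, and a cluster-based
permutation test for time-resolved traces (pointwise t statistic, cluster
mass = summed t, label-permutation null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def _resultant(angles: np.ndarray) -> tuple[float, float]:
    z = np.mean(np.exp(1j * np.asarray(angles, dtype=float)))
    return float(np.abs(z)), float(np.angle(z))


def circular_mean_sd(angles) -> tuple[float, float]:
    """Circular mean (arg of the resultant) and SD ``sqrt(-2 ln Rbar)``.

    Raises for an (effectively) zero resultant, where the mean direction is
    undefined.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("at least one angle required")
    rbar, mean = _resultant(angles)
    if rbar < 1e-12:
        raise ValueError("zero resultant vector: circular mean undefined")
    sd = float(np.sqrt(max(-2.0 * np.log(min(rbar, 1.0)), 0.0)))
    return mean, sd


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: ``z = n * Rbar**2``.

    The p-value uses the standard series approximation, accurate for the
    sample sizes used here.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    n = angles.size
    if n < 2:
        raise ValueError("need at least two angles")
    rbar, _ = _resultant(angles)
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(z), float(np.clip(p, 0.0, 1.0))


def _kappa_from_rbar(rbar: float) -> float:
    """Fisher's approximation of the von Mises concentration parameter."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(*groups) -> tuple[float, tuple[int, int], float]:
    """Watson-Williams test for a common mean direction across groups.

    Returns ``(F, (df1, df2), p)``.  Assumes von Mises samples with shared,
    reasonably high concentration; a warning is issued when the pooled
    resultant suggests the correction is unreliable.
    """
    groups = [np.atleast_1d(np.asarray(g, dtype=float)) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least two angles")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    N = int(ns.sum())
    Rs = np.array([g.size * _resultant(g)[0] for g in groups])  # resultant lengths
    all_angles = np.concatenate(groups)
    R_tot = N * _resultant(all_angles)[0]
    rw = Rs.sum() / N
    if rw < 0.45:
        warnings.warn(
            "low concentration (pooled Rbar < 0.45): the Watson-Williams "
            "approximation may be unreliable",
            stacklevel=2,
        )
    kappa = _kappa_from_rbar(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa)
    num = (N - k) * (Rs.sum() - R_tot)
    den = (k - 1) * (N - Rs.sum())
    if den <= 0:
        return float("inf"), (k - 1, N - k), 0.0
    F = correction * num / den
    F = max(F, 0.0)
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), (k - 1, N - k), p


@dataclass
class ClusterResult:
    """Clusters of contiguous significant samples from the permutation test."""

    clusters: list[dict]  # start, end (s), mass, p
    alpha: float
    n_perm: int
    min_duration: float = 0.02
    max_reported: int = 5
    t_critical: float = field(default=np.nan)

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p"] < self.alpha]


def _find_clusters(t: np.ndarray, tcrit: float, fs: float):
    """Contiguous same-sign runs of |t| > tcrit with their summed-t mass."""
    above = np.abs(t) > tcrit
    clusters = []
    i = 0
    n = t.size
    while i < n:
        if above[i]:
            sgn = np.sign(t[i])
            j = i
            while j < n and above[j] and np.sign(t[j]) == sgn:
                j += 1
            clusters.append((i, j, float(t[i:j].sum())))
            i = j
        else:
            i += 1
    return clusters


def cluster_permutation(
    test_traces: np.ndarray,
    ref_traces: np.ndarray,
    fs: float,
    n_perm: int = 500,
    alpha: float = 0.05,
    min_duration: float = 0.02,
    max_reported: int = 5,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Cluster-based permutation comparison of two sets of traces.

    Pointwise two-sample t statistics are thresholded at the two-sided
    ``alpha`` critical value; contiguous suprathreshold runs form clusters
    whose mass is the summed t.  The null distribution is the maximum
    absolute cluster mass over ``n_perm`` label permutations.  Clusters
    shorter than ``min_duration`` are excluded and at most ``max_reported``
    clusters (largest mass first) are returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    test_traces = np.atleast_2d(np.asarray(test_traces, dtype=float))
    ref_traces = np.atleast_2d(np.asarray(ref_traces, dtype=float))
    if test_traces.shape[1] != ref_traces.shape[1]:
        raise ValueError("trace lengths must match")
    if test_traces.shape[0] < 2 or ref_traces.shape[0] < 2:
        raise ValueError("need at least two traces per condition")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable cluster p-values", stacklevel=2)

    n1, n2 = test_traces.shape[0], ref_traces.shape[0]
    df = n1 + n2 - 2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    pooled = np.vstack([test_traces, ref_traces])

    def tstat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / df * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sp > 0, (a.mean(axis=0) - b.mean(axis=0)) / sp, 0.0)
        return t

    t_obs = tstat(test_traces, ref_traces)
    obs_clusters = _find_clusters(t_obs, tcrit, fs)

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        idx = rng.permutation(n1 + n2)
        a, b = pooled[idx[:n1]], pooled[idx[n1:]]
        cl = _find_clusters(tstat(a, b), tcrit, fs)
        null_max[p] = max((abs(m) for _, _, m in cl), default=0.0)

    results = []
    for i, j, mass in obs_clusters:
        dur = (j - i) / fs
        if dur < min_duration:
            continue
        pval = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        results.append(
            {"start": i / fs, "end": j / fs, "mass": mass, "p": float(pval)}
        )
    results.sort(key=lambda c: -abs(c["mass"]))
    return ClusterResult(
        clusters=results[:max_reported],
        alpha=alpha,
        n_perm=n_perm,
        min_duration=min_duration,
        max_reported=max_reported,
        t_critical=float(tcrit),
    )
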