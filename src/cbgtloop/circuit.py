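"""Circuit description of the cortico-basal ganglia-thalamic (CBGT) neural mass model.

The model comprises six sources -- motor cortex (M2), striatum (STR), external
and internal pallidal segments (GPe/GPi), subthalamic nucleus (STN) and
ventrolateral thalamus (Thal) -- built from nine neural-mass populations.  The
motor cortex is a laminar microcircuit of three pyramidal layers (superficial
SP, middle MP, deep DP) plus an inhibitory interneuron population (II); each
subcortical source is a single population.

Each population follows a damped second-order neural-mass kernel

    v''(t) = (H / tau) * p(t) - (2 / tau) * v'(t) - v(t) / tau**2

where ``p`` sums sigmoid-transformed, delayed afferent voltages, stochastic
input and (optionally) an injected stimulation voltage.  Long-range
connections between sources carry finite, strictly positive delays.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

POPULATIONS = ("M2.SP", "M2.MP", "M2.DP", "M2.II", "STR", "GPe", "STN", "GPi", "Thal")
SOURCES = ("M2", "STR", "GPe", "STN", "GPi", "Thal")

POP_INDEX = {name: i for i, name in enumerate(POPULATIONS)}
SOURCE_INDEX = {name: i for i, name in enumerate(SOURCES)}

#: population through which a source receives long-range input
SOURCE_INPUT_POP = {
    "M2": "M2.MP",
    "STR": "STR",
    "GPe": "GPe",
    "STN": "STN",
    "GPi": "GPi",
    "Thal": "Thal",
}
#: population whose (delayed, sigmoid-transformed) voltage a source projects
SOURCE_OUTPUT_POP = {
    "M2": "M2.DP",
    "STR": "STR",
    "GPe": "GPe",
    "STN": "STN",
    "GPi": "GPi",
    "Thal": "Thal",
}
#: observed (recorded) population per source; M2 is read at the superficial
#: layer as a surface-ECoG proxy
DEFAULT_OBSERVATION = {
    "M2": "M2.SP",
    "STR": "STR",
    "GPe": "GPe",
    "STN": "STN",
    "GPi": "GPi",
    "Thal": "Thal",
}

INHIBITORY_SOURCES = frozenset({"STR", "GPe", "GPi"})
INHIBITORY_POPULATIONS = frozenset({"M2.II", "STR", "GPe", "GPi"})

#: allowed nonzero entries of the 6x6 source-level weight matrix, (to, from)
INTER_SPARSITY = frozenset(
    {
        (SOURCE_INDEX["M2"], SOURCE_INDEX["Thal"]),
        (SOURCE_INDEX["STR"], SOURCE_INDEX["M2"]),
        (SOURCE_INDEX["GPe"], SOURCE_INDEX["STR"]),
        (SOURCE_INDEX["GPe"], SOURCE_INDEX["STN"]),
        (SOURCE_INDEX["STN"], SOURCE_INDEX["M2"]),   # hyperdirect pathway
        (SOURCE_INDEX["STN"], SOURCE_INDEX["GPe"]),  # pallido-subthalamic pathway
        (SOURCE_INDEX["GPi"], SOURCE_INDEX["STR"]),
        (SOURCE_INDEX["GPi"], SOURCE_INDEX["STN"]),
        (SOURCE_INDEX["Thal"], SOURCE_INDEX["GPi"]),
    }
)

#: (to_source, from_source) index pairs of the two STN input pathways
HD_EDGE = (SOURCE_INDEX["STN"], SOURCE_INDEX["M2"])
PS_EDGE = (SOURCE_INDEX["STN"], SOURCE_INDEX["GPe"])


@dataclass
class PopulationSpec:
    """Parameters of one neural-mass population.

    Parameters
    ----------
    id : str
        Population label, one of :data:`POPULATIONS`.
    sign : str
        ``"excitatory"`` or ``"inhibitory"``; fixes the sign with which this
        population's output enters its targets.
    tau : float
        Lumped membrane/synaptic time constant in seconds.
    gain : float
        Synaptic gain ``H`` in millivolts.
    slope : float
        Sigmoid slope of the population's activation function
        ``S(v) = 1 / (1 + exp(-slope * v))``.
    noise_sd : float
        Standard deviation of the intrinsic stochastic input.  Nonzero only
        for the subcortical populations and the middle pyramidal layer.
    noise_scale : float
        Dimensionless multiplier on the intrinsic input (``C_stim``); during
        stimulation the population input becomes
        ``u_ex + noise_scale * u_in``.
    """

    id: str
    sign: str
    tau: float
    gain: float
    slope: float
    noise_sd: float = 0.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.id not in POPULATIONS:
            raise ValueError(f"unknown population id {self.id!r}")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"sign must be excitatory|inhibitory, got {self.sign!r}")
        if not self.tau > 0:
            raise ValueError(f"{self.id}: tau must be > 0")
        if not self.slope > 0:
            raise ValueError(f"{self.id}: slope must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"{self.id}: noise_sd must be >= 0")


@dataclass
class CircuitGraph:
    """Full parameterization of the 6-source / 9-population circuit.

    ``inter_weights`` is the signed 6x6 source-level coupling matrix in
    (to, from) indexing over :data:`SOURCES`; ``inter_delays`` holds the
    matching axonal delays in seconds (strictly positive wherever a weight is
    nonzero).  ``intra_cortical`` lists the M2 microcircuit connections as
    ``(from_pop, to_pop, weight)`` triples, including per-layer
    self-inhibition.
    """

    populations: list[PopulationSpec]
    inter_weights: np.ndarray
    inter_delays: np.ndarray
    intra_cortical: list[tuple[str, str, float]]
    observation_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OBSERVATION)
    )

    def __post_init__(self) -> None:
        self.inter_weights = np.asarray(self.inter_weights, dtype=float)
        self.inter_delays = np.asarray(self.inter_delays, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ids = [p.id for p in self.populations]
        if sorted(ids) != sorted(POPULATIONS):
            raise ValueError(f"populations must be exactly {POPULATIONS}, got {ids}")
        if self.inter_weights.shape != (6, 6) or self.inter_delays.shape != (6, 6):
            raise ValueError("inter_weights and inter_delays must be 6x6")
        nz = set(zip(*np.nonzero(self.inter_weights)))
        extra = nz - INTER_SPARSITY
        if extra:
            names = [(SOURCES[t], SOURCES[f]) for t, f in sorted(extra)]
            raise ValueError(f"weights outside the allowed sparsity pattern: {names}")
        if np.any((self.inter_weights != 0) & (self.inter_delays <= 0)):
            raise ValueError("every nonzero connection needs a delay D > 0")
        # inhibitory sources must enter their targets with negative weight
        for t, f in nz:
            w = self.inter_weights[t, f]
            if SOURCES[f] in INHIBITORY_SOURCES and w > 0:
                raise ValueError(f"inhibitory source {SOURCES[f]} has positive weight")
            if SOURCES[f] not in INHIBITORY_SOURCES and w < 0:
                raise ValueError(f"excitatory source {SOURCES[f]} has negative weight")
        noisy = {p.id for p in self.populations if p.noise_sd > 0}
        expected_noisy = {"M2.MP", "STR", "GPe", "STN", "GPi", "Thal"}
        if noisy and noisy != expected_noisy:
            raise ValueError(
                "stochastic input is restricted to the subcortical populations "
                f"and M2.MP; got noise on {sorted(noisy)}"
            )
        pops = set(POPULATIONS)
        for frm, to, w in self.intra_cortical:
            if frm not in pops or to not in pops:
                raise ValueError(f"unknown population in intra connection {frm}->{to}")
            if not (frm.startswith("M2.") and to.startswith("M2.")):
                raise ValueError("intra_cortical connections must stay within M2")
            p = self.population(frm)
            if p.sign == "inhibitory" and w > 0:
                raise ValueError(f"inhibitory {frm} must project with weight <= 0")
            if frm == to and w > 0:
                raise ValueError("self-connections must be inhibitory (weight < 0)")
        for src, pop in self.observation_map.items():
            if src not in SOURCE_INDEX or pop not in POP_INDEX:
                raise ValueError(f"bad observation mapping {src!r} -> {pop!r}")

    # -- access helpers -----------------------------------------------------
    def population(self, pop_id: str) -> PopulationSpec:
        for p in self.populations:
            if p.id == pop_id:
                return p
        raise KeyError(pop_id)

    def copy(self) -> "CircuitGraph":
        return copy.deepcopy(self)

    def scaled(self, edge: tuple[int, int], multiplier: float) -> "CircuitGraph":
        """Return a copy with one source-level weight scaled by ``multiplier``."""
        out = self.copy()
        out.inter_weights[edge] *= multiplier
        return out

    def noise_reference_sd(self, pop_id: str) -> float:
        """Noise SD used to scale stimulation amplitude for ``pop_id``.

        Falls back to the cortical (M2.MP) noise level for noise-free
        populations such as the superficial pyramidal layer.
        """
        sd = self.population(pop_id).noise_sd
        if sd > 0:
            return sd
        return self.population("M2.MP").noise_sd

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "populations": {
                p.id: {
                    "sign": p.sign,
                    "tau": float(p.tau),
                    "gain": float(p.gain),
                    "slope": float(p.slope),
                    "noise_sd": float(p.noise_sd),
                    "noise_scale": float(p.noise_scale),
                }
                for p in self.populations
            },
            "inter": [
                {
                    "from": SOURCES[f],
                    "to": SOURCES[t],
                    "weight": float(self.inter_weights[t, f]),
                    "delay": float(self.inter_delays[t, f]),
                }
                for t, f in sorted(zip(*np.nonzero(self.inter_weights)))
            ],
            "intra": [
                {"from": frm, "to": to, "weight": float(w)}
                for frm, to, w in self.intra_cortical
            ],
            "observation": dict(self.observation_map),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "CircuitGraph":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "CircuitGraph":
        pops = [
            PopulationSpec(id=pid, **spec) for pid, spec in doc["populations"].items()
        ]
        w = np.zeros((6, 6))
        d = np.zeros((6, 6))
        for e in doc["inter"]:
            t, f = SOURCE_INDEX[e["to"]], SOURCE_INDEX[e["from"]]
            w[t, f] = e["weight"]
            d[t, f] = e["delay"]
        intra = [(e["from"], e["to"], float(e["weight"])) for e in doc["intra"]]
        obs = dict(doc.get("observation", DEFAULT_OBSERVATION))
        return cls(pops, w, d, intra, obs)


# -- compiled (array) form used by the integrator ---------------------------


@dataclass
class CompiledCircuit:
    """Flat array view of a :class:`CircuitGraph` for the integration kernel."""

    tau: np.ndarray          # (9,)
    gain: np.ndarray         # (9,)
    slope: np.ndarray        # (9,)
    noise_sd: np.ndarray     # (9,)
    noise_scale: np.ndarray  # (9,)
    conn_target: np.ndarray  # (n_conn,) population indices
    conn_source: np.ndarray  # (n_conn,) population indices
    conn_weight: np.ndarray  # (n_conn,)
    conn_delay: np.ndarray   # (n_conn,) seconds
    observed_pops: np.ndarray  # (6,) population index observed per source

    def delay_steps(self, dt: float) -> np.ndarray:
        """Delays rounded to integration steps (minimum one step)."""
        return np.maximum(1, np.rint(self.conn_delay / dt)).astype(np.int64)


def compile_circuit(circuit: CircuitGraph) -> CompiledCircuit:
    pops = {p.id: p for p in circuit.populations}
    order = [pops[name] for name in POPULATIONS]
    tgt, src, wgt, dly = [], [], [], []
    for t, f in zip(*np.nonzero(circuit.inter_weights)):
        tgt.append(POP_INDEX[SOURCE_INPUT_POP[SOURCES[t]]])
        src.append(POP_INDEX[SOURCE_OUTPUT_POP[SOURCES[f]]])
        wgt.append(circuit.inter_weights[t, f])
        dly.append(circuit.inter_delays[t, f])
    for frm, to, w in circuit.intra_cortical:
        tgt.append(POP_INDEX[to])
        src.append(POP_INDEX[frm])
        wgt.append(w)
        dly.append(0.0)  # rounded up to the 1-step minimum by delay_steps()
    return CompiledCircuit(
        tau=np.array([p.tau for p in order]),
        gain=np.array([p.gain for p in order]),
        slope=np.array([p.slope for p in order]),
        noise_sd=np.array([p.noise_sd for p in order]),
        noise_scale=np.array([p.noise_scale for p in order]),
        conn_target=np.array(tgt, dtype=np.int64),
        conn_source=np.array(src, dtype=np.int64),
        conn_weight=np.array(wgt, dtype=float),
        conn_delay=np.array(dly, dtype=float),
        observed_pops=np.array(
            [POP_INDEX[circuit.observation_map[s]] for s in SOURCES], dtype=np.int64
        ),
    )


def default_circuit() -> CircuitGraph:
    """The packaged fitted-surrogate parameter set (beta-dominant regime)."""
    with resources.files("cbgtloop.data").joinpath("default_circuit.yaml").open() as fh:
        return CircuitGraph.from_yaml(fh)
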