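"""Validated parameter containers for E/I-clustered spiking networks.

A :class:`NetworkSpec` bundles neuron, synapse and clustering parameters in
one place.  Two presets, :func:`table1` (the 5000-neuron network used for the
balanced-state and metastability analyses) and :func:`table2` (the 1500-neuron
six-cluster task network), carry the standard parameterizations.

Units follow the conventions of the field: potentials in mV, capacitance in
pF, time constants in ms, currents in pA.  With C_m = 1 pF and time in ms this
makes V_th - E_L = 15 mV reachable by a 1.5 pA current in 10 ms membrane time
constants, i.e. currents and voltages are on the same numeric scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass(frozen=True)
class NeuronParameters:
    """Leaky integrate-and-fire single-neuron parameters.

    ``tau_m_E`` / ``tau_m_I`` are the membrane time constants of the
    excitatory and inhibitory populations; all other parameters are shared.
    """

    E_L: float = 0.0          # resting potential (mV)
    V_th: float = 15.0        # spike threshold (mV)
    V_R: float = 0.0          # reset potential (mV)
    C_m: float = 1.0          # membrane capacitance (pF)
    tau_m_E: float = 20.0     # E membrane time constant (ms)
    tau_m_I: float = 10.0     # I membrane time constant (ms)
    tau_r: float = 5.0        # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if not self.V_R < self.V_th:
            raise ValueError("require V_R < V_th")
        for name in ("C_m", "tau_m_E", "tau_m_I", "tau_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def tau_m(self, population: str) -> float:
        return {"E": self.tau_m_E, "I": self.tau_m_I}[population]


@dataclass(frozen=True)
class SynapseParameters:
    """Synaptic and connectivity parameters.

    ``tau_syn_E``/``tau_syn_I`` are the decay constants of currents from
    excitatory/inhibitory *sources*; ``p_XY`` is the connection probability
    for Y -> X (postsynaptic population first, as in the weight labels);
    ``g`` scales inhibition relative to excitation; ``n_E``/``n_I`` are
    population fractions of the total size ``N``.
    """

    tau_syn_E: float = 3.0
    tau_syn_I: float = 2.0
    p_EE: float = 0.2
    p_EI: float = 0.5
    p_IE: float = 0.5
    p_II: float = 0.5
    g: float = 1.2
    N: int = 5000
    n_E: float = 0.8
    n_I: float = 0.2

    def __post_init__(self) -> None:
        for name in ("p_EE", "p_EI", "p_IE", "p_II"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if abs(self.n_E + self.n_I - 1.0) > 1e-12:
            raise ValueError("population fractions must satisfy n_E + n_I = 1")
        if self.N <= 0:
            raise ValueError("N must be positive")

    def p(self, post: str, pre: str) -> float:
        return getattr(self, f"p_{post}{pre}")

    def tau_syn(self, source: str) -> float:
        return {"E": self.tau_syn_E, "I": self.tau_syn_I}[source]

    @property
    def N_E(self) -> int:
        return int(round(self.N * self.n_E))

    @property
    def N_I(self) -> int:
        return int(round(self.N * self.n_I))


@dataclass(frozen=True)
class WeightSet:
    """Base synaptic efficacies in pA (inhibitory ones negative)."""

    J_EE: float
    J_EI: float
    J_IE: float
    J_II: float

    def __post_init__(self) -> None:
        if not (self.J_EE > 0 and self.J_IE > 0):
            raise ValueError("excitatory weights must be positive")
        if not (self.J_EI <= 0 and self.J_II <= 0):
            raise ValueError("inhibitory weights must be non-positive")

    def J(self, post: str, pre: str) -> float:
        return getattr(self, f"J_{post}{pre}")


@dataclass(frozen=True)
class ClusterScaling:
    """Within/across-cluster weight multipliers.

    Potentiating within-cluster weights by ``J_plus`` and depressing
    across-cluster weights by ``J_minus = (Q - J_plus)/(Q - 1)`` preserves
    the mean synaptic strength exactly: J_plus + (Q-1) J_minus = Q.
    The inhibitory cluster strength follows the excitatory one through
    ``J_Iplus = 1 + R_J (J_Eplus - 1)``.
    """

    Q: int
    J_Eplus: float
    R_J: float = 0.75
    J_Eminus: float = field(init=False)
    J_Iplus: float = field(init=False)
    J_Iminus: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Q < 2:
            raise ValueError("Q must be >= 2")
        if not 1 <= self.J_Eplus <= self.Q:
            raise ValueError("require 1 <= J_Eplus <= Q (across-cluster weight"
                             " would change sign otherwise)")
        if not 0 <= self.R_J <= 1:
            raise ValueError("require 0 <= R_J <= 1")
        object.__setattr__(self, "J_Eminus",
                           (self.Q - self.J_Eplus) / (self.Q - 1))
        object.__setattr__(self, "J_Iplus",
                           1.0 + self.R_J * (self.J_Eplus - 1.0))
        object.__setattr__(self, "J_Iminus",
                           (self.Q - self.J_Iplus) / (self.Q - 1))

    def plus(self, alpha: str) -> float:
        return {"E": self.J_Eplus, "I": self.J_Iplus}[alpha]

    def minus(self, alpha: str) -> float:
        return {"E": self.J_Eminus, "I": self.J_Iminus}[alpha]


@dataclass(frozen=True)
class NetworkSpec:
    """Complete description of one network parameterization."""

    neuron: NeuronParameters
    synapse: SynapseParameters
    I_x_factor_E: float      # external current, multiples of I_th(E)
    I_x_factor_I: float      # external current, multiples of I_th(I)
    scaling: Optional[ClusterScaling] = None

    @property
    def N(self) -> int:
        return self.synapse.N

    @property
    def N_E(self) -> int:
        return self.synapse.N_E

    @property
    def N_I(self) -> int:
        return self.synapse.N_I

    def with_scaling(self, Q: int, J_Eplus: float,
                     R_J: float = 0.75) -> "NetworkSpec":
        return NetworkSpec(self.neuron, self.synapse,
                           self.I_x_factor_E, self.I_x_factor_I,
                           ClusterScaling(Q=Q, J_Eplus=J_Eplus, R_J=R_J))

    def to_dict(self) -> dict:
        d = {"neuron": asdict(self.neuron),
             "synapse": asdict(self.synapse),
             "I_x_factor_E": self.I_x_factor_E,
             "I_x_factor_I": self.I_x_factor_I}
        if self.scaling is not None:
            d["scaling"] = {"Q": self.scaling.Q,
                            "J_Eplus": self.scaling.J_Eplus,
                            "R_J": self.scaling.R_J}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        scaling = None
        if "scaling" in d and d["scaling"] is not None:
            scaling = ClusterScaling(**d["scaling"])
        return cls(neuron=NeuronParameters(**d["neuron"]),
                   synapse=SynapseParameters(**d["synapse"]),
                   I_x_factor_E=d["I_x_factor_E"],
                   I_x_factor_I=d["I_x_factor_I"],
                   scaling=scaling)

    @classmethod
    def from_yaml(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def table1(Q: Optional[int] = None, J_Eplus: float = 1.0,
           R_J: float = 0.75) -> NetworkSpec:
    """Standard 5000-neuron network (4000 E / 1000 I).

    External drive: I_x = 2.13 I_th for E, 1.24 I_th for I, tuned for
    spontaneous rates of ~3 (E) and ~5 (I) spikes/s in the balanced state.
    """
    spec = NetworkSpec(
        neuron=NeuronParameters(),
        synapse=SynapseParameters(N=5000),
        I_x_factor_E=2.13,
        I_x_factor_I=1.24,
    )
    if Q is not None:
        spec = spec.with_scaling(Q=Q, J_Eplus=J_Eplus, R_J=R_J)
    return spec


def table2(Q: int = 6, J_Eplus: float = 3.2, R_J: float = 0.75) -> NetworkSpec:
    """Six-cluster task network (1200 E / 300 I), one cluster per target."""
    return NetworkSpec(
        neuron=NeuronParameters(),
        synapse=SynapseParameters(N=1500),
        I_x_factor_E=1.25,
        I_x_factor_I=0.78,
        scaling=ClusterScaling(Q=Q, J_Eplus=J_Eplus, R_J=R_J),
    )
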