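"""Balanced-state calibration: PSP kernels, scale-free weights, currents.

The calibration requires that sqrt(K) near-synchronous excitatory spikes
(K = in-degree) drive the membrane from rest to threshold.  A presynaptic
spike injects an exponentially decaying current J e^{-t/tau_syn}; filtering
it through the membrane gives the postsynaptic potential (PSP)

    PSP(t) = (J / C_m) * tau_m tau_syn / (tau_m - tau_syn)
             * (exp(-t/tau_m) - exp(-t/tau_syn)),

whose peak sets the voltage "quantum" of one synapse.  The base weights are
scale-free in the in-degree and normalized by the PSP peak of the respective
synapse type, so that networks of different size N share the same operating
point.
"""

from __future__ import annotations

import math

import numpy as np

from .params import NeuronParameters, SynapseParameters, WeightSet, \
    ClusterScaling, NetworkSpec

__all__ = [
    "psp_kernel", "psp_max", "compute_weights", "threshold_current",
    "external_currents", "cluster_scaling", "derived_parameters",
]


def _check_taus(tau_m: float, tau_syn: float) -> None:
    if tau_m <= 0 or tau_syn <= 0:
        raise ValueError("time constants must be positive")
    if math.isclose(tau_m, tau_syn, rel_tol=1e-9):
        raise ValueError(
            "degenerate tau_m == tau_syn: the two-exponential PSP kernel has "
            "a pole there; use distinct time constants")


def psp_kernel(J: float, tau_m: float, tau_syn: float, C_m: float, t):
    """Membrane deflection (mV) at time(s) ``t`` (ms) after a presynaptic
    spike of efficacy ``J`` (pA).  Zero for t <= 0."""
    _check_taus(tau_m, tau_syn)
    t = np.asarray(t, dtype=float)
    pref = (J / C_m) * tau_m * tau_syn / (tau_m - tau_syn)
    out = pref * (np.exp(-t / tau_m) - np.exp(-t / tau_syn))
    return np.where(t > 0, out, 0.0)[()]


def psp_max(tau_m: float, tau_syn: float, C_m: float) -> tuple[float, float]:
    """Time of the PSP peak and its height per unit efficacy (mV/pA)."""
    _check_taus(tau_m, tau_syn)
    t_star = math.log(tau_syn / tau_m) / (1.0 / tau_m - 1.0 / tau_syn)
    peak = float(psp_kernel(1.0, tau_m, tau_syn, C_m, t_star))
    return t_star, peak


def _psp_peak(post: str, pre: str, neuron: NeuronParameters,
              syn: SynapseParameters) -> float:
    """PSP peak per unit efficacy for a pre -> post synapse: the membrane
    time constant is the target's, the synaptic one is the source's."""
    return psp_max(neuron.tau_m(post), syn.tau_syn(pre), neuron.C_m)[1]


def compute_weights(neuron: NeuronParameters,
                    syn: SynapseParameters) -> WeightSet:
    """Base synaptic efficacies (pA) from the balanced-state construction.

    The scale-free weights use sqrt(p_aE n_E N) = sqrt(K) normalization for
    the excitatory inputs, inhibition balances the mean excitatory drive
    (factor g for the E population), and every weight is divided by the PSP
    peak of its synapse type so that efficacies translate into comparable
    voltage deflections.
    """
    dV = neuron.V_th - neuron.E_L
    peak = {(a, b): _psp_peak(a, b, neuron, syn)
            for a in "EI" for b in "EI"}

    rad_EE = syn.p_EE * syn.n_E * syn.N
    rad_IE = syn.p_IE * syn.n_E * syn.N
    if rad_EE <= 0 or rad_IE <= 0:
        raise ValueError("non-positive in-degree radicand")

    J_EE = dV / math.sqrt(rad_EE) / peak[("E", "E")]
    J_EI = -syn.g * J_EE * (syn.p_EE * syn.n_E) / (syn.p_EI * syn.n_I) \
        * peak[("E", "E")] / peak[("E", "I")]
    J_IE = dV / math.sqrt(rad_IE) / peak[("I", "E")]
    J_II = -J_IE * (syn.p_IE * syn.n_E) / (syn.p_II * syn.n_I) \
        * peak[("I", "E")] / peak[("I", "I")]
    return WeightSet(J_EE=J_EE, J_EI=J_EI, J_IE=J_IE, J_II=J_II)


def threshold_current(neuron: NeuronParameters, population: str) -> float:
    """Rheobase current I_th = (V_th - E_L) C_m / tau_m (pA)."""
    return (neuron.V_th - neuron.E_L) * neuron.C_m / neuron.tau_m(population)


def external_currents(spec: NetworkSpec) -> tuple[float, float]:
    """Constant external currents (I_x_E, I_x_I) in pA.

    Expressed as multiples of the population rheobase; the multipliers are
    part of the network specification (they were tuned, once, to yield the
    target spontaneous rates).
    """
    return (spec.I_x_factor_E * threshold_current(spec.neuron, "E"),
            spec.I_x_factor_I * threshold_current(spec.neuron, "I"))


def cluster_scaling(Q: int, J_Eplus: float, R_J: float = 0.75) -> ClusterScaling:
    """Within/across-cluster multipliers with exact mean-weight balance."""
    return ClusterScaling(Q=Q, J_Eplus=J_Eplus, R_J=R_J)


def derived_parameters(spec: NetworkSpec) -> dict:
    """All derived quantities of a network spec as one flat report."""
    w = compute_weights(spec.neuron, spec.synapse)
    I_x_E, I_x_I = external_currents(spec)
    out = {
        "J_EE": w.J_EE, "J_EI": w.J_EI, "J_IE": w.J_IE, "J_II": w.J_II,
        "I_th_E": threshold_current(spec.neuron, "E"),
        "I_th_I": threshold_current(spec.neuron, "I"),
        "I_x_E": I_x_E, "I_x_I": I_x_I,
    }
    for (a, b) in (("E", "E"), ("E", "I"), ("I", "E"), ("I", "I")):
        t_star, peak = psp_max(spec.neuron.tau_m(a),
                               spec.synapse.tau_syn(b), spec.neuron.C_m)
        out[f"PSPmax_{a}{b}"] = peak
        out[f"t_star_{a}{b}"] = t_star
    if spec.scaling is not None:
        s = spec.scaling
        out.update({"Q": s.Q, "J_Eplus": s.J_Eplus, "J_Eminus": s.J_Eminus,
                    "J_Iplus": s.J_Iplus, "J_Iminus": s.J_Iminus,
                    "R_J": s.R_J})
    return out
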