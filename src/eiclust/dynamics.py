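"""Network simulation: leaky integrate-and-fire with exponential currents.

The membrane potential of each unit follows

    dV/dt = -(V - E_L)/tau_m + (I_syn + I_x + I_stim)/C_m,

with a spike emitted at V >= V_th, after which V is clamped to V_R for the
absolute refractory period tau_r.  Synaptic currents decay exponentially
with the time constant of the *source* population and jump by the synaptic
efficacy J_ij on arrival of a presynaptic spike (delivered one time step
after emission).  Integration is exponential-Euler at dt = 0.1 ms by
default; randomness enters only through the initial membrane potentials,
drawn uniformly on [V_R, V_th) to avoid start-up synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .calibration import external_currents
from .params import NetworkSpec
from .spikedata import SpikeData
from .topology import ConnectivityMatrix

__all__ = ["StimulusEpoch", "StimulusProtocol", "NetworkState",
           "initialize_state", "simulate", "record_currents"]


@dataclass(frozen=True)
class StimulusEpoch:
    """Constant extra current to a set of units during [t_start, t_end)."""

    t_start: float
    t_end: float
    units: np.ndarray
    amplitude: float

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("epoch must have non-negative duration")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        object.__setattr__(self, "units",
                           np.asarray(self.units, dtype=np.int64))


@dataclass
class StimulusProtocol:
    """Ordered list of stimulation epochs (may overlap; currents add)."""

    epochs: list = field(default_factory=list)

    def add(self, t_start: float, t_end: float, units,
            amplitude: float) -> "StimulusProtocol":
        self.epochs.append(StimulusEpoch(t_start, t_end, np.asarray(units),
                                         amplitude))
        return self

    def _events(self, dt: float, n_steps: int):
        """Flatten epochs into (step, amplitude delta, unit list) events."""
        ev = []
        for e in self.epochs:
            s0 = int(round(e.t_start / dt))
            s1 = int(round(e.t_end / dt))
            if s0 < n_steps and s1 > s0:
                ev.append((s0, e.amplitude, e.units))
                if s1 < n_steps:
                    ev.append((s1, -e.amplitude, e.units))
        ev.sort(key=lambda x: x[0])
        steps = np.array([x[0] for x in ev], dtype=np.int64)
        amps = np.array([x[1] for x in ev], dtype=float)
        uptr = np.zeros(len(ev) + 1, dtype=np.int64)
        for k, (_, _, u) in enumerate(ev):
            uptr[k + 1] = uptr[k] + len(u)
        units = (np.concatenate([x[2] for x in ev]).astype(np.int64)
                 if ev else np.empty(0, dtype=np.int64))
        return steps, amps, uptr, units


@dataclass
class NetworkState:
    """Initial (or snapshot) state of the network."""

    V: np.ndarray
    t: float = 0.0
    seed: Optional[int] = None


def initialize_state(spec: NetworkSpec, seed=None) -> NetworkState:
    """Membrane potentials uniform on [V_R, V_th); currents zero."""
    rng = np.random.default_rng(seed)
    V = rng.uniform(spec.neuron.V_R, spec.neuron.V_th, size=spec.N)
    return NetworkState(V=V, seed=seed)


def _per_unit_arrays(connectivity: ConnectivityMatrix, spec: NetworkSpec):
    pop = connectivity.assignment.population
    is_exc = (pop == "E")
    tau_m = np.where(is_exc, spec.neuron.tau_m_E, spec.neuron.tau_m_I)
    I_x_E, I_x_I = external_currents(spec)
    I_x = np.where(is_exc, I_x_E, I_x_I)
    return is_exc, tau_m.astype(float), I_x.astype(float)


def simulate(connectivity: ConnectivityMatrix, spec: NetworkSpec,
             protocol: Optional[StimulusProtocol] = None,
             duration: float = 1000.0, seed=None, dt: float = 0.1,
             state: Optional[NetworkState] = None,
             probe_units: Sequence[int] = (),
             ) -> SpikeData:
    """Run the network for ``duration`` ms and return the emitted spikes.

    Fully deterministic given (connectivity, protocol, seed, dt).  When
    ``probe_units`` is non-empty, per-step current and voltage traces of
    those units are attached to ``SpikeData.meta['probes']``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = connectivity.n_units
    if n != spec.N:
        raise ValueError("connectivity size does not match spec")
    if protocol is None:
        protocol = StimulusProtocol()
    if state is None:
        state = initialize_state(spec, seed)

    n_steps = int(round(duration / dt))
    is_exc, tau_m, I_x = _per_unit_arrays(connectivity, spec)
    w = connectivity.weights.tocsc()
    steps, amps, uptr, units = protocol._events(dt, n_steps)
    probes = np.asarray(probe_units, dtype=np.int64)
    if len(probes) and (probes.min() < 0 or probes.max() >= n):
        raise ValueError("probe unit out of range")

    (sp_step, sp_unit, tr_Ie, tr_Ii, tr_Ix, tr_V,
     error_step) = _engine.run_network(
        w.indptr.astype(np.int64), w.indices.astype(np.int64),
        w.data.astype(float), is_exc, tau_m, I_x,
        spec.neuron.E_L, spec.neuron.V_th, spec.neuron.V_R, spec.neuron.C_m,
        dt, n_steps, int(round(spec.neuron.tau_r / dt)),
        np.exp(-dt / spec.synapse.tau_syn_E),
        np.exp(-dt / spec.synapse.tau_syn_I),
        steps, amps, uptr, units, state.V.astype(float), probes)
    if error_step >= 0:
        raise FloatingPointError(
            f"membrane potential diverged near t = {error_step * dt:.1f} ms")

    meta_df = pd.DataFrame({
        "population": connectivity.assignment.population,
        "cluster": connectivity.assignment.cluster})
    data = SpikeData(times=sp_step * dt, units=sp_unit, duration=duration,
                     n_units=n, units_meta=meta_df,
                     meta={"seed": seed, "dt": dt,
                           "topology": connectivity.kind,
                           "topology_seed": connectivity.seed})
    if len(probes):
        t = np.arange(n_steps) * dt
        data.meta["probes"] = {
            "units": probes, "t": t, "I_E": tr_Ie, "I_I": tr_Ii,
            "I_x": tr_Ix, "I_tot": tr_Ie + tr_Ii + tr_Ix, "V": tr_V}
    return data


def record_currents(connectivity: ConnectivityMatrix, spec: NetworkSpec,
                    probe_units: Sequence[int],
                    protocol: Optional[StimulusProtocol] = None,
                    duration: float = 1000.0, seed=None,
                    dt: float = 0.1) -> dict:
    """Convenience wrapper: simulate with probes and return the traces
    (keys: units, t, I_E, I_I, I_x, I_tot, V) plus the spikes."""
    data = simulate(connectivity, spec, protocol=protocol, duration=duration,
                    seed=seed, dt=dt, probe_units=probe_units)
    traces = data.meta["probes"]
    traces["spikes"] = data
    return traces
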