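"""Synthetic spike-train generators and figure-protocol scan runners.

The generators produce reference processes with known statistics for
validating the estimators without a network simulation:

  * homogeneous Poisson (FF = CV2 = 1),
  * equilibrium gamma renewal with shape k (CV^2 = limiting FF = 1/k),
  * Poisson modulated by a two-state Markov (telegraph) rate, emulating
    metastable cluster switching (FF > 1 while CV2 ~ 1).

The scan runners reproduce, at configurable scale, the two spontaneous /
evoked protocols used to characterize the clustered networks: the Fano
factor as a function of cluster strength (metastability map) and the
stimulus-response curves of rate and FF changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .params import NetworkSpec
from .spikedata import SpikeData, TrialAlignedSpikes
from . import stats as st
from .topology import build_e_clustered, build_ei_clustered, \
    build_e_plus_i_variant, build_random_balanced
from .dynamics import simulate, StimulusProtocol

__all__ = ["FixtureSpec", "gen_poisson", "gen_gamma", "gen_switching",
           "run_fig_metastability_scan", "run_stimulus_scan",
           "TOPOLOGY_BUILDERS", "manifest"]


TOPOLOGY_BUILDERS = {
    "random": lambda spec, scaling, seed: build_random_balanced(spec, seed),
    "e": build_e_clustered,
    "ei": build_ei_clustered,
    "e_plus_i": build_e_plus_i_variant,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic spike-train ensemble."""

    kind: str                      # poisson | gamma | switching
    rate: float                    # spikes/s (low state for switching)
    duration: float                # ms
    n_units: int = 1
    n_trials: int = 1
    shape: float = 1.0             # gamma shape k
    rate_high: float = 0.0         # switching high-state rate (spikes/s)
    switch_up: float = 0.0         # low->high rate (1/s)
    switch_down: float = 0.0       # high->low rate (1/s)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.kind == "gamma" and self.shape <= 0:
            raise ValueError("gamma shape must be positive")

    def generate(self, seed=None) -> TrialAlignedSpikes:
        if self.kind == "poisson":
            return gen_poisson(self.rate, self.duration, self.n_units,
                               self.n_trials, seed)
        if self.kind == "gamma":
            return gen_gamma(self.rate, self.shape, self.duration,
                             self.n_units, self.n_trials, seed)
        if self.kind == "switching":
            return gen_switching(self.rate, self.rate_high, self.switch_up,
                                 self.switch_down, self.duration,
                                 self.n_units, self.n_trials, seed)
        raise ValueError(f"unknown fixture kind {self.kind!r}")


def _package(trains: dict, duration: float, n_units: int,
             n_trials: int) -> TrialAlignedSpikes:
    frames = [pd.DataFrame({"unit": u, "trial": tr, "time": t})
              for (u, tr), t in trains.items() if len(t)]
    events = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["unit", "trial", "time"]))
    info = pd.DataFrame(index=pd.RangeIndex(n_trials))
    return TrialAlignedSpikes(events=events, trial_info=info,
                              n_units=n_units, t_start=0.0,
                              t_stop=duration)


def aligned_to_spikedata(aligned: TrialAlignedSpikes,
                         trial: int = 0) -> SpikeData:
    """One trial of an aligned ensemble as a flat multi-unit event list."""
    ev = aligned.events
    sel = ev[ev["trial"] == trial]
    return SpikeData(times=sel["time"].to_numpy() - aligned.t_start,
                     units=sel["unit"].to_numpy(),
                     duration=aligned.t_stop - aligned.t_start,
                     n_units=aligned.n_units)


def gen_poisson(rate: float, duration: float, n_units: int = 1,
                n_trials: int = 1, seed=None) -> TrialAlignedSpikes:
    """Homogeneous Poisson trains at ``rate`` spikes/s, ``duration`` ms."""
    rng = np.random.default_rng(seed)
    lam = rate / 1000.0
    trains = {}
    for u in range(n_units):
        for tr in range(n_trials):
            n = rng.poisson(lam * duration)
            trains[(u, tr)] = np.sort(rng.uniform(0, duration, n))
    return _package(trains, duration, n_units, n_trials)


def gen_gamma(rate: float, shape: float, duration: float, n_units: int = 1,
              n_trials: int = 1, seed=None,
              burn_in_isis: float = 50.0) -> TrialAlignedSpikes:
    """Equilibrium gamma-renewal trains (shape k, mean rate ``rate``).

    Equilibrium is reached by starting the renewal sequence a burn-in of
    ``burn_in_isis`` mean intervals before the observation window.
    """
    rng = np.random.default_rng(seed)
    mean_isi = 1000.0 / rate
    burn = burn_in_isis * mean_isi
    scale = mean_isi / shape
    trains = {}
    for u in range(n_units):
        for tr in range(n_trials):
            total = burn + duration
            n_guess = int((total / mean_isi) * 1.5 + 30)
            t = -burn
            times = []
            while t < duration:
                draws = rng.gamma(shape, scale, n_guess)
                arr = t + np.cumsum(draws)
                times.append(arr)
                t = arr[-1]
            arr = np.concatenate(times)
            trains[(u, tr)] = arr[(arr >= 0) & (arr < duration)]
    return _package(trains, duration, n_units, n_trials)


def gen_switching(rate_low: float, rate_high: float, switch_up: float,
                  switch_down: float, duration: float, n_units: int = 1,
                  n_trials: int = 1, seed=None) -> TrialAlignedSpikes:
    """Poisson trains modulated by a two-state Markov telegraph rate.

    The rate switches low -> high with rate ``switch_up`` (1/s) and back
    with ``switch_down``; state durations are exponential.  The initial
    state is drawn from the stationary occupancy.
    """
    if rate_high <= 0:
        rate_high = rate_low
    rng = np.random.default_rng(seed)
    rates = (rate_low, rate_high)
    trains = {}
    p_high = (switch_up / (switch_up + switch_down)
              if (switch_up + switch_down) > 0 else 0.0)
    for u in range(n_units):
        for tr in range(n_trials):
            t = 0.0
            state = 1 if rng.random() < p_high else 0
            times = []
            while t < duration:
                out_rate = (switch_down if state else switch_up)
                dwell = (rng.exponential(1000.0 / out_rate)
                         if out_rate > 0 else duration - t)
                seg_end = min(t + dwell, duration)
                lam = rates[state] / 1000.0
                n = rng.poisson(lam * (seg_end - t))
                times.append(t + np.sort(rng.uniform(0, seg_end - t, n)))
                t = seg_end
                state = 1 - state
            trains[(u, tr)] = np.concatenate(times)
    return _package(trains, duration, n_units, n_trials)


# ------------------------------------------------------------ protocols

def spontaneous_ff(spec: NetworkSpec, kind: str, n_realizations: int = 5,
                   n_trials: int = 20, trial_ms: float = 400.0,
                   warmup_ms: float = 400.0, seed=0,
                   dt: float = 0.1) -> float:
    """Mean Fano factor of excitatory units during spontaneous activity.

    Per realization: build the network, simulate a warm-up plus
    ``n_trials`` contiguous windows of ``trial_ms``, compute the per-unit
    FF of spike counts across the windows, and average across E units;
    returned is the mean over realizations.
    """
    builder = TOPOLOGY_BUILDERS[kind]
    ffs = []
    rng = np.random.default_rng(seed)
    for _ in range(n_realizations):
        s_topo, s_sim = rng.integers(2 ** 31, size=2)
        conn = builder(spec, spec.scaling, int(s_topo))
        total = warmup_ms + n_trials * trial_ms
        data = simulate(conn, spec, duration=total, seed=int(s_sim), dt=dt)
        e_units = data.population_units("E")
        starts = warmup_ms + trial_ms * np.arange(n_trials)
        aligned = data.cut_trials(starts, trial_ms)
        counts = aligned.counts(0.0, trial_ms, units=e_units).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            ff = np.where(counts.mean(0) > 0,
                          counts.var(0, ddof=1) / counts.mean(0), np.nan)
        ffs.append(np.nanmean(ff))
    return float(np.mean(ffs))


def run_fig_metastability_scan(spec_base: NetworkSpec, J_Eplus_grid,
                               Q_grid=(50,), kind: str = "ei",
                               n_realizations: int = 5, n_trials: int = 20,
                               trial_ms: float = 400.0, seed=0,
                               R_J: float = 0.75,
                               dt: float = 0.1) -> pd.DataFrame:
    """FF as a function of cluster strength and cluster count.

    Returns a tidy (Q, J_Eplus, ff) table; the protocol per grid point is
    that of :func:`spontaneous_ff`.
    """
    rows = []
    for qi, Q in enumerate(Q_grid):
        for ji, J in enumerate(J_Eplus_grid):
            spec = spec_base.with_scaling(Q=int(Q), J_Eplus=float(J),
                                          R_J=R_J)
            ff = spontaneous_ff(spec, kind, n_realizations, n_trials,
                                trial_ms,
                                seed=np.random.SeedSequence(
                                    [seed, qi, ji]).generate_state(1)[0]
                                % (2 ** 31), dt=dt)
            rows.append({"Q": int(Q), "J_Eplus": float(J), "ff": ff,
                         "kind": kind})
    return pd.DataFrame(rows)


def run_stimulus_scan(spec: NetworkSpec, amplitudes, kind: str = "ei",
                      n_stimulated: int = 5, n_trials: int = 20,
                      epoch_ms: float = 1000.0, gap_ms: float = 1000.0,
                      seed=0, dt: float = 0.1) -> pd.DataFrame:
    """Stimulus-evoked rate and FF changes versus stimulus amplitude.

    Each trial consists of one spontaneous and one evoked epoch of
    ``epoch_ms``, preceded by ``gap_ms`` of relaxation so the network
    returns to its spontaneous metastable state between stimulations; the
    constant stimulus current is injected into all E units of the first
    ``n_stimulated`` clusters.  Changes are computed per neuron
    (evoked - spontaneous) and averaged within the stimulated and
    non-stimulated groups (see :func:`eiclust.stats.delta_stats`).
    """
    if spec.scaling is None:
        raise ValueError("spec must define a clustering")
    builder = TOPOLOGY_BUILDERS[kind]
    rng = np.random.default_rng(seed)
    s_topo, s_sim = rng.integers(2 ** 31, size=2)
    conn = builder(spec, spec.scaling, int(s_topo))
    stim_clusters = np.arange(n_stimulated)
    e_units = np.where((conn.assignment.population == "E")
                       & np.isin(conn.assignment.cluster, stim_clusters))[0]
    cluster_of_unit = conn.assignment.cluster.copy()
    # inhibitory units excluded from the neuron-level statistics
    cluster_of_unit[conn.assignment.population == "I"] = -1

    warmup = 400.0
    trial_len = gap_ms + 2 * epoch_ms
    rows = []
    for ai, amp in enumerate(amplitudes):
        protocol = StimulusProtocol()
        starts = warmup + gap_ms + trial_len * np.arange(n_trials)
        for s in starts:
            protocol.add(s + epoch_ms, s + 2 * epoch_ms, e_units,
                         float(amp))
        data = simulate(conn, spec, protocol=protocol,
                        duration=warmup + n_trials * trial_len,
                        seed=int(np.random.default_rng(
                            [int(s_sim), ai]).integers(2 ** 31)), dt=dt)
        spont = data.cut_trials(starts, epoch_ms)
        evoked = data.cut_trials(starts + epoch_ms, epoch_ms)
        table = st.delta_stats(spont, evoked, cluster_of_unit,
                               stim_clusters)
        table["amplitude"] = float(amp)
        table["kind"] = kind
        rows.append(table)
    return pd.concat(rows, ignore_index=True)


def manifest(params: dict, seed, path=None) -> dict:
    """Provenance record for an experiment run (parameter hash + seed)."""
    blob = json.dumps(params, sort_keys=True, default=str)
    out = {"parameters": params, "seed": seed,
           "param_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2, default=str)
    return out
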