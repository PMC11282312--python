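"""Delayed center-out task protocol, task network runs, and the decision
readout.

The task couples the six-cluster network (one excitatory/inhibitory cluster
pair per target direction) to a leaky-integrator decoder.  Each trial starts
at TS; the preparatory signal (PS) at TS+500 ms injects a constant current
into all excitatory units of the cued cluster(s) for 1000 ms; the response
signal (RS) at TS+1500 ms keeps stimulating only the final target's cluster
for 400 ms.  Trials are separated by an inter-trial interval drawn uniformly
from 1.5-1.7 s and cut post hoc from one continuous simulation.

Conditions cue 1, 2 or 3 adjacent targets; with six directions, Condition 2
uses only the pairs (1,2), (3,4), (5,6) and Condition 3 only the triples
(6,1,2) and (3,4,5), so all conditions offer the same number of trial types.

For every direction d a leaky integrator dI_d/dt = -I_d/tau_I + C_d
accumulates the instantaneous population spike count C_d of cluster d's
excitatory units; the decision variable DV_d = I_d / sum_j I_j is the
probability that d is the correct target.  A decision is the first DV to
cross the common threshold theta within 400 ms after RS (a DV already above
theta at RS counts as an anticipatory decision with reaction time 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .params import NetworkSpec
from .spikedata import SpikeData, TrialAlignedSpikes
from .dynamics import StimulusProtocol, simulate
from .topology import build_ei_clustered
from .stats import VariabilityTrace, _window_centers

__all__ = [
    "CONDITION_CUES", "DecoderParams", "make_task_protocol", "run_task",
    "cut_task_trials", "leaky_integrate", "decision_variable",
    "detect_decision", "decide_all_trials", "tune_threshold",
    "decoding_accuracy",
]

# cue sets per condition; directions are 1-based
CONDITION_CUES = {
    1: [(d,) for d in range(1, 7)],
    2: [(1, 2), (3, 4), (5, 6)],
    3: [(6, 1, 2), (3, 4, 5)],
}

PS_DELAY = 500.0        # TS -> PS (ms)
PREP_MS = 1000.0        # PS duration / preparatory period (ms)
RS_MS = 400.0           # RS duration = decision window (ms)
TRIAL_MS = 2000.0       # analyzed trial length from TS (ms)
ITI_RANGE = (1500.0, 1700.0)


@dataclass(frozen=True)
class DecoderParams:
    """Leaky-integrator decision readout parameters."""

    tau_I: float = 50.0          # integration time constant (ms)
    theta: float = 0.6           # decision threshold on DV (probability)
    bin_ms: float = 1.0          # spike-count bin of the integrator
    decision_window: float = RS_MS
    integrate_from: str = "PS"   # PS or RS

    def __post_init__(self) -> None:
        if self.tau_I <= 0:
            raise ValueError("tau_I must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")


def _e_units_of_cluster(spec: NetworkSpec, q: int) -> np.ndarray:
    size = spec.N_E // spec.scaling.Q
    return np.arange(q * size, (q + 1) * size)


def make_task_protocol(spec: NetworkSpec,
                       conditions: Sequence[int] = (1, 2, 3),
                       trials_per_condition: int = 150,
                       amplitude: float = 0.1,
                       seed=None) -> tuple[pd.DataFrame, StimulusProtocol]:
    """Trial table and stimulus protocol on one continuous timeline.

    Condition blocks run in the given order.  Within a block the cue sets
    cycle through the condition's trial types in randomized order and the
    final target is drawn uniformly from the cued set.
    """
    if spec.scaling is None or spec.scaling.Q != 6:
        raise ValueError("task requires a six-cluster network spec")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    protocol = StimulusProtocol()
    rows = []
    t = float(rng.uniform(*ITI_RANGE))
    for cond in conditions:
        if cond not in CONDITION_CUES:
            raise ValueError(f"invalid condition {cond}")
        cue_pool = CONDITION_CUES[cond]
        reps = int(np.ceil(trials_per_condition / len(cue_pool)))
        order = np.concatenate(
            [rng.permutation(len(cue_pool)) for _ in range(reps)]
        )[:trials_per_condition]
        for k in order:
            cues = cue_pool[int(k)]
            final = int(cues[rng.integers(len(cues))])
            ts, ps, rs = t, t + PS_DELAY, t + PS_DELAY + PREP_MS
            if amplitude > 0:
                cued_units = np.concatenate(
                    [_e_units_of_cluster(spec, d - 1) for d in cues])
                protocol.add(ps, rs, cued_units, amplitude)
                protocol.add(rs, rs + RS_MS,
                             _e_units_of_cluster(spec, final - 1), amplitude)
            iti = float(rng.uniform(*ITI_RANGE))
            rows.append({"condition": cond,
                         "cued": "+".join(map(str, cues)),
                         "final_direction": final,
                         "TS": ts, "PS": ps, "RS": rs,
                         "RS_duration": RS_MS, "ITI": iti})
            t = ts + TRIAL_MS + iti
    table = pd.DataFrame(rows)
    table.index.name = "trial"
    return table, protocol


def run_task(spec: NetworkSpec, trial_table: pd.DataFrame,
             protocol: StimulusProtocol, seed=None,
             dt: float = 0.1) -> SpikeData:
    """Build the E/I-clustered task network and run the whole protocol as
    one continuous simulation."""
    rng = np.random.default_rng(seed)
    s_topo, s_sim = (int(x) for x in rng.integers(2 ** 31, size=2))
    conn = build_ei_clustered(spec, spec.scaling, s_topo)
    duration = float(trial_table["TS"].iloc[-1] + TRIAL_MS
                     + trial_table["ITI"].iloc[-1])
    return simulate(conn, spec, protocol=protocol, duration=duration,
                    seed=s_sim, dt=dt)


def cut_task_trials(data: SpikeData, trial_table: pd.DataFrame,
                    pre_ms: float = 0.0) -> TrialAlignedSpikes:
    """Cut trials aligned to TS (time 0 = TS), optionally including
    ``pre_ms`` of preceding spontaneous activity."""
    starts = trial_table["TS"].to_numpy() - pre_ms
    aligned = data.cut_trials(starts, TRIAL_MS + pre_ms,
                              align=trial_table["TS"].to_numpy(),
                              trial_info=trial_table)
    return aligned


# -------------------------------------------------------------- decoder

def leaky_integrate(counts: np.ndarray, bin_ms: float,
                    tau_I: float) -> np.ndarray:
    """Discrete-time leaky integration of per-bin spike counts.

    ``counts`` has shape (n_bins, n_directions); the integrator starts at
    zero and decays by exp(-bin/tau_I) per bin; output is non-negative.
    """
    decay = np.exp(-bin_ms / tau_I)
    out = np.empty_like(counts, dtype=float)
    acc = np.zeros(counts.shape[1])
    for k in range(counts.shape[0]):
        acc = acc * decay + counts[k]
        out[k] = acc
    return out


def decision_variable(I: np.ndarray) -> np.ndarray:
    """Normalize integrator outputs to probabilities per time bin.

    Rows with an all-zero denominator become the uniform distribution.
    """
    I = np.asarray(I, dtype=float)
    total = I.sum(axis=-1, keepdims=True)
    n_dir = I.shape[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        dv = I / total
    return np.where(total > 0, dv, 1.0 / n_dir)


def cluster_counts(data: SpikeData, spec: NetworkSpec, t0: float,
                   t1: float, bin_ms: float = 1.0) -> np.ndarray:
    """Per-bin spike counts of each cluster's excitatory population in
    [t0, t1); shape (n_bins, Q)."""
    Q = spec.scaling.Q
    n_bins = int(round((t1 - t0) / bin_ms))
    edges = t0 + bin_ms * np.arange(n_bins + 1)
    out = np.zeros((n_bins, Q))
    pop = data.units_meta["population"].to_numpy()
    clu = data.units_meta["cluster"].to_numpy()
    for q in range(Q):
        members = np.where((pop == "E") & (clu == q))[0]
        m = np.isin(data.units, members)
        h, _ = np.histogram(data.times[m], bins=edges)
        out[:, q] = h
    return out


def trial_dv(data: SpikeData, spec: NetworkSpec, trial_row: pd.Series,
             params: DecoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Decision-variable traces of one trial.

    Returns (t, DV) where t is in ms relative to RS and DV has shape
    (n_bins, Q).  Integration starts at PS (or RS, per the parameters) and
    runs to the end of the decision window.
    """
    start = trial_row["PS"] if params.integrate_from == "PS" \
        else trial_row["RS"]
    stop = trial_row["RS"] + params.decision_window
    counts = cluster_counts(data, spec, start, stop, params.bin_ms)
    dv = decision_variable(leaky_integrate(counts, params.bin_ms,
                                           params.tau_I))
    t = (start - trial_row["RS"]) + params.bin_ms * (
        np.arange(counts.shape[0]) + 1)
    return t, dv


@dataclass(frozen=True)
class DecisionOutcome:
    """Outcome of one trial's threshold readout."""

    chosen: Optional[int]        # 1-based direction, None if no crossing
    reaction_time: Optional[float]  # ms from RS (0 = anticipatory)
    success: bool


def detect_decision(t: np.ndarray, dv: np.ndarray, theta: float,
                    final_direction: int,
                    decision_window: float = RS_MS) -> DecisionOutcome:
    """First threshold crossing in (RS, RS + window]; a DV already above
    threshold at RS is an anticipatory decision with RT = 0.  Ties at the
    same bin are broken toward the lower direction index."""
    at_rs = np.searchsorted(t, 0.0, side="right") - 1
    if at_rs >= 0:
        above = np.where(dv[at_rs] >= theta)[0]
        if len(above):
            d = int(above[0]) + 1
            return DecisionOutcome(chosen=d, reaction_time=0.0,
                                   success=d == final_direction)
    in_win = (t > 0) & (t <= decision_window)
    idx = np.where(in_win)[0]
    for k in idx:
        above = np.where(dv[k] >= theta)[0]
        if len(above):
            d = int(above[0]) + 1
            return DecisionOutcome(chosen=d, reaction_time=float(t[k]),
                                   success=d == final_direction)
    return DecisionOutcome(chosen=None, reaction_time=None, success=False)


def decide_all_trials(data: SpikeData, spec: NetworkSpec,
                      trial_table: pd.DataFrame,
                      params: DecoderParams) -> pd.DataFrame:
    """Decision outcome per trial of the table."""
    rows = []
    for trial, row in trial_table.iterrows():
        t, dv = trial_dv(data, spec, row, params)
        out = detect_decision(t, dv, params.theta,
                              int(row["final_direction"]),
                              params.decision_window)
        rows.append({"trial": trial, "condition": row["condition"],
                     "chosen": out.chosen,
                     "reaction_time": out.reaction_time,
                     "success": out.success})
    return pd.DataFrame(rows).set_index("trial")


def tune_threshold(data: SpikeData, spec: NetworkSpec,
                   trial_table: pd.DataFrame,
                   params: DecoderParams = DecoderParams(),
                   grid=None) -> tuple[float, float, pd.DataFrame]:
    """Threshold maximizing the mean success fraction over the condition
    blocks.  Returns (theta_star, best accuracy, per-theta table)."""
    if grid is None:
        grid = np.round(np.arange(0.50, 0.995, 0.01), 3)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    # compute DV traces once per trial
    traces = {trial: trial_dv(data, spec, row, params)
              for trial, row in trial_table.iterrows()}
    rows = []
    for theta in grid:
        acc_by_cond = []
        for cond, block in trial_table.groupby("condition"):
            successes = [
                detect_decision(*traces[trial], theta,
                                int(row["final_direction"]),
                                params.decision_window).success
                for trial, row in block.iterrows()]
            acc_by_cond.append(np.mean(successes))
        rows.append({"theta": theta, "accuracy": np.mean(acc_by_cond)})
    table = pd.DataFrame(rows)
    best = table.loc[table["accuracy"].idxmax()]
    return float(best["theta"]), float(best["accuracy"]), table


def condition_ff(aligned: TrialAlignedSpikes, t0: float, t1: float,
                 units=None, min_trials: int = 2) -> dict[int, float]:
    """Mean Fano factor per condition in the window [t0, t1).

    Trials are first grouped by identical cue set and final target within
    each condition (trial types are not pooled, since different cues drive
    different clusters); the per-unit FF is computed within each group,
    averaged over units with defined values, and then averaged over groups.
    """
    info = aligned.trial_info
    if units is None:
        units = np.arange(aligned.n_units)
    out = {}
    for cond, block in info.groupby("condition"):
        group_vals = []
        for _, g in block.groupby(["cued", "final_direction"]):
            if len(g) < min_trials:
                continue
            sub = aligned.subset_trials(g.index.to_numpy())
            counts = sub.counts(t0, t1, units=units).to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                ff = np.where(counts.mean(0) > 0,
                              counts.var(0, ddof=1) / counts.mean(0),
                              np.nan)
            if np.isfinite(ff).any():
                group_vals.append(np.nanmean(ff))
        out[int(cond)] = float(np.mean(group_vals)) if group_vals \
            else np.nan
    return out


# ------------------------------------------------------------- decoding

def decoding_accuracy(aligned: TrialAlignedSpikes, window: float = 400.0,
                      step: float = 100.0, n_folds: int = 5,
                      units=None, C: float = 1.0,
                      seed: int = 0) -> dict[int, VariabilityTrace]:
    """Cross-validated movement-direction decoding accuracy over time.

    Per condition and sliding window, a multinomial logistic-regression
    classifier is trained on per-trial spike-count vectors and scored with
    stratified ``n_folds``-fold cross-validation.  The accuracy is the
    fraction of correctly predicted directions averaged over the
    directions (macro average), so chance level is 1/6 regardless of class
    balance.  Classes with too few trials reduce the fold count (with a
    warning).
    """
    info = aligned.trial_info
    if units is None:
        units = np.arange(aligned.n_units)
    centers = _window_centers(aligned.t_start, aligned.t_stop, window, step)
    out = {}
    for cond, block in info.groupby("condition"):
        trials = block.index.to_numpy()
        y = block["final_direction"].to_numpy()
        sub = aligned.subset_trials(trials)
        min_class = np.bincount(pd.factorize(y)[0]).min()
        folds = n_folds
        if min_class < n_folds:
            folds = max(2, min_class)
            import warnings
            warnings.warn(f"condition {cond}: class with {min_class} "
                          f"trials, reducing folds to {folds}")
        values = np.empty(len(centers))
        for k, c in enumerate(centers):
            X = sub.counts(c - window / 2.0, c + window / 2.0,
                           units=units).to_numpy(dtype=float)
            accs = []
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=seed)
            for train, test in skf.split(X, y):
                clf = LogisticRegression(max_iter=2000, C=C)
                clf.fit(X[train], y[train])
                pred = clf.predict(X[test])
                per_dir = [np.mean(pred[y[test] == d] == d)
                           for d in np.unique(y[test])]
                accs.append(np.mean(per_dir))
            values[k] = np.mean(accs)
        out[int(cond)] = VariabilityTrace(
            t_center=centers, value=values,
            n_samples=np.full(len(centers), len(trials)),
            statistic="decoding_accuracy", window=window)
    return out
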