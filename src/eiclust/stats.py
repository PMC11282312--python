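"""Spike-train variability statistics.

Estimators for trial-to-trial count variability (Fano factor), interval
irregularity (CV and the rate-robust CV2), time-resolved sliding-window
traces, population synchrony, kernel rate estimates, stimulus-evoked
changes, the renewal-theory relation between interval and count
variability, and the unit-inclusion filter used before cross-condition
comparisons.

Estimator conventions (applied consistently):
  * variances use the unbiased (n-1) denominator;
  * statistics undefined on a window (empty counts, < 3 spikes for CV2)
    are excluded from averages rather than zero-filled, and returned as NaN
    at the single-train level;
  * population traces average the per-unit statistic across units.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .spikedata import SpikeData, TrialAlignedSpikes

__all__ = [
    "fano_factor", "cv", "cv2", "isis", "time_resolved", "VariabilityTrace",
    "synchrony_chi", "rate_kernel", "delta_stats", "renewal_consistency",
    "unit_inclusion_filter",
]


# ---------------------------------------------------------------- basic

def fano_factor(counts) -> float:
    """Variance/mean of spike counts across trials (NaN when mean is 0)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("Fano factor needs at least 2 trials")
    mu = counts.mean()
    if mu == 0:
        return np.nan
    return counts.var(ddof=1) / mu


def cv(intervals) -> float:
    """Coefficient of variation sigma/mu of inter-spike intervals."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise ValueError("CV needs at least 2 intervals")
    return intervals.std(ddof=1) / intervals.mean()


def cv2(intervals) -> float:
    """Local interval irregularity 2 <|tau - tau'| / (tau + tau')> over
    consecutive interval pairs; NaN for fewer than 2 intervals."""
    tau = np.asarray(intervals, dtype=float)
    if tau.size < 2:
        return np.nan
    a, b = tau[:-1], tau[1:]
    return float(2.0 * np.mean(np.abs(a - b) / (a + b)))


def isis(times) -> np.ndarray:
    """Inter-spike intervals of one sorted spike train."""
    return np.diff(np.sort(np.asarray(times, dtype=float)))


# ------------------------------------------------------- time-resolved

@dataclass
class VariabilityTrace:
    """Window-centered time series of one statistic.

    ``n_samples`` counts the units (or unit/trial pairs) contributing to
    each window average.
    """

    t_center: np.ndarray
    value: np.ndarray
    n_samples: np.ndarray
    statistic: str
    window: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_center": self.t_center,
                             "statistic": self.statistic,
                             "value": self.value, "n": self.n_samples})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _window_centers(t_start: float, t_stop: float, window: float,
                    step: float) -> np.ndarray:
    first = t_start + window / 2.0
    last = t_stop - window / 2.0
    if last < first:
        raise ValueError("window wider than the trial span")
    n = int(np.floor((last - first) / step + 1e-9)) + 1
    return first + step * np.arange(n)


def time_resolved(aligned: TrialAlignedSpikes, window: float = 400.0,
                  step: float = 25.0, statistic: str = "ff",
                  units=None) -> VariabilityTrace:
    """Sliding-window (centered) population trace of FF, CV2 or rate.

    FF: per unit, counts across trials in each window -> FF, then averaged
    over units with defined values.  CV2: per (unit, trial) within the
    window, averaged over trials then units.  rate: mean rate per unit
    (spikes/s) averaged over units.
    """
    statistic = statistic.lower()
    if statistic not in ("ff", "cv2", "rate"):
        raise ValueError(f"unknown statistic {statistic!r}")
    centers = _window_centers(aligned.t_start, aligned.t_stop, window, step)
    if units is None:
        units = np.unique(aligned.events["unit"].to_numpy())
    units = np.asarray(units)
    trials = aligned.trial_ids
    ev = aligned.events
    ev = ev[ev["unit"].isin(units)]
    values = np.full(len(centers), np.nan)
    n_samples = np.zeros(len(centers), dtype=int)

    for k, c in enumerate(centers):
        lo, hi = c - window / 2.0, c + window / 2.0
        sub = ev[(ev["time"] >= lo) & (ev["time"] < hi)]
        if statistic == "ff":
            counts = sub.groupby(["unit", "trial"]).size() \
                .unstack(fill_value=0) \
                .reindex(index=units, columns=trials, fill_value=0)
            vals = np.array([fano_factor(row) for row in counts.to_numpy()])
        elif statistic == "rate":
            counts = sub.groupby("unit").size() \
                .reindex(units, fill_value=0).to_numpy()
            vals = counts / len(trials) / (window / 1000.0)
        else:  # cv2: per (unit, trial), then trials, then units
            vals = np.full(len(units), np.nan)
            for i, u in enumerate(units):
                per_trial = []
                g = sub[sub["unit"] == u]
                for _, times in g.groupby("trial")["time"]:
                    c2 = cv2(np.diff(np.sort(times.to_numpy())))
                    if np.isfinite(c2):
                        per_trial.append(c2)
                if per_trial:
                    vals[i] = np.mean(per_trial)
        good = np.isfinite(vals)
        n_samples[k] = int(good.sum())
        if n_samples[k]:
            values[k] = vals[good].mean()
    return VariabilityTrace(t_center=centers, value=values,
                            n_samples=n_samples, statistic=statistic,
                            window=window)


# ----------------------------------------------------------- synchrony

def synchrony_chi(spikes: SpikeData, bin_ms: float = 20.0,
                  units=None) -> float:
    """Population synchrony chi = sqrt(var(pop mean trace) / <var_i>).

    Computed on per-unit spike counts in bins of ``bin_ms``; equals 1 for
    identical trains and scales as 1/sqrt(N) for independent units.  NaN
    for all-silent input.
    """
    if units is None:
        units = np.arange(spikes.n_units)
    units = np.asarray(units)
    if len(units) < 2:
        raise ValueError("chi needs at least 2 units")
    n_bins = int(np.floor(spikes.duration / bin_ms))
    if n_bins < 2:
        raise ValueError("chi needs at least 2 bins")
    edges = np.arange(n_bins + 1) * bin_ms
    counts = np.empty((len(units), n_bins))
    mask = np.isin(spikes.units, units)
    u_index = {u: i for i, u in enumerate(units)}
    rows = np.array([u_index[u] for u in spikes.units[mask]], dtype=int) \
        if mask.any() else np.empty(0, dtype=int)
    cols = np.digitize(spikes.times[mask], edges) - 1
    ok = (cols >= 0) & (cols < n_bins)
    counts[:] = 0.0
    np.add.at(counts, (rows[ok], cols[ok]), 1.0)
    var_i = counts.var(axis=1, ddof=1)
    denom = var_i.mean()
    if denom == 0:
        return np.nan
    return float(np.sqrt(counts.mean(axis=0).var(ddof=1) / denom))


def rate_kernel(times, duration: float, width: float = 50.0,
                dt: float = 1.0, n_trials: int = 1):
    """Firing-rate trace (spikes/s) from a triangular kernel of the given
    total ``width`` (ms), unit area; evaluated on a grid of step ``dt``."""
    if width <= 0:
        raise ValueError("kernel width must be positive")
    n = int(round(duration / dt))
    grid = np.zeros(n)
    idx = np.floor(np.asarray(times, dtype=float) / dt).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(grid, idx, 1.0)
    half = max(int(round(width / 2.0 / dt)), 1)
    k = 1.0 - np.abs(np.arange(-half, half + 1)) / half
    k = k / (k.sum() * dt / 1000.0)      # unit area in seconds
    t = np.arange(n) * dt
    return t, np.convolve(grid, k, mode="same") / n_trials


# ------------------------------------------------------- evoked deltas

def delta_stats(spont: TrialAlignedSpikes, evoked: TrialAlignedSpikes,
                cluster_of_unit: np.ndarray, stimulated_clusters,
                rate_mask_bin: float = 20.0) -> pd.DataFrame:
    """Per-group stimulus-evoked changes in rate and Fano factor.

    Both inputs must hold the same units and equally many trials; counts
    are taken over each full epoch.  The difference (evoked - spontaneous)
    is computed per neuron before group averaging; the table reports the
    group mean and standard error for stimulated vs non-stimulated
    clusters.

    The evoked rate of stimulated clusters is restricted to active
    periods: time bins in which the cluster's trial-averaged population
    rate exceeds the median rate of the non-stimulated clusters.  This
    isolates the rate attained in the activated state from trials/periods
    where the cluster failed to switch.
    """
    if spont.n_units != evoked.n_units:
        raise ValueError("unit sets of the two epochs differ")
    if spont.n_trials != evoked.n_trials:
        raise ValueError("trial counts of the two epochs differ")
    units = np.arange(spont.n_units)
    cluster_of_unit = np.asarray(cluster_of_unit)
    stimulated = set(int(q) for q in np.atleast_1d(stimulated_clusters))

    def epoch_counts(al):
        return al.counts(al.t_start, al.t_stop, units=units)

    c_sp = epoch_counts(spont).to_numpy(dtype=float)   # trials x units
    c_ev = epoch_counts(evoked).to_numpy(dtype=float)
    dur_sp = (spont.t_stop - spont.t_start) / 1000.0
    dur_ev = (evoked.t_stop - evoked.t_start) / 1000.0

    with np.errstate(invalid="ignore", divide="ignore"):
        ff_sp = np.where(c_sp.mean(0) > 0,
                         c_sp.var(0, ddof=1) / c_sp.mean(0), np.nan)
        ff_ev = np.where(c_ev.mean(0) > 0,
                         c_ev.var(0, ddof=1) / c_ev.mean(0), np.nan)
    d_ff = ff_ev - ff_sp
    rate_sp = c_sp.mean(0) / dur_sp

    # trial-averaged cluster rate traces in the evoked epoch
    n_bins = int(np.floor((evoked.t_stop - evoked.t_start) / rate_mask_bin))
    edges = evoked.t_start + rate_mask_bin * np.arange(n_bins + 1)
    clusters = np.unique(cluster_of_unit[cluster_of_unit >= 0])
    traces = {}
    ev = evoked.events
    for q in clusters:
        members = units[cluster_of_unit == q]
        sel = ev[ev["unit"].isin(members)]
        h, _ = np.histogram(sel["time"], bins=edges)
        traces[q] = h / len(members) / evoked.n_trials \
            / (rate_mask_bin / 1000.0)
    non_stim = [q for q in clusters if q not in stimulated]
    med = np.median(np.concatenate([traces[q] for q in non_stim])) \
        if non_stim else 0.0

    d_rate = np.empty(len(units))
    for i, u in enumerate(units):
        q = cluster_of_unit[u]
        if q in stimulated:
            active = traces[q] > med
            if active.any():
                sel = ev[ev["unit"] == u]
                h, _ = np.histogram(sel["time"], bins=edges)
                r_ev = h[active].sum() / evoked.n_trials \
                    / (active.sum() * rate_mask_bin / 1000.0)
            else:
                r_ev = c_ev[:, i].mean() / dur_ev
        else:
            r_ev = c_ev[:, i].mean() / dur_ev
        d_rate[i] = r_ev - rate_sp[i]

    rows = []
    for label, in_group in (("stimulated", True), ("non_stimulated", False)):
        sel = np.array([(cluster_of_unit[u] in stimulated) == in_group
                        and cluster_of_unit[u] >= 0 for u in units])
        for name, vals in (("delta_rate", d_rate), ("delta_ff", d_ff)):
            v = vals[sel]
            v = v[np.isfinite(v)]
            rows.append({"group": label, "statistic": name,
                         "mean": v.mean() if len(v) else np.nan,
                         "sem": (v.std(ddof=1) / np.sqrt(len(v))
                                 if len(v) > 1 else np.nan),
                         "n": len(v)})
    return pd.DataFrame(rows)


# ------------------------------------------------ renewal consistency

def renewal_consistency(intervals, max_lag: int = 10,
                        min_intervals: int = 100) -> dict:
    """Interval-based prediction of the limiting Fano factor.

    For a stationary point process the count variability converges to
    CV^2 (1 + 2 xi), with xi the sum of the serial interval correlation
    coefficients (here truncated at ``max_lag``).  For renewal trains
    xi ~ 0 and the limit is CV^2.
    """
    tau = np.asarray(intervals, dtype=float)
    flagged = tau.size < min_intervals
    if tau.size < max_lag + 2:
        raise ValueError("too few intervals for the requested max_lag")
    cv_sq = float(cv(tau) ** 2)
    xi = 0.0
    for lag in range(1, max_lag + 1):
        a, b = tau[:-lag], tau[lag:]
        xi += float(np.corrcoef(a, b)[0, 1])
    return {"cv_squared": cv_sq, "xi": xi,
            "predicted_ff": cv_sq * (1.0 + 2.0 * xi),
            "flagged_short": flagged}


# ------------------------------------------------------------ filtering

def unit_inclusion_filter(aligned: TrialAlignedSpikes,
                          min_spikes: int = 10, min_trials: int = 10,
                          count_window: tuple[float, float] = (0.0, 2000.0),
                          condition_col: str = "condition",
                          direction_col: str = "final_direction"
                          ) -> TrialAlignedSpikes:
    """Retain (unit, direction) pairs that satisfy the inclusion criteria
    in *every* condition: at least ``min_trials`` trials recorded and a
    mean of at least ``min_spikes`` spikes per trial in ``count_window``
    (ms after trial start)."""
    info = aligned.trial_info
    conditions = info[condition_col].unique()
    ev = aligned.events
    t0, t1 = count_window
    in_win = ev[(ev["time"] >= t0) & (ev["time"] < t1)]

    units = np.arange(aligned.n_units)
    directions = info[direction_col].unique()
    keep: set[tuple[int, object]] = set()
    for d in directions:
        ok_everywhere = np.ones(len(units), dtype=bool)
        for cond in conditions:
            tr = info[(info[condition_col] == cond)
                      & (info[direction_col] == d)].index.to_numpy()
            if len(tr) < min_trials:
                ok_everywhere[:] = False
                break
            counts = in_win[in_win["trial"].isin(tr)] \
                .groupby("unit").size().reindex(units, fill_value=0)
            ok_everywhere &= (counts.to_numpy() / len(tr)) >= min_spikes
        for u in units[ok_everywhere]:
            keep.add((int(u), d))

    if not keep:
        empty = ev.iloc[0:0]
        return TrialAlignedSpikes(events=empty, trial_info=info.iloc[0:0],
                                  n_units=aligned.n_units,
                                  t_start=aligned.t_start,
                                  t_stop=aligned.t_stop)
    kept_mask = ev.apply(
        lambda r: (int(r["unit"]),
                   info.loc[r["trial"], direction_col]) in keep, axis=1)
    kept_trials = sorted({t for t in info.index
                          if any((u, info.loc[t, direction_col]) in keep
                                 for u in units)})
    return TrialAlignedSpikes(events=ev[kept_mask].reset_index(drop=True),
                              trial_info=info.loc[kept_trials],
                              n_units=aligned.n_units,
                              t_start=aligned.t_start,
                              t_stop=aligned.t_stop)
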