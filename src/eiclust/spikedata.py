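"""Spike-event containers and their plain-text interchange formats.

:class:`SpikeData` is the interchange object between the simulator, the
synthetic generators, and the statistics: a flat event list (time in ms,
unit id) plus unit metadata (population, cluster) and the simulated
duration.  :class:`TrialAlignedSpikes` holds the same events cut into trials
and aligned to a reference event, together with per-trial labels.

Both round-trip through CSV losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SpikeData", "TrialAlignedSpikes"]


@dataclass
class SpikeData:
    """Event list (ms, unit id) with unit metadata.

    ``units_meta`` is a DataFrame indexed 0..n_units-1 with columns
    ``population`` ('E'/'I') and ``cluster`` (int, -1 if unclustered).
    """

    times: np.ndarray
    units: np.ndarray
    duration: float
    n_units: int
    units_meta: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.units = np.asarray(self.units, dtype=np.int64)
        if self.times.shape != self.units.shape:
            raise ValueError("times and units must have equal length")
        if len(self.units) and (self.units.min() < 0
                                or self.units.max() >= self.n_units):
            raise ValueError("unit id out of range")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spikes_of(self, unit: int) -> np.ndarray:
        return np.sort(self.times[self.units == unit])

    def population_units(self, population: str) -> np.ndarray:
        if self.units_meta is None:
            raise ValueError("no unit metadata attached")
        return np.where(self.units_meta["population"].to_numpy()
                        == population)[0]

    def rate(self, unit_subset=None) -> float:
        """Mean firing rate (spikes/s) over the full duration."""
        if unit_subset is None:
            n, count = self.n_units, self.n_spikes
        else:
            unit_subset = np.asarray(unit_subset)
            n = len(unit_subset)
            count = int(np.isin(self.units, unit_subset).sum())
        return count / n / (self.duration / 1000.0)

    def select(self, t_start: float, t_stop: float) -> "SpikeData":
        """Events in [t_start, t_stop), re-referenced to t_start."""
        m = (self.times >= t_start) & (self.times < t_stop)
        return SpikeData(self.times[m] - t_start, self.units[m],
                         duration=t_stop - t_start, n_units=self.n_units,
                         units_meta=self.units_meta, meta=dict(self.meta))

    def to_csv(self, events_path, units_path=None) -> None:
        pd.DataFrame({"time_ms": self.times, "unit_id": self.units}
                     ).to_csv(events_path, index=False)
        if units_path is not None:
            meta = self.units_meta
            if meta is None:
                meta = pd.DataFrame({
                    "population": ["?"] * self.n_units,
                    "cluster": [-1] * self.n_units})
            out = meta.copy()
            out.insert(0, "unit_id", np.arange(self.n_units))
            out.to_csv(units_path, index=False)

    @classmethod
    def from_csv(cls, events_path, units_path=None,
                 duration: Optional[float] = None,
                 n_units: Optional[int] = None) -> "SpikeData":
        ev = pd.read_csv(events_path, float_precision="round_trip")
        meta = None
        if units_path is not None:
            meta = pd.read_csv(units_path).sort_values("unit_id") \
                .set_index("unit_id")[["population", "cluster"]] \
                .reset_index(drop=True)
            n_units = len(meta)
        if n_units is None:
            n_units = int(ev["unit_id"].max()) + 1 if len(ev) else 0
        if duration is None:
            duration = float(ev["time_ms"].max()) if len(ev) else 0.0
        return cls(ev["time_ms"].to_numpy(), ev["unit_id"].to_numpy(),
                   duration=duration, n_units=n_units, units_meta=meta)

    def cut_trials(self, starts, duration: float,
                   align: Optional[np.ndarray] = None,
                   trial_info: Optional[pd.DataFrame] = None
                   ) -> "TrialAlignedSpikes":
        """Cut windows [start, start+duration) into trials.

        ``align`` (default: the starts) gives the per-trial reference event;
        trial times are reported relative to it.
        """
        starts = np.asarray(starts, dtype=float)
        if align is None:
            align = starts
        frames = []
        order = np.argsort(self.times, kind="stable")
        t_sorted = self.times[order]
        u_sorted = self.units[order]
        for k, (s, a) in enumerate(zip(starts, align)):
            lo, hi = np.searchsorted(t_sorted, [s, s + duration])
            frames.append(pd.DataFrame({
                "unit": u_sorted[lo:hi], "trial": k,
                "time": t_sorted[lo:hi] - a}))
        events = pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=["unit", "trial", "time"])
        if trial_info is None:
            trial_info = pd.DataFrame(index=pd.RangeIndex(len(starts)))
        return TrialAlignedSpikes(events=events, trial_info=trial_info,
                                  n_units=self.n_units,
                                  t_start=float(starts[0] - align[0]),
                                  t_stop=float(starts[0] - align[0]
                                               + duration))


@dataclass
class TrialAlignedSpikes:
    """Spike times per (unit, trial), aligned to a reference event.

    ``events`` has columns (unit, trial, time); ``trial_info`` is indexed by
    trial id and may carry condition, cued directions, final direction and
    epoch timestamps.  ``t_start``/``t_stop`` bound the aligned times.
    """

    events: pd.DataFrame
    trial_info: pd.DataFrame
    n_units: int
    t_start: float
    t_stop: float

    @property
    def n_trials(self) -> int:
        return len(self.trial_info)

    @property
    def trial_ids(self) -> np.ndarray:
        return self.trial_info.index.to_numpy()

    def counts(self, t0: float, t1: float,
               units=None) -> pd.DataFrame:
        """Spike-count matrix (trials x units) in the window [t0, t1)."""
        if units is None:
            units = np.arange(self.n_units)
        ev = self.events
        m = (ev["time"] >= t0) & (ev["time"] < t1)
        sub = ev[m]
        table = sub.groupby(["trial", "unit"]).size().unstack(fill_value=0)
        table = table.reindex(index=self.trial_ids, columns=units,
                              fill_value=0)
        return table

    def spikes_of(self, unit: int, trial: int) -> np.ndarray:
        ev = self.events
        m = (ev["unit"] == unit) & (ev["trial"] == trial)
        return np.sort(ev.loc[m, "time"].to_numpy())

    def subset_trials(self, trial_ids) -> "TrialAlignedSpikes":
        trial_ids = np.asarray(trial_ids)
        ev = self.events[self.events["trial"].isin(trial_ids)]
        return TrialAlignedSpikes(events=ev.reset_index(drop=True),
                                  trial_info=self.trial_info.loc[trial_ids],
                                  n_units=self.n_units,
                                  t_start=self.t_start, t_stop=self.t_stop)

    def to_csv(self, events_path, trials_path=None) -> None:
        self.events.to_csv(events_path, index=False)
        if trials_path is not None:
            self.trial_info.to_csv(trials_path, index_label="trial")

    @classmethod
    def from_csv(cls, events_path, trials_path, n_units: int,
                 t_start: float, t_stop: float) -> "TrialAlignedSpikes":
        events = pd.read_csv(events_path, float_precision="round_trip")
        trial_info = pd.read_csv(trials_path, index_col="trial")
        return cls(events=events, trial_info=trial_info, n_units=n_units,
                   t_start=t_start, t_stop=t_stop)
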