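"""Statistics estimators against closed-form and synthetic oracles."""

import numpy as np
import pandas as pd
import pytest

from eiclust import (fano_factor, cv, cv2, isis, time_resolved,
                     synchrony_chi, rate_kernel, delta_stats,
                     renewal_consistency, unit_inclusion_filter,
                     gen_poisson, gen_gamma)
from eiclust.spikedata import SpikeData, TrialAlignedSpikes


class TestBasics:
    def test_fano_known_values(self):
        # var([1,3]) = 2, mean = 2
        assert fano_factor([1, 3]) == pytest.approx(1.0)
        assert fano_factor([4, 4, 4]) == 0.0

    def test_fano_zero_mean_is_nan(self):
        assert np.isnan(fano_factor([0, 0, 0]))

    def test_fano_needs_two_trials(self):
        with pytest.raises(ValueError):
            fano_factor([5])

    def test_cv_known_values(self):
        assert cv([2.0, 2.0, 2.0]) == 0.0
        x = np.array([1.0, 3.0])
        assert cv(x) == pytest.approx(x.std(ddof=1) / 2.0)

    def test_cv2_regular_train_is_zero(self):
        assert cv2([10.0] * 20) == 0.0

    def test_cv2_alternating_closed_form(self):
        # consecutive pairs always (a, b) or (b, a): CV2 = 2|a-b|/(a+b)
        a, b = 5.0, 15.0
        tau = np.tile([a, b], 50)
        assert cv2(tau) == pytest.approx(2 * abs(a - b) / (a + b))

    def test_cv2_short_input_nan(self):
        assert np.isnan(cv2([7.0]))

    def test_isis_sorts_first(self):
        assert np.array_equal(isis([30.0, 10.0, 20.0]), [10.0, 10.0])


@pytest.fixture(scope="module")
def poisson_ensemble():
    return gen_poisson(20.0, 2000.0, n_units=30, n_trials=40, seed=3)


class TestTimeResolved:
    def test_poisson_ff_near_one(self, poisson_ensemble):
        tr = time_resolved(poisson_ensemble, window=400.0, step=200.0,
                           statistic="ff")
        # FF of Poisson counts: sampling SE ~ sqrt(2/(n_trials-1)) per unit,
        # averaged over 30 units
        assert np.all(np.abs(tr.value - 1.0) < 0.15)

    def test_poisson_cv2_near_one(self, poisson_ensemble):
        tr = time_resolved(poisson_ensemble, window=2000.0, step=2000.0,
                           statistic="cv2")
        # E[CV2] = 1 for Poisson
        assert tr.value[0] == pytest.approx(1.0, abs=0.05)

    def test_rate_statistic_recovers_rate(self, poisson_ensemble):
        tr = time_resolved(poisson_ensemble, window=400.0, step=200.0,
                           statistic="rate")
        assert np.all(np.abs(tr.value - 20.0) < 2.0)

    def test_window_centering(self, poisson_ensemble):
        tr = time_resolved(poisson_ensemble, window=400.0, step=100.0)
        assert tr.t_center[0] == pytest.approx(200.0)
        assert tr.t_center[-1] == pytest.approx(1800.0)
        assert np.allclose(np.diff(tr.t_center), 100.0)

    def test_unknown_statistic_rejected(self, poisson_ensemble):
        with pytest.raises(ValueError):
            time_resolved(poisson_ensemble, statistic="skewness")

    def test_window_wider_than_trial_rejected(self, poisson_ensemble):
        with pytest.raises(ValueError):
            time_resolved(poisson_ensemble, window=5000.0)

    def test_trace_frame_round_trip(self, tmp_path, poisson_ensemble):
        tr = time_resolved(poisson_ensemble, window=400.0, step=200.0)
        tr.to_csv(tmp_path / "trace.csv")
        back = pd.read_csv(tmp_path / "trace.csv")
        assert np.allclose(back["value"], tr.value)
        assert list(back.columns) == ["t_center", "statistic", "value", "n"]


class TestSynchrony:
    def test_duplicated_trains_give_one(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1000.0, 200))
        times = np.concatenate([t] * 5)
        units = np.repeat(np.arange(5), len(t))
        data = SpikeData(times, units, duration=1000.0, n_units=5)
        assert synchrony_chi(data, bin_ms=20.0) == pytest.approx(1.0)

    def test_independent_trains_scale_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        n, rate, dur = 100, 20.0, 20000.0
        counts = rng.poisson(rate / 1000.0 * dur, n)
        times = np.concatenate([np.sort(rng.uniform(0, dur, c))
                                for c in counts])
        units = np.repeat(np.arange(n), counts)
        data = SpikeData(times, units, duration=dur, n_units=n)
        chi = synchrony_chi(data, bin_ms=20.0)
        assert chi == pytest.approx(1.0 / np.sqrt(n), rel=0.2)

    def test_too_few_units_rejected(self):
        data = SpikeData([1.0], [0], duration=100.0, n_units=1)
        with pytest.raises(ValueError):
            synchrony_chi(data)


class TestRateKernel:
    def test_unit_area(self):
        t, r = rate_kernel([500.0], duration=1000.0, width=50.0, dt=1.0)
        # one spike -> integral of rate (in s) equals 1
        assert np.trapezoid(r, t / 1000.0) == pytest.approx(1.0, rel=1e-6)

    def test_recovers_constant_rate(self):
        rng = np.random.default_rng(2)
        dur, rate = 50000.0, 30.0
        times = np.sort(rng.uniform(0, dur, int(rate / 1000.0 * dur)))
        t, r = rate_kernel(times, duration=dur, width=50.0)
        interior = r[1000:-1000]
        assert interior.mean() == pytest.approx(rate, rel=0.05)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            rate_kernel([1.0], duration=10.0, width=0.0)


def _make_aligned(rate_per_unit, duration, n_trials, seed):
    """Independent Poisson units with per-unit rates (spikes/s)."""
    rng = np.random.default_rng(seed)
    frames = []
    for u, rate in enumerate(rate_per_unit):
        for tr in range(n_trials):
            n = rng.poisson(rate / 1000.0 * duration)
            frames.append(pd.DataFrame({
                "unit": u, "trial": tr,
                "time": np.sort(rng.uniform(0, duration, n))}))
    events = pd.concat(frames, ignore_index=True)
    info = pd.DataFrame(index=pd.RangeIndex(n_trials))
    return TrialAlignedSpikes(events=events, trial_info=info,
                              n_units=len(rate_per_unit), t_start=0.0,
                              t_stop=duration)


class TestDeltaStats:
    def test_rate_change_detected(self):
        # 3 clusters of 5 units; cluster 0 doubles its rate when "evoked"
        cluster_of_unit = np.repeat([0, 1, 2], 5)
        spont = _make_aligned([10.0] * 15, 1000.0, 30, seed=4)
        evoked = _make_aligned([20.0] * 5 + [10.0] * 10, 1000.0, 30, seed=5)
        table = delta_stats(spont, evoked, cluster_of_unit,
                            stimulated_clusters=[0])
        dr = table.set_index(["group", "statistic"])["mean"]
        assert dr[("stimulated", "delta_rate")] > 5.0
        assert abs(dr[("non_stimulated", "delta_rate")]) < 3.0

    def test_group_sizes(self):
        cluster_of_unit = np.repeat([0, 1, 2], 5)
        spont = _make_aligned([10.0] * 15, 500.0, 20, seed=6)
        evoked = _make_aligned([10.0] * 15, 500.0, 20, seed=7)
        table = delta_stats(spont, evoked, cluster_of_unit, [0])
        n = table.set_index(["group", "statistic"])["n"]
        assert n[("stimulated", "delta_rate")] == 5
        assert n[("non_stimulated", "delta_rate")] == 10

    def test_mismatched_trials_rejected(self):
        cluster_of_unit = np.zeros(3, dtype=int)
        a = _make_aligned([10.0] * 3, 500.0, 10, seed=8)
        b = _make_aligned([10.0] * 3, 500.0, 12, seed=9)
        with pytest.raises(ValueError):
            delta_stats(a, b, cluster_of_unit, [0])


class TestRenewalConsistency:
    def test_gamma_interval_prediction(self):
        # gamma renewal: no serial correlations, limit FF = CV^2 = 1/k
        for k in (0.5, 2.0, 4.0):
            aligned = gen_gamma(100.0, k, 2_000_000.0, seed=int(k * 10))
            tau = np.diff(np.sort(
                aligned.events.loc[aligned.events["unit"] == 0, "time"]
                .to_numpy()))
            out = renewal_consistency(tau)
            assert out["cv_squared"] == pytest.approx(1.0 / k, rel=0.05)
            assert abs(out["xi"]) < 0.05
            assert out["predicted_ff"] == pytest.approx(1.0 / k, rel=0.15)
            assert not out["flagged_short"]

    def test_short_train_flagged(self):
        out = renewal_consistency(np.random.default_rng(0).exponential(
            10.0, 50), min_intervals=100)
        assert out["flagged_short"]

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            renewal_consistency([1.0, 2.0, 3.0], max_lag=10)


class TestInclusionFilter:
    @staticmethod
    def _two_condition_ensemble(low_rate):
        """Units 0 (high rate) and 1 (``low_rate``), 12 trials in each of
        2 conditions, one direction."""
        rng = np.random.default_rng(11)
        frames, info_rows = [], []
        trial = 0
        for condition in (1, 2):
            for _ in range(12):
                for u, rate in ((0, 20.0), (1, low_rate)):
                    n = rng.poisson(rate / 1000.0 * 2000.0)
                    frames.append(pd.DataFrame({
                        "unit": u, "trial": trial,
                        "time": np.sort(rng.uniform(0, 2000.0, n))}))
                info_rows.append({"condition": condition,
                                  "final_direction": 1})
                trial += 1
        events = pd.concat(frames, ignore_index=True)
        info = pd.DataFrame(info_rows)
        return TrialAlignedSpikes(events=events, trial_info=info, n_units=2,
                                  t_start=0.0, t_stop=2000.0)

    def test_low_rate_unit_dropped(self):
        aligned = self._two_condition_ensemble(low_rate=1.0)
        kept = unit_inclusion_filter(aligned)
        assert set(kept.events["unit"].unique()) == {0}

    def test_high_rate_units_kept(self):
        aligned = self._two_condition_ensemble(low_rate=20.0)
        kept = unit_inclusion_filter(aligned)
        assert set(kept.events["unit"].unique()) == {0, 1}

    def test_too_few_trials_drops_everything(self):
        aligned = self._two_condition_ensemble(low_rate=20.0)
        kept = unit_inclusion_filter(aligned, min_trials=50)
        assert len(kept.events) == 0
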