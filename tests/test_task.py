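"""Task protocol, decoder readout and decoding analysis (no heavy sims)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst
import hypothesis.extra.numpy as hnp

from eiclust import table1, table2, SpikeData
from eiclust.spikedata import TrialAlignedSpikes
from eiclust.task import (CONDITION_CUES, DecoderParams, make_task_protocol,
                          leaky_integrate, decision_variable,
                          detect_decision, decide_all_trials,
                          tune_threshold, decoding_accuracy, trial_dv,
                          PS_DELAY, PREP_MS, RS_MS, ITI_RANGE)


class TestProtocol:
    def test_condition_cue_sets(self):
        assert CONDITION_CUES[1] == [(d,) for d in range(1, 7)]
        assert CONDITION_CUES[2] == [(1, 2), (3, 4), (5, 6)]
        assert CONDITION_CUES[3] == [(6, 1, 2), (3, 4, 5)]

    def test_trial_table_invariants(self):
        spec = table2()
        table, protocol = make_task_protocol(spec, trials_per_condition=12,
                                             amplitude=0.1, seed=0)
        assert len(table) == 36
        assert np.allclose(table["PS"] - table["TS"], PS_DELAY)
        assert np.allclose(table["RS"] - table["PS"], PREP_MS)
        assert np.all(table["RS_duration"] == RS_MS)
        assert np.all((table["ITI"] >= ITI_RANGE[0])
                      & (table["ITI"] <= ITI_RANGE[1]))
        for _, row in table.iterrows():
            cued = [int(x) for x in row["cued"].split("+")]
            assert len(cued) == row["condition"]
            assert row["final_direction"] in cued
            assert tuple(cued) in CONDITION_CUES[row["condition"]]
        # one PS + one RS epoch per trial
        assert len(protocol.epochs) == 2 * len(table)

    def test_zero_amplitude_adds_no_epochs(self):
        table, protocol = make_task_protocol(table2(),
                                             trials_per_condition=6,
                                             amplitude=0.0, seed=0)
        assert len(protocol.epochs) == 0

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError):
            make_task_protocol(table2(), conditions=(4,),
                               trials_per_condition=2, seed=0)

    def test_non_task_spec_rejected(self):
        with pytest.raises(ValueError):
            make_task_protocol(table1(Q=50, J_Eplus=10.0),
                               trials_per_condition=2, seed=0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            make_task_protocol(table2(), trials_per_condition=2,
                               amplitude=-0.1, seed=0)


class TestLeakyIntegrator:
    def test_zero_counts_stay_zero(self):
        out = leaky_integrate(np.zeros((100, 6)), bin_ms=1.0, tau_I=50.0)
        assert np.all(out == 0.0)

    def test_constant_input_fixed_point(self):
        c = 3.0
        counts = np.full((5000, 1), c)
        out = leaky_integrate(counts, bin_ms=1.0, tau_I=50.0)
        expected = c / (1.0 - np.exp(-1.0 / 50.0))
        assert out[-1, 0] == pytest.approx(expected, rel=1e-6)

    def test_impulse_decays_with_tau(self):
        counts = np.zeros((200, 1))
        counts[0, 0] = 1.0
        out = leaky_integrate(counts, bin_ms=1.0, tau_I=50.0)
        assert out[50, 0] / out[0, 0] == pytest.approx(np.exp(-1.0),
                                                       rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DecoderParams(tau_I=-1.0)
        with pytest.raises(ValueError):
            DecoderParams(theta=1.5)


class TestDecisionVariable:
    def test_uniform_for_equal_inputs(self):
        dv = decision_variable(np.full((10, 6), 2.0))
        assert np.allclose(dv, 1.0 / 6.0)

    def test_single_nonzero_gives_one(self):
        I = np.zeros((3, 6))
        I[:, 2] = 5.0
        dv = decision_variable(I)
        assert np.allclose(dv[:, 2], 1.0)

    def test_zero_denominator_uniform(self):
        dv = decision_variable(np.zeros((4, 6)))
        assert np.allclose(dv, 1.0 / 6.0)

    @given(hnp.arrays(float, (7, 6),
                      elements=hst.floats(0.0, 1e6, allow_nan=False)))
    def test_normalization_property(self, I):
        dv = decision_variable(I)
        assert np.allclose(dv.sum(axis=1), 1.0)


def dv_trace(values_at, n=400, q=6):
    """DV trace over t=1..n ms built from {t: (direction0based, dv)}."""
    t = np.arange(1, n + 1, dtype=float)
    dv = np.full((n, q), 0.01)
    for tt, (d, v) in values_at.items():
        dv[tt - 1, :] = (1 - v) / (q - 1)
        dv[tt - 1, d] = v
    return t, dv


class TestDetectDecision:
    def test_no_crossing_unsuccessful(self):
        t, dv = dv_trace({})
        out = detect_decision(t, dv, 0.6, final_direction=1)
        assert out.chosen is None and out.reaction_time is None
        assert not out.success

    def test_anticipatory_rt_zero(self):
        t = np.arange(-100, 401, dtype=float)
        dv = np.full((len(t), 6), 0.05)
        dv[t <= 0, 3] = 0.9
        out = detect_decision(t, dv, 0.6, final_direction=4)
        assert out.chosen == 4 and out.reaction_time == 0.0 and out.success

    def test_first_crossing_wins(self):
        t, dv = dv_trace({50: (2, 0.9), 100: (4, 0.9)})
        out = detect_decision(t, dv, 0.6, final_direction=5)
        assert out.chosen == 3 and out.reaction_time == 50.0
        assert not out.success

    def test_tie_breaks_to_lower_index(self):
        t = np.arange(1, 401, dtype=float)
        dv = np.full((400, 6), 0.0)
        dv[99, 1] = 0.5
        dv[99, 4] = 0.5
        out = detect_decision(t, dv, 0.5, final_direction=5)
        assert out.chosen == 2

    def test_crossing_after_window_ignored(self):
        t = np.arange(1, 601, dtype=float)
        dv = np.full((600, 6), 0.05)
        dv[499, 0] = 0.95
        out = detect_decision(t, dv, 0.6, final_direction=1,
                              decision_window=400.0)
        assert out.chosen is None and not out.success


def synthetic_task_data(spec, table, rate_final=80.0, rate_back=2.0,
                        seed=0):
    """Spike data where the final cluster fires strongly from PS onward."""
    rng = np.random.default_rng(seed)
    duration = table["TS"].iloc[-1] + 2000.0 + table["ITI"].iloc[-1]
    size = spec.N_E // spec.scaling.Q
    times, units = [], []
    # low background on one unit of each cluster
    for q in range(spec.scaling.Q):
        n = rng.poisson(rate_back / 1000.0 * duration)
        times.append(np.sort(rng.uniform(0, duration, n)))
        units.append(np.full(n, q * size))
    for _, row in table.iterrows():
        q = int(row["final_direction"]) - 1
        member = q * size + 1
        n = rng.poisson(rate_final / 1000.0 * (row["RS"] + 400.0
                                               - row["PS"]))
        times.append(np.sort(rng.uniform(row["PS"], row["RS"] + 400.0, n)))
        units.append(np.full(n, member))
    times = np.concatenate(times)
    units = np.concatenate(units)
    meta = pd.DataFrame({
        "population": ["E"] * spec.N_E + ["I"] * spec.N_I,
        "cluster": np.r_[np.arange(spec.N_E) // size,
                         np.arange(spec.N_I) // (spec.N_I
                                                 // spec.scaling.Q)]})
    return SpikeData(times, units, duration=duration, n_units=spec.N,
                     units_meta=meta)


@pytest.fixture(scope="module")
def separable_task():
    spec = table2()
    table, _ = make_task_protocol(spec, conditions=(1,),
                                  trials_per_condition=12,
                                  amplitude=0.0, seed=3)
    data = synthetic_task_data(spec, table, seed=4)
    return spec, table, data


class TestReadoutPipeline:
    def test_decisions_all_correct(self, separable_task):
        spec, table, data = separable_task
        dec = decide_all_trials(data, spec, table,
                                DecoderParams(theta=0.6))
        assert dec["success"].all()

    def test_trial_dv_window(self, separable_task):
        spec, table, data = separable_task
        t, dv = trial_dv(data, spec, table.iloc[0], DecoderParams())
        assert t[0] == pytest.approx(-PREP_MS + 1.0)
        assert t[-1] == pytest.approx(RS_MS)
        assert np.allclose(dv.sum(axis=1), 1.0)

    def test_tune_threshold_saturates(self, separable_task):
        spec, table, data = separable_task
        theta, acc, tab = tune_threshold(data, spec, table,
                                         grid=[0.5, 0.7, 0.9])
        assert acc == 1.0
        assert set(tab["theta"]) == {0.5, 0.7, 0.9}

    def test_unreachable_threshold_zero_accuracy(self, separable_task):
        spec, table, data = separable_task
        theta, acc, _ = tune_threshold(data, spec, table, grid=[0.9999])
        assert acc == 0.0

    def test_empty_grid_rejected(self, separable_task):
        spec, table, data = separable_task
        with pytest.raises(ValueError):
            tune_threshold(data, spec, table, grid=[])


class TestDecodingAccuracy:
    @staticmethod
    def _aligned(separation, n_trials=30, seed=0):
        """6 units, direction d makes unit d-1 fire at base+separation."""
        rng = np.random.default_rng(seed)
        frames, rows = [], []
        for tr in range(n_trials):
            d = tr % 6 + 1
            rows.append({"condition": 1, "final_direction": d})
            for u in range(6):
                rate = 10.0 + (separation if u == d - 1 else 0.0)
                n = rng.poisson(rate / 1000.0 * 400.0)
                frames.append(pd.DataFrame({
                    "unit": u, "trial": tr,
                    "time": np.sort(rng.uniform(0, 400.0, n))}))
        return TrialAlignedSpikes(
            events=pd.concat(frames, ignore_index=True),
            trial_info=pd.DataFrame(rows), n_units=6,
            t_start=0.0, t_stop=400.0)

    def test_separable_counts_decode_perfectly(self):
        acc = decoding_accuracy(self._aligned(200.0), window=400.0,
                                step=400.0)
        assert acc[1].value[0] == pytest.approx(1.0, abs=0.05)

    def test_uninformative_counts_at_chance(self):
        acc = decoding_accuracy(self._aligned(0.0), window=400.0,
                                step=400.0)
        assert acc[1].value[0] == pytest.approx(1.0 / 6.0, abs=0.2)
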