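"""Baseline stats, dF, k-sigma classification, ratio traces and their invariants."""

import numpy as np
import pytest

import clquant as cq
from clquant.errors import DataError
from clquant.traces import false_positive_bound


def _trace(values, dt=0.5, cell_id=""):
    values = np.asarray(values, dtype=float)
    return cq.FluorescenceTrace(np.arange(values.size) * dt, values, cell_id)


class TestBaselineStats:
    def test_constant_baseline(self):
        base = cq.baseline_stats(_trace([100.0] * 20))
        assert base.mean == 100.0 and base.sd == 0.0

    def test_alternating_baseline_sample_sd(self):
        # ten frames alternating 99/101: mean 100, sample SD sqrt(10/9)
        base = cq.baseline_stats(_trace([99.0, 101.0] * 10))
        assert base.mean == 100.0
        assert base.sd == pytest.approx(1.054, abs=1e-3)

    def test_short_trace_rejected(self):
        with pytest.raises(DataError):
            cq.baseline_stats(_trace([100.0] * 5))


class TestDeltaF:
    def test_at_baseline_is_zero_and_double_is_plus_100(self):
        trace = _trace([100.0] * 10 + [100.0, 200.0])
        dff = cq.delta_f(trace, cq.baseline_stats(trace))
        assert dff[10] == 0.0 and dff[11] == 100.0

    def test_noiseless_synthetic_efflux_cell_matches_generator_truth(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(40), seed=9)
        kin = cq.KineticsParams(noise_sd=0.0)
        traces, protocol, truth = cq.gen_stimulation_traces(
            cells, kinetics=kin, seed=9
        )
        t = traces["time_s"].to_numpy()
        for rec in truth["cells"]:
            trace = cq.FluorescenceTrace(t, traces[rec["cell_id"]].to_numpy())
            dff = cq.delta_f(trace, cq.baseline_stats(trace))
            extremum = dff[np.argmax(np.abs(dff))]
            # truth is evaluated at the analytic stimulus end; the sampled
            # extremum sits one frame earlier, hence the 2% headroom
            assert extremum == pytest.approx(
                rec["attained_delta_f_pct"], rel=0.02, abs=1e-9
            )


class TestClassifyResponse:
    def test_flat_trace_is_none(self, flat_trace):
        base = cq.baseline_stats(flat_trace)
        call = cq.classify_response(flat_trace, base, (10.0, 20.0))
        assert call.direction == "none"

    @pytest.mark.parametrize("sign, expected", [(+1, "efflux"), (-1, "influx")])
    def test_six_sigma_step_is_called(self, sign, expected):
        rng = np.random.default_rng(3)
        values = 100.0 + rng.normal(0, 1.0, 60)
        values[30:] += sign * 6.0  # step of 6 baseline SDs
        trace = _trace(values)
        base = cq.baseline_stats(trace)
        call = cq.classify_response(trace, base, (15.0, 25.0), k=4.0)
        assert call.direction == expected

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        values = 100.0 + rng.normal(0, 1.0, 60)
        values[30:] += 8.0
        for scale in (0.01, 1.0, 250.0):
            trace = _trace(values * scale)
            call = cq.classify_response(
                trace, cq.baseline_stats(trace), (15.0, 25.0)
            )
            assert call.direction == "efflux"
            assert call.amplitude_pct == pytest.approx(
                cq.classify_response(
                    _trace(values), cq.baseline_stats(_trace(values)), (15.0, 25.0)
                ).amplitude_pct
            )

    def test_truncation_outside_windows_does_not_change_call(self):
        rng = np.random.default_rng(5)
        values = 100.0 + rng.normal(0, 1.0, 120)
        values[40:60] += 7.0
        full = _trace(values)
        call_full = cq.classify_response(full, cq.baseline_stats(full), (20.0, 30.0))
        truncated = full.window(0.0, 45.0)  # drops frames after window + tail
        call_trunc = cq.classify_response(
            truncated, cq.baseline_stats(truncated), (20.0, 30.0)
        )
        assert call_full.direction == call_trunc.direction
        assert call_full.amplitude_pct == call_trunc.amplitude_pct

    def test_empty_window_rejected(self, flat_trace):
        with pytest.raises(DataError):
            cq.classify_response(
                flat_trace, cq.baseline_stats(flat_trace), (500.0, 510.0)
            )

    def test_false_positive_rate_bounded(self):
        # modest-n version of the flat-trace control; the large-n run lives
        # in the acceptance suite
        rng = np.random.default_rng(6)
        t = np.arange(50) * 0.5
        data = 100.0 * (1 + 0.01 * rng.standard_normal((2000, 50)))
        fp = 0
        for row in data:
            trace = cq.FluorescenceTrace(t, row)
            call = cq.classify_response(trace, cq.baseline_stats(trace), (10.0, 15.0))
            fp += call.direction != "none"
        n_window = int(np.sum((t >= 10.0) & (t <= 25.0)))
        assert fp / 2000 <= false_positive_bound(4.0, 10, n_window)


class TestRatioTrace:
    def test_equal_channels_give_unit_ratio(self):
        f = _trace([50.0] * 20)
        ratio = cq.ratio_trace(f, f)
        assert np.allclose(ratio.values, 1.0)
        assert ratio.channel == "ratio"

    def test_linear_in_numerator(self):
        f340 = _trace(np.linspace(40, 60, 20))
        f380 = _trace([100.0] * 20)
        doubled = _trace(2 * f340.values)
        assert np.allclose(
            cq.ratio_trace(doubled, f380).values,
            2 * cq.ratio_trace(f340, f380).values,
        )

    def test_misaligned_time_bases_rejected(self):
        f340 = _trace([50.0] * 20, dt=0.5)
        f380 = cq.FluorescenceTrace(np.arange(20) * 0.5 + 0.4, [100.0] * 20)
        with pytest.raises(DataError):
            cq.ratio_trace(f340, f380)

    def test_nonpositive_denominator_rejected(self):
        f340 = _trace([50.0] * 20)
        bad = _trace([100.0] * 19 + [0.0])
        with pytest.raises(DataError):
            cq.ratio_trace(f340, bad)

    def test_synthetic_transient_peak_matches_truth(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(15), seed=13)
        kin = cq.KineticsParams(noise_sd=0.0)
        f340_df, f380_df, protocol, truth = cq.gen_fura_traces(
            cells, kinetics=kin, seed=13
        )
        t = f340_df["time_s"].to_numpy()
        stim = next(s for s in protocol if s.stimulus)
        for cell_id, amp in truth["amplitudes"].items():
            ratio = cq.ratio_trace(
                cq.FluorescenceTrace(t, f340_df[cell_id].to_numpy()),
                cq.FluorescenceTrace(t, f380_df[cell_id].to_numpy()),
            )
            base = cq.baseline_stats(ratio)
            measured = cq.response_amplitude(ratio, base, (stim.start_s, stim.end_s))
            assert measured == pytest.approx(amp, rel=0.01)


class TestResponseAmplitude:
    def test_flat_ratio_is_zero(self, flat_trace):
        base = cq.baseline_stats(flat_trace)
        assert cq.response_amplitude(flat_trace, base, (10.0, 20.0)) == pytest.approx(
            0.0
        )

    def test_shift_invariance(self):
        values = np.concatenate([np.full(20, 1.0), np.full(20, 1.4)])
        a = _trace(values)
        b = _trace(values + 3.0)
        amp_a = cq.response_amplitude(a, cq.baseline_stats(a), (10.0, 20.0))
        amp_b = cq.response_amplitude(b, cq.baseline_stats(b), (10.0, 20.0))
        assert amp_a == pytest.approx(amp_b)

    def test_low_chloride_population_has_smaller_amplitudes(self):
        wt = cq.gen_cell_population(cq.PopulationParams.wild_type(300), seed=17)
        ko = cq.gen_cell_population(cq.PopulationParams.nkcc1_ko(300), seed=18)
        _, _, _, t_wt = cq.gen_fura_traces(wt, seed=17)
        _, _, _, t_ko = cq.gen_fura_traces(ko, seed=18)
        mean_wt = np.mean(list(t_wt["amplitudes"].values()))
        mean_ko = np.mean(list(t_ko["amplitudes"].values()))
        # generator default amplification targets a ~38% reduction
        assert mean_ko / mean_wt == pytest.approx(0.615, abs=0.05)


class TestViabilityFilter:
    def _ratio_with_step(self, amplitude):
        values = np.full(60, 1.0)
        values[40:50] += amplitude
        return _trace(values)

    def test_unresponsive_cell_dropped(self):
        ratio = self._ratio_with_step(0.0)
        base = cq.baseline_stats(ratio)
        assert not cq.viability_filter(ratio, base, (20.0, 25.0), min_amplitude=0.1)

    def test_responsive_cell_kept(self):
        ratio = self._ratio_with_step(0.5)
        base = cq.baseline_stats(ratio)
        assert cq.viability_filter(ratio, base, (20.0, 25.0), min_amplitude=0.1)

    def test_zero_threshold_keeps_everything(self):
        ratio = self._ratio_with_step(0.0)
        base = cq.baseline_stats(ratio)
        assert cq.viability_filter(ratio, base, (20.0, 25.0), min_amplitude=0.0)
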