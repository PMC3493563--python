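"""Generator contracts: determinism, truncation, forward models, directionality."""

import numpy as np
import pandas as pd
import pytest

import clquant as cq
from clquant.calibration import CalibrationStep
from clquant.errors import ConfigurationError
from clquant.synth import _quench


class TestCellPopulation:
    def test_seeded_determinism(self):
        a = cq.gen_cell_population(cq.PopulationParams.wild_type(100), seed=42)
        b = cq.gen_cell_population(cq.PopulationParams.wild_type(100), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = cq.gen_cell_population(cq.PopulationParams.wild_type(100), seed=42)
        b = cq.gen_cell_population(cq.PopulationParams.wild_type(100), seed=43)
        assert not np.allclose(a.cl_i_mM, b.cl_i_mM)

    def test_large_sample_mean_hits_target(self):
        pop = cq.gen_cell_population(cq.PopulationParams.wild_type(10_000), seed=0)
        assert pop.cl_i_mM.mean() == pytest.approx(34.1, rel=0.01)

    def test_truncation_respected(self):
        params = cq.PopulationParams.wild_type(5000)
        pop = cq.gen_cell_population(params, seed=1)
        assert pop.cl_i_mM.min() >= params.lower_trunc
        assert pop.cl_i_mM.max() <= params.upper_trunc
        assert pop.ksv_per_M.min() > 0

    def test_degenerate_sd_gives_constant_population(self):
        params = cq.PopulationParams(mean_cl=20.0, sd_cl=0.0)
        pop = cq.gen_cell_population(params, seed=0)
        assert np.all(pop.cl_i_mM == 20.0)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ConfigurationError):
            cq.PopulationParams(lower_trunc=50.0, upper_trunc=40.0)


class TestCalibrationTraces:
    def test_noiseless_plateaus_equal_forward_model(self):
        cells = pd.DataFrame(
            {"cell_id": ["c0"], "cl_i_mM": [34.1], "ksv_per_M": [14.4], "f0": [100.0]}
        )
        kin = cq.KineticsParams(noise_sd=0.0)
        traces, protocol, _ = cq.gen_calibration_traces(cells, kinetics=kin, seed=0)
        expected = {0.0: 100.0, 20.0: 77.64, 40.0: 63.45, 60.0: 53.65}
        for step in protocol:
            if step.cl_mM is None:
                continue
            tail = traces[
                (traces.time_s >= step.end_s - 60.0) & (traces.time_s < step.end_s)
            ]["c0"]
            assert tail.mean() == pytest.approx(expected[step.cl_mM], abs=5e-3)

    def test_protocol_steps_last_ten_minutes(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(2), seed=0)
        _, protocol, _ = cq.gen_calibration_traces(cells, seed=0)
        cal = [s for s in protocol if s.cl_mM is not None]
        assert all(s.end_s - s.start_s == 600.0 for s in cal)

    def test_zero_step_required(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(2), seed=0)
        with pytest.raises(ConfigurationError):
            cq.gen_calibration_traces(cells, conc_steps=(20.0, 40.0), seed=0)

    def test_seeded_determinism(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(3), seed=7)
        a, _, _ = cq.gen_calibration_traces(cells, seed=7)
        b, _, _ = cq.gen_calibration_traces(cells, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_forward_inverse_consistency(self, wt_cells, noiseless_kinetics):
        traces, protocol, _ = cq.gen_calibration_traces(
            wt_cells, kinetics=noiseless_kinetics, seed=11
        )
        steps = [
            CalibrationStep(s.cl_mM, s.start_s, s.end_s)
            for s in protocol
            if s.cl_mM is not None
        ]
        estimates = cq.calibrate_cells(traces, steps, (0.0, 120.0))
        rel_err = [
            abs(e.cl_i_mM - c) / c
            for e, c in zip(estimates, wt_cells.cl_i_mM)
        ]
        assert max(rel_err) < 1e-6


class TestStimulationTraces:
    def test_cell_at_equilibrium_is_flat(self, ctx):
        crit = cq.critical_cli(ctx)
        cells = pd.DataFrame(
            {"cell_id": ["c0"], "cl_i_mM": [crit], "ksv_per_M": [14.4], "f0": [100.0]}
        )
        kin = cq.KineticsParams(noise_sd=0.0)
        traces, _, truth = cq.gen_stimulation_traces(cells, ctx=ctx, kinetics=kin)
        assert np.ptp(traces["c0"].to_numpy()) == pytest.approx(0.0, abs=1e-9)
        assert truth["cells"][0]["direction"] == "none"

    def test_directional_consistency(self, ctx):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(60), seed=23)
        kin = cq.KineticsParams(noise_sd=0.0)
        traces, protocol, truth = cq.gen_stimulation_traces(
            cells, ctx=ctx, kinetics=kin, seed=23
        )
        crit = truth["critical_cl_mM"]
        stim = next(s for s in protocol if s.stimulus)
        t = traces["time_s"].to_numpy()
        in_stim = (t >= stim.start_s) & (t < stim.end_s)
        for _, cell in cells.iterrows():
            rest = traces[cell.cell_id].to_numpy()[0]
            change = traces[cell.cell_id].to_numpy()[in_stim][-1] - rest
            assert np.sign(change) == np.sign(cell.cl_i_mM - crit)

    def test_efflux_fraction_matches_population_above_critical(self, ctx):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(4000), seed=29)
        _, _, truth = cq.gen_stimulation_traces(cells, ctx=ctx, seed=29)
        frac = truth["efflux_fraction"]
        assert frac == pytest.approx(
            np.mean(cells.cl_i_mM > cq.critical_cli(ctx)), abs=1e-12
        )
        # the untreated population keeps roughly two thirds above critical
        assert 0.55 < frac < 0.85

    def test_low_bath_chloride_increases_mean_response(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(200), seed=31)
        kin = cq.KineticsParams(noise_sd=0.0)
        high = cq.EquilibriumContext(cl_out_mM=148.0, rmp_mV=-54.0)
        low = cq.EquilibriumContext(cl_out_mM=6.0, rmp_mV=-54.0)
        _, _, t_high = cq.gen_stimulation_traces(cells, ctx=high, kinetics=kin)
        _, _, t_low = cq.gen_stimulation_traces(cells, ctx=low, kinetics=kin)
        mean_high = np.mean([c["plateau_delta_f_pct"] for c in t_high["cells"]])
        mean_low = np.mean([c["plateau_delta_f_pct"] for c in t_low["cells"]])
        assert mean_low > mean_high


class TestFuraTraces:
    def test_zero_amplitude_is_flat_ratio(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(5), seed=3)
        fura = cq.FuraParams(base_amplitude=0.0, amplification=0.0)
        kin = cq.KineticsParams(noise_sd=0.0)
        f340, f380, _, _ = cq.gen_fura_traces(cells, fura=fura, kinetics=kin, seed=3)
        ratio = f340.iloc[:, 1].to_numpy() / f380.iloc[:, 1].to_numpy()
        assert np.ptp(ratio) == pytest.approx(0.0, abs=1e-12)

    def test_f380_never_nonpositive(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(50), seed=5)
        kin = cq.KineticsParams(noise_sd=0.5)  # absurd noise to stress the floor
        _, f380, _, _ = cq.gen_fura_traces(cells, kinetics=kin, seed=5)
        assert (f380.iloc[:, 1:].to_numpy() > 0).all()

    def test_seeded_determinism(self):
        cells = cq.gen_cell_population(cq.PopulationParams.wild_type(4), seed=9)
        a340, a380, _, _ = cq.gen_fura_traces(cells, seed=9)
        b340, b380, _, _ = cq.gen_fura_traces(cells, seed=9)
        pd.testing.assert_frame_equal(a340, b340)
        pd.testing.assert_frame_equal(a380, b380)


class TestDrinkingSessions:
    def test_low_dose_expected_eir_is_baseline(self):
        params = cq.BehaviorParams(intake_noise_cv=0.0)
        sessions, truth = cq.gen_drinking_sessions(
            params, concentrations=(1e-6, 1.0, 3.0, 10.0), seed=0
        )
        eirs = sessions[sessions.concentration_uM == 1e-6]
        ratio = (eirs.intake2_ul / eirs.intake1_ul).mean()
        assert ratio == pytest.approx(params.baseline_eir, rel=1e-6)

    def test_at_ec50_expected_eir_is_half_baseline(self):
        params = cq.BehaviorParams(intake_noise_cv=0.0)
        sessions, _ = cq.gen_drinking_sessions(
            params, concentrations=(params.ec50, 2 * params.ec50, 1.0, 3.0), seed=0
        )
        at_ec50 = sessions[sessions.concentration_uM == params.ec50]
        ratio = (at_ec50.intake2_ul / at_ec50.intake1_ul).mean()
        assert ratio == pytest.approx(params.baseline_eir / 2, rel=1e-9)

    def test_seeded_determinism(self):
        a, _ = cq.gen_drinking_sessions(cq.BehaviorParams.wild_type(), seed=12)
        b, _ = cq.gen_drinking_sessions(cq.BehaviorParams.wild_type(), seed=12)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            cq.gen_drinking_sessions(
                cq.BehaviorParams.wild_type(), concentrations=(0.0, 1.0), seed=0
            )


class TestQuenchModel:
    def test_forward_values_by_hand(self):
        f0 = np.array([100.0])
        ksv = np.array([14.4])
        for conc, expected in [(0.0, 100.0), (20.0, 77.64), (40.0, 63.45), (60.0, 53.65)]:
            assert _quench(np.array([conc]), f0, ksv)[0] == pytest.approx(
                expected, abs=5e-3
            )
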