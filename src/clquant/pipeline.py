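"""End-to-end pipeline: simulate -> calibrate -> classify -> predict -> summarize.

`run_pipeline` drives every stage on one seeded synthetic dataset and
writes all intermediates (trace CSVs, protocol YAML, per-cell fit CSV,
response-call CSV, behavior tables, a JSON report and a run manifest with
a config hash) to an output directory. Identical config + seed gives
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .behavior import avoidance_curve, session_ratios
from .calibration import CalibrationStep, calibrate_cells, summarize_population
from .equilibrium import EquilibriumContext, critical_cli, efflux_fraction
from .errors import ConfigurationError
from .synth import (
    BehaviorParams,
    KineticsParams,
    PopulationParams,
    gen_calibration_traces,
    gen_cell_population,
    gen_drinking_sessions,
    gen_stimulation_traces,
)
from .traces import FluorescenceTrace, baseline_stats, classify_response

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class ClassifierConfig:
    k: float = 4.0
    n_baseline: int = 10
    tail_s: float = 10.0


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full synthetic run.

    Defaults mirror the measurement conditions the package models:
    calibration solutions 0/20/40/60 mM, bath chloride 151 mM, membrane
    potential -54 mV, 10-frame baselines, 4-sigma response threshold.
    """

    seed: int = 0
    population: PopulationParams = field(default_factory=PopulationParams.wild_type)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams.wild_type)
    cl_out_mM: float = 151.0
    rmp_mV: float = -54.0
    decade_slope_mV: float = 58.0
    calibration_steps_mM: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    @property
    def context(self) -> EquilibriumContext:
        return EquilibriumContext(
            cl_out_mM=self.cl_out_mM,
            rmp_mV=self.rmp_mV,
            decade_slope_mV=self.decade_slope_mV,
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from nested plain dicts (e.g. parsed YAML); unknown keys are rejected."""
        raw = dict(raw)
        nested = {
            "population": PopulationParams,
            "kinetics": KineticsParams,
            "behavior": BehaviorParams,
            "classifier": ClassifierConfig,
        }
        kwargs = {}
        for key, typ in nested.items():
            if key in raw:
                sub = raw.pop(key)
                unknown = set(sub) - set(typ.__dataclass_fields__)
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in {key!r}: {sorted(unknown)}"
                    )
                kwargs[key] = typ(**sub)
        if "calibration_steps_mM" in raw:
            kwargs["calibration_steps_mM"] = tuple(raw.pop("calibration_steps_mM"))
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **kwargs)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on one seeded synthetic dataset; return the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = config.context

    # simulate
    cells = gen_cell_population(config.population, seed=config.seed)
    cal_traces, cal_protocol, cal_truth = gen_calibration_traces(
        cells,
        conc_steps=config.calibration_steps_mM,
        kinetics=config.kinetics,
        seed=config.seed,
    )
    stim_traces, stim_protocol, stim_truth = gen_stimulation_traces(
        cells, ctx=ctx, kinetics=config.kinetics, seed=config.seed
    )
    sessions, behavior_truth = gen_drinking_sessions(
        config.behavior, genotype="WT", seed=config.seed
    )
    io.write_trace_csv(cal_traces, outdir / "calibration_mqae.csv")
    io.write_protocol(cal_protocol, outdir / "calibration_protocol.yaml")
    io.write_trace_csv(stim_traces, outdir / "stimulation_mqae.csv")
    io.write_protocol(stim_protocol, outdir / "stimulation_protocol.yaml")
    io.write_sessions_csv(sessions, outdir / "drinking_sessions.csv")
    io.write_json(
        {"calibration": cal_truth, "stimulation": stim_truth, "behavior": behavior_truth},
        outdir / "ground_truth.json",
    )

    # calibrate
    steps = [
        CalibrationStep(s.cl_mM, s.start_s, s.end_s)
        for s in cal_protocol
        if s.cl_mM is not None
    ]
    rest = next(s for s in cal_protocol if s.label == "rest")
    estimates = calibrate_cells(cal_traces, steps, (rest.start_s, rest.end_s))
    pd.DataFrame(
        {
            "cell_id": [e.cell_id for e in estimates],
            "f0": [e.fit.f0 for e in estimates],
            "ksv_per_M": [e.fit.ksv_per_M for e in estimates],
            "r2": [e.fit.r_squared for e in estimates],
            "cl_i_mM": [e.cl_i_mM for e in estimates],
            "flag": [e.quality_flag for e in estimates],
        }
    ).to_csv(outdir / "calibration_fits.csv", index=False, float_format=io.FLOAT_FORMAT)
    population = summarize_population(estimates)

    # classify
    stim_step = next(s for s in stim_protocol if s.stimulus)
    time_s = stim_traces["time_s"].to_numpy()
    calls = []
    for cell_id in (c for c in stim_traces.columns if c != "time_s"):
        trace = FluorescenceTrace(time_s, stim_traces[cell_id].to_numpy(), cell_id)
        base = baseline_stats(trace, n_frames=config.classifier.n_baseline)
        calls.append(
            classify_response(
                trace,
                base,
                (stim_step.start_s, stim_step.end_s),
                k=config.classifier.k,
                tail_s=config.classifier.tail_s,
            )
        )
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "direction": [c.direction for c in calls],
            "amplitude_pct": [c.amplitude_pct for c in calls],
            "threshold_pct": [c.threshold_pct for c in calls],
            "window_start_s": [c.window[0] for c in calls],
            "window_end_s": [c.window[1] for c in calls],
        }
    ).to_csv(outdir / "response_calls.csv", index=False, float_format=io.FLOAT_FORMAT)
    observed_efflux = sum(c.direction == "efflux" for c in calls) / len(calls)

    # equilibrium prediction from the calibrated population
    predicted_efflux = efflux_fraction(population.values, ctx)

    # behavior
    curve = avoidance_curve(sessions)
    session_ratios(sessions[sessions["concentration_uM"] > 0]).to_csv(
        outdir / "eir_long.csv", index=False, float_format=io.FLOAT_FORMAT
    )

    report = {
        "n_cells": int(len(cells)),
        "population_mean_cl_mM": population.mean,
        "population_sem_cl_mM": population.sem,
        "population_n": population.n,
        "critical_cl_mM": critical_cli(ctx),
        "predicted_efflux_fraction": predicted_efflux,
        "observed_efflux_fraction": observed_efflux,
        "generator_efflux_fraction": stim_truth["efflux_fraction"],
        "avoidance_ec50_uM": curve.ec50,
        "avoidance_converged": curve.converged,
    }
    io.write_json(report, outdir / "report.json")
    from . import __version__

    io.write_json(
        {"config_hash": config.hash(), "seed": config.seed, "clquant_version": __version__},
        outdir / "manifest.json",
    )
    return report
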