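"""Per-cell Stern-Volmer calibration on synthetic double-ionophore traces.

Generates a 200-cell population with known [Cl-]i and quenching constants,
simulates the 0/20/40/60 mM calibration protocol with 1% frame noise, then
runs plateau detection, per-cell Stern-Volmer fits and resting-chloride
estimation, and compares the recovered population to the ground truth.
"""

import numpy as np

import clquant as cq
from clquant.calibration import CalibrationStep

SEED = 7

cells = cq.gen_cell_population(cq.PopulationParams.wild_type(200), seed=SEED)
traces, protocol, truth = cq.gen_calibration_traces(cells, seed=SEED)
print(f"simulated {len(cells)} cells, {len(traces)} frames "
      f"({traces.time_s.iloc[-1]/60:.0f} min protocol)")

steps = [
    CalibrationStep(s.cl_mM, s.start_s, s.end_s)
    for s in protocol
    if s.cl_mM is not None
]
estimates = cq.calibrate_cells(traces, steps, rest_window=(0.0, 120.0))
summary = cq.summarize_population(estimates)

mean_ksv = np.mean([e.fit.ksv_per_M for e in estimates])
print(f"mean fitted Ksv : {mean_ksv:.2f} M^-1  (true mean "
      f"{cells.ksv_per_M.mean():.2f}, population target 14.4)")
print(f"population [Cl-]i: {summary.mean:.1f} +/- {summary.sem:.1f} mM "
      f"(mean +/- SEM, n = {summary.n}; target 34.1)")
print(f"excluded cells   : {summary.n_excluded} (clamped or low r^2)")
print(
    "-> the calibration stage inverts the quenching relation F0/F = 1 + Ksv*[Cl-] "
    "per cell; recovered means sit on the generator's targets within sampling error."
)
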