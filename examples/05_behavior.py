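"""Brief-access drinking avoidance: EIR, per-genotype curves, genotype shift.

Simulates drinking sessions for a wild-type and a knockout cohort (11 mice
each, capsaicin 1-300 uM), computes Exposure Intake Ratios, fits the
concentration-avoidance curve per genotype and reports the log10 shift
between their midpoints.
"""

import clquant as cq

SEED = 7

wt_sessions, wt_truth = cq.gen_drinking_sessions(
    cq.BehaviorParams.wild_type(), genotype="WT", seed=SEED
)
ko_sessions, ko_truth = cq.gen_drinking_sessions(
    cq.BehaviorParams.nkcc1_ko(), genotype="KO", seed=SEED
)

for sessions, truth in [(wt_sessions, wt_truth), (ko_sessions, ko_truth)]:
    curve = cq.avoidance_curve(sessions)
    print(f"{curve.genotype}: fitted avoidance EC50 = {curve.ec50:.2f} uM "
          f"(generator truth {truth['ec50_uM']})")
    print(curve.table.to_string(index=False,
                                formatters={"mean_eir": "{:.3f}".format,
                                            "sem_eir": "{:.3f}".format}))

wt_curve = cq.avoidance_curve(wt_sessions)
ko_curve = cq.avoidance_curve(ko_sessions)
shift = cq.curve_shift(wt_curve, ko_curve)
print(f"rightward shift KO vs WT: {shift:.2f} log10 units "
      f"(truth log10(17.3/6.4) = 0.43)")
print(
    "-> an EIR of 1 means the mouse drank as much adulterated water as plain "
    "water; the knockout curve sits to the right, i.e. higher concentrations "
    "are needed for the same avoidance. Note a single 11-mouse cohort carries "
    "~11% sampling error on the fitted EC50."
)
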