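# Methods

`clquant` quantifies intracellular chloride and its functional consequences
in sensory neurons from fluorescence-imaging time series, and validates
every analysis stage against seeded synthetic data with known ground truth.
This note documents the models, the defaults and why they were chosen, and
what the synthetic generators do and do not emulate.

## Models and procedures

### Stern-Volmer calibration

The chloride-sensitive dye (MQAE) is quenched collisionally, so

F0 / F = 1 + Ksv · [Cl⁻],

with F0 the fluorescence at 0 mM chloride and Ksv the Stern-Volmer constant
(M⁻¹). In a double-ionophore calibration the cytosolic chloride is clamped
to a series of bath concentrations (default 0, 20, 40, 60 mM), each held
until the fluorescence plateaus (default 10 min/step). Per cell:

1. the plateau of each step is the mean over the last `plateau_frac`
   (default 0.2) of the step's frames; a step whose tail still drifts more
   than `slope_tol` (default 5·10⁻⁴ relative units per frame) is flagged
   unsteady;
2. F0 is the measured 0 mM plateau, and Ksv is the slope of the
   through-origin regression of (F0/F − 1) on concentration in molar. The
   regression is through the origin because F0 is *defined* as the measured
   0 mM fluorescence, not a free intercept. The reported r² is the
   uncentered coefficient of the through-origin model;
3. resting chloride is read off the resting-segment plateau via
   [Cl⁻]i = (F0/F_rest − 1)/Ksv. Raw negative estimates — expected for
   noisy cells near 0 mM — clamp to 0 with flag `clamped` rather than
   erroring; fits with r² < 0.9 flag `low_r2`. Both flags exclude a cell
   from population summaries (mean ± SEM over `ok` cells) but are counted.
   The r² gate is a package default; no per-cell QC rule is standard for
   this assay.

Concentrations are converted from mM to M exactly once, inside the fit and
the inverse; a useful anchor is that 14.4 M⁻¹ · 34.1 mM = 0.491 of
quenching ratio minus one.

### Nernst equilibrium

For chloride (valence −1), E_Cl = s · log10([Cl⁻]i/[Cl⁻]o) with decade
slope s, and the *critical* intracellular concentration at which E_Cl
equals the resting membrane potential (RMP) is
[Cl⁻]i* = [Cl⁻]o · 10^(RMP/s). Cells strictly above it lose chloride
(depolarizing efflux) when a chloride conductance opens; the boundary cell
has zero driving force and is classified non-efflux.

Two slope conventions are supported: the default fixed 58.0 mV/decade (the
rounded room-temperature constant; at [Cl⁻]o = 151 mM and RMP = −54 mV it
gives the commonly quoted 17.7 mM critical level and −61.4 mV for a
13.2 mM cell) and the physically exact ln(10)·R·T/F
(58.56 mV/decade at 22 °C, shifting the critical level to ~18.1 mM). The
fixed constant is the default so that the headline numbers are reproduced
exactly; the temperature-derived mode is one classmethod away.

The efflux-competent fraction of a population is computed empirically
(fraction of samples strictly above critical) and in closed form for a
Gaussian population, Φ((mean − critical)/sd); the Monte-Carlo estimate
converges to the closed form.

### Response classification

Baselines are the mean and sample SD of the first 10 pre-stimulus frames.
ΔF is expressed in percent of the baseline mean, which makes classification
invariant under rescaling a trace. The response amplitude is the signed ΔF
extremum within the stimulus window plus a 10 s tail (the window is a
package choice; only the threshold rule is canonical). A call is

* efflux if amplitude > +k·SD (k = 4 by default),
* influx if amplitude < −k·SD,
* none otherwise,

with the MQAE sign convention (fluorescence up = chloride down = efflux)
fixed in exactly one place. Noiseless traces would make the threshold zero,
so the SD is floored at 10⁻⁶ of the baseline mean.

Because the baseline mean and SD are estimated from 10 frames, the
per-frame statistic under pure noise is Student-t with 9 degrees of
freedom scaled by √(1 + 1/10), not Gaussian. The analytic false-positive
bound exposed as `false_positive_bound(k, n_baseline, n_window)` is the
Bonferroni bound with that t tail; it reduces to the Gaussian
n_window·2Φ(−k) as the baseline grows. The empirical false-positive rate
on flat noisy traces sits below this bound (≈8% vs bound ≈12% for a
30-frame window at k = 4 — the 4σ label is nominal; the effective per-frame
tail is heavier because the SD itself is noisy).

### Dose-response fitting

Single-site Hill curves: r(c) = bottom + (top − bottom)/(1 + (EC50/c)^n)
for activation, the mirrored falling form with (c/IC50)^n for inhibition.
Fitting is nonlinear least squares on (log10 EC50, n, top, bottom) — the
log parameterization conditions the problem and makes the fit exactly
scale-equivariant — with bounds EC50 ∈ [min(c)/100, max(c)·100],
n ∈ (0, 10]. Initialization: EC50 at the geometric mean of the two doses
bracketing the half-range response, n = 1, top/bottom at the response
extremes. Standard errors are asymptotic (Jacobian covariance), with the
EC50 error delta-transformed from the log scale. Flat data raise a
degenerate-fit error; non-convergence is flagged, not raised. Optional
1/sem² weighting is available when per-point SEMs exist.

### Drinking avoidance

The Exposure Intake Ratio (EIR) is the 2nd-exposure intake divided by the
1st-exposure intake of the same mouse; sessions with zero first intake are
excluded with a logged reason. The concentration-avoidance curve fits the
falling Hill form to the *mean* EIR per concentration (per-mouse EIRs are
also emitted as a tidy table for external mixed-model or repeated-measures
analysis, which this package deliberately does not re-implement). The
curve's top is fitted rather than pinned to the water-day EIR, since
control-day and solvent-day baselines need not agree. The genotype shift is
log10(EC50_b/EC50_a) of two converged curves.

## Synthetic-data generators

All generators take one master seed and draw from named substreams, so
regenerating one data type never perturbs another; identical seeds give
bit-identical outputs.

**Population.** [Cl⁻]i is sampled from a Gaussian truncated to
[2, 110] mM — bounds bracketing the plausible single-cell range (observed
extremes ~7.8 and ~102 mM). Truncating a N(34.1, 27.6²) to that interval
would inflate the mean by ~18%, so the generator solves for the underlying
Gaussian location that makes the *truncated* mean equal the target
(location ≈ 24.0 mM for the default population); the scale parameter stays
at the nominal SD, giving a post-truncation SD of ~20.7 mM. Presets:
untreated (mean 34.1, SD 27.6 mM), cotransporter-knockout (13.2, 6.3) and
cotransporter-blocked (10.9, 6.5); the SDs are reconstructed from reported
SEMs (SD = SEM·√n). Ksv is Gaussian (14.4 ± 3.3 M⁻¹) truncated positive;
per-cell brightness F0 is log-normal (mean 100 a.u., CV 0.1).

**Kinetics.** Cytosolic chloride relaxes first-order toward its current
target with rate 0.05 s⁻¹ — a plumbing constant, not a measured one; the
plateau-based estimators are insensitive to it as long as steps settle
(0.05 s⁻¹ over a 10-min step leaves a residual of e⁻³⁰). Frame noise is
multiplicative Gaussian, CV 1% by default; photobleaching defaults to 0
(the dye is stable over the protocol) but can be injected and is measured
by `bleaching_check` as relative drift per minute (fail threshold 1%/min).

**Calibration traces** open with a 120 s resting segment at each cell's own
[Cl⁻]i (the resting-fluorescence reference) followed by the solution
steps. **Stimulation traces** relax each cell toward the critical
concentration while the stimulus is on and back toward rest afterwards, so
the *sign* of every noiseless cell's response equals the sign of
([Cl⁻]i − critical) by construction, and the generator's efflux fraction
is exactly the fraction of cells above critical.

**Fura-2 traces** are dual-channel: both channels deflect symmetrically by
a factor chosen so the ratio excursion equals the intended amplitude
exactly at full transient. Per-cell amplitude is
base · (1 + α·max(0, [Cl⁻]i − crit)/crit) with α = 0.65, the value at
which the knockout-to-untreated mean-amplitude ratio under the default
populations is ≈0.615 (a ~38% reduction) — α is a named default, not a
fitted quantity. The f380 channel is floored at 10⁻³ of its baseline so
the ratio is defined under any noise.

**Drinking sessions.** First-exposure intake is log-normal (mean 242 µl);
the second exposure is suppressed by EIR(c) = baseline_EIR/(1 + (c/EC50)^n)
with multiplicative log-normal noise per intake (CV 0.15, chosen so the
per-session EIR CV ≈ 0.21 matches the observed control-day spread).
Defaults: EC50 6.4 µM / baseline 1.11 (wild type), 17.3 µM / 1.15
(knockout); the Hill slope n = 1.2 is not a published number — it is the
value most consistent with the reported per-concentration mean EIRs given
the published midpoint. Each cohort also gets a water/water control
session per mouse.

### What the generators do not emulate

No membrane biophysics (conductances, action potentials, bicarbonate
permeation), no pixel-level imaging (ROI extraction, motion, focal drift),
no dye loading/compartmentalization artifacts, no inter-day or inter-animal
batch structure in behavior, and noise is independent across frames (no
1/f or shot-noise correlation). Passing recovery tests therefore shows the
*estimators* are correct and unbiased under the stated noise model — not
that real recordings meet that model.

## Numerical choices and degeneracies

* Steady-state windows are half-open [start, end); a protocol step ending
  one frame interval past the last timestamp is accepted.
* A baseline SD of exactly zero is floored (10⁻⁶ of the mean) instead of
  erroring, so noiseless synthetic inputs classify cleanly.
* A cell exactly at the critical concentration is non-efflux (strict
  inequality) and produces a flat trace.
* Negative [Cl⁻]i estimates clamp to zero with a flag; non-physical fits
  (Ksv ≤ 0) are reported but refuse to produce concentration estimates.
* All CSV floats are written with 9 significant digits; identical
  config + seed reproduces files byte-for-byte (the run manifest records a
  SHA-256 of the config).

## Problem sizes

Recovery statistics in the tests and the acceptance script use 200–1000
synthetic cells, 10,000 flat traces for the false-positive control, 100
noisy dose-response replicates, and 11-mouse drinking cohorts (the study's
design). Because a single 11-mouse cohort carries ~11% sampling error on
its fitted avoidance EC50 — comparable to the reported uncertainty of the
measured curve — cohort-level EC50 recovery is summarized as the median
over 15 seeded cohorts.

## Known limitations

* The fixed 58.0 mV/decade slope is a convention; reversal potentials
  computed with the exact 22 °C slope differ by ~0.5 mV and the critical
  concentration by ~0.4 mM. Published chloride reversal values for the two
  populations are themselves not reproducible to the last digit with any
  single slope constant.
* The avoidance fit on 6 mean points with 4 free parameters is weakly
  identified at the top end; per-mouse tidy output is provided for
  stronger hierarchical analyses.
* `fit_hill` is single-site only; biphasic or two-site models are out of
  scope.
* Group-comparison inferential statistics (t/U tests, repeated-measures
  ANOVA) are intentionally delegated to standard statistical software; the
  package emits the tidy tables they consume.
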