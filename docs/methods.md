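# Methods

This note records the models, conventions and numerical choices behind
`ctamem`, in the spirit of a package methods appendix: what is computed, what
is assumed, and where a design decision was genuinely open.

## Statistical machinery (`stats_core`)

All tests are two-sided; no continuity or sphericity corrections are applied
anywhere (the within-subject factors analyzed here either have two levels or
are reported without such corrections).

* **Unpaired t-test.** Student's pooled-variance form is the default because
  group comparisons in this literature report integer degrees of freedom
  (t(10) for groups of 6 and 6); Welch with Satterthwaite df is available by
  flag.  The statistic's sign follows `mean(group1) − mean(group2)`, and the
  behavioral layer always passes the control group first so reported signs
  are reproducible.  Zero pooled variance with equal means returns statistic
  0 / p 1 with a degeneracy flag rather than NaN.
* **Split-plot (two-way mixed) ANOVA.** Implemented from the classical
  decomposition: the between-subjects stratum splits into the group effect
  and subjects-within-groups (the error term for group); the within-subjects
  stratum into the within factor, the group×within interaction and the
  residual.  Complete repeated measures are required, but group sizes may
  differ (the designs analyzed here include 6-vs-7 groups); incomplete
  designs raise an error instead of being silently approximated.  Sums of
  squares within 1e-12 (relative to the total) of zero are clamped to exact
  zero so that all-constant inputs yield F = 0, p = 1 with a degeneracy
  flag.
* **Fixed two-way ANOVA.** Type-I sums of squares by sequential nested
  least-squares fits (grand mean, +A, +B, +cells).  On balanced data this
  equals the classical cell-mean decomposition; balanced designs are the
  supported contract and empty cells are an error.
* **Bonferroni.** p × family size, capped at 1; the family is always the
  length of the vector passed in, so callers choose the family explicitly.

## Neuron simulator (`synthetic`)

A leaky integrate-and-fire membrane with three extensions, integrated by
forward Euler at dt ≤ 0.1 ms (coarser sampling is refused because the spike
threshold criterion is a slope threshold):

* **Sag** — a first-order hyperpolarization-activated conductance
  g_sag·h·(E_h − V) with Boltzmann activation h∞(V) (half-activation −82 mV,
  slope 6 mV, reversal −30 mV, τ_h 50 ms).  Its strength is given relative
  to the leak conductance; at 0 the subthreshold steady-state deflection is
  exactly R_m·I.
* **Slow adaptation** — a spike-triggered hyperpolarizing current
  incremented per spike (default 0.8 mV equivalent, τ 500 ms).  This both
  flattens the F–I curve into the 10–20 Hz band at physiological currents
  and produces a measurable slow AHP and spike-frequency accommodation.
* **Stamped spikes** — when V reaches threshold, a stereotyped triangular
  waveform (rise 200 V/s to +30 mV, fall 100 V/s to a trough 8 mV below
  threshold) is written into the trace and integration resumes from the
  trough.  The subthreshold approach always has dV/dt far below 10 V/s while
  the stamp rises far above it starting exactly at V_T, so AP threshold,
  amplitude, half-width and the post-spike minimum have closed-form true
  values.  Stamp rise/fall durations are snapped to the sample grid so the
  sampled waveform attains the nominal peak exactly; ground-truth half-width
  uses the grid-effective slopes.

The default protocol is a 25 pA / 150 ms seal test inside a 400 ms baseline
(the post-seal gap is > 11 membrane time constants, so the baseline is clean
to ~1e-4 mV), then a 1000 ms step, amplitudes −100 and 0–450 pA in 50 pA
increments.  The step duration is a declared default — firing rate is
defined as spikes per step duration and is always taken from sweep metadata.
Membrane noise is an additive per-step Gaussian scaled by √(2·dt/τ_m) so the
parameter is the stationary voltage SD in mV.

Series resistance is carried as metadata (it feeds the QC rule) and is not
synthesized into the voltage traces; input resistance is measured from the
seal-test deflection.

The **sag-ratio ground truth** is defined operationally: the same
(V_ss − V_min)/(V_baseline − V_min) formula the extractor uses, evaluated on
a noiseless simulation at 4× finer dt with a 2000 ms step (true steady
state).  This makes the oracle independent of sampling and step-duration
artifacts while keeping a single definition of "sag ratio".

## Feature extraction (`ephys`)

* **Spike detection**: upward crossing of dV/dt > 10 V/s (forward
  difference), the trace must reach −20 mV within 5 ms, and events are
  separated by a 2 ms refractory interval.  The criterion is a design choice
  consistent with the threshold definition used for AP metrics.
* **AP threshold** is the first sample (searching back ≤ 5 ms from the peak)
  whose forward slope exceeds 10 V/s; amplitude is peak − threshold;
  half-width is the time above threshold + amplitude/2 with sub-sample
  linear interpolation; the post-spike minimum is taken within 50 ms or
  until the next event.
* **AHPs**: only sweeps firing 10–20 Hz contribute; the mAHP averages
  (threshold − post-spike minimum) over the 5th–10th APs (a sweep with fewer
  APs contributes what it has from the 5th on and is flagged partial); the
  sAHP is baseline minus the minimum within 500 ms after step offset.
  Magnitudes are reported positive.
* **Sag ratio** = (V_ss − V_min)/(V_baseline − V_min) on the −100 pA step,
  steady state = last 20 % of the step.  Of the two orientations the verbal
  definition admits, this one reproduces the reported scale (~0.13–0.15) and
  is the documented choice; a trace with no hyperpolarization returns 0 with
  a degeneracy convention.
* **Rheobase**: abscissa intercept of the line through the first two
  suprathreshold F–I points, clamped to (last zero-rate current, first
  spiking current].  An alternative one-spike interpolation between the last
  silent and first spiking step is available by flag.  The interpolation
  method was an open choice; both are labeled in outputs.
* **Accommodation** = last inter-spike interval / first.  Whether published
  "firing-rate accommodation" used an ISI ratio or a rate-decline metric is
  not recoverable; the ISI ratio is the implemented, labeled default.
* **QC**: strict inequalities — series resistance must *exceed* 30 MΩ or
  drift *exceed* 10 mV to exclude, so boundary values pass.

## Palatability coding (`palatability`)

Windows of 250 ms stepped by 25 ms tile [0, T − 250]; rates use half-open
intervals.  The correlation is computed **across trials**: each of the 60
trials contributes its window rate and its taste's palatability rank; ties
get average ranks.  Population aggregation uses |ρ| (sign carries no
information when units may encode palatability with either polarity); the
signed per-unit series is retained.  Zero-variance windows return ρ = 0 with
a flag.  The genotype comparison supports two observation layouts — every
unit×window cell in a two-way genotype×window ANOVA, or one mean |ρ| per
unit in a one-way layout with unit-level error df — because published df
conventions do not pin down which was used; both are labeled.  The
responsiveness criterion (Wilcoxon signed-rank of evoked 0–2 s vs
pre-stimulus baseline rate, Bonferroni over the four tastes) is a documented
choice, as no printed criterion exists.

The taste generator applies identity-epoch gains (per-taste rate multipliers
drawn with SD 0.05, uncorrelated with rank) that fade as a linear ramp
(default onset 600 ms, ramp 300 ms) brings in rank-ordered modulation of
depth 0.75·ρ_target.  The identity gain SD was chosen from the variance
budget: gain-induced rate separation must stay well below Poisson count
noise in a 250 ms window so that a zero-coupling population's mean |ρ| stays
at the analytic chance level, which is what the null checks assert.  The
achieved plateau correlation is an empirical, monotone function of ρ_target
(≈0.54 at the 0.7 default), not an analytic identity.  A deterministic
"regular" spike mode (evenly spaced spikes at the target rate) exists for
exact closed-form tests.  The generator emulates rate-coded palatability
with trial-independent gains; it does not emulate bursting, trial-to-trial
state switching, or correlated noise across units, so passing tests
demonstrate correctness of the analysis, not realism of cortical dynamics.

## Differential expression (`de`)

TPM: rate_g = count_g/length_kb_g per sample, normalized to 1e6.  The screen
tests each gene with the pooled t-test on linear TPM by default (matching
how the published values behave); a log2(TPM+1) mode is provided and
recommended for heavy-tailed data, and flagged in output.  Fold change is
mean(CTA)/mean(control) on linear TPM; a zero control mean reports an
infinite fold change with an exclusion flag.  The abundance gate is the
grand mean across all samples ≥ 30 TPM — the printed criterion is ambiguous
between ">30" and "≥30" and between per-group and overall means; the
inclusive grand-mean reading is implemented with a per-group option,
affecting only exact-boundary genes.  No transcriptome-wide multiple-testing
correction is applied (none is applied in the screen being reproduced);
Bonferroni enters only in declared panel comparisons, with the family equal
to the panel size.  Bundled marker panels are editable configuration, not
ground truth.

## Behavior (`behavior`)

Memory strength is the per-animal test/training consumption ratio (lower =
stronger aversion); animals with zero training volume are flagged and
excluded from ratios.  The post-hoc family is the four cell comparisons the
figure legends report — training-vs-test within each group (paired, same
animals) and control-vs-treated at each session (unpaired) — with Bonferroni
×4; the two diagonal cross-comparisons can be added by flag, which grows the
family accordingly.  Whether published post-hocs were paired within-animal
is not fully stated; both kinds are computed where applicable and labeled.
Source-data spreadsheet layouts vary, so column/sheet mappings are
configuration (a "dialect" dict), not code.

## Orchestration (`io`, `cli`)

Traces use an HDF5 container (`/cell` attributes, one group per sweep with
unit-tagged datasets); tabular exchange is TSV/CSV with declared schemas;
synthetic ground truth goes to JSON sidecars that analysis stages never
read.  Report writers are deterministic (fixed %.6g float format, fixed row
order, no timestamps) and carry provenance headers with the seed and a hash
of the analysis-relevant configuration.  Unknown config keys are rejected
before any stage runs.

## Problem sizes and calibration checks

The test suite and the acceptance script size their simulations as follows,
chosen to make each statistical claim decisive at desk scale: genotype
contrast 12 cells/genotype over 150–450 pA with 500 ms steps (power over 100
seeded runs, null calibration over 200); palatability populations of 20
units × 60 trials (onset/plateau over 100 runs; exact-enumeration Spearman
null at 2 trials/taste, 2520 assignments); DE screens of 2000 genes ×
4 samples/group over 50 seeds; type-I error of the mixed ANOVA over 1000
null replicates; behavioral power over 40 replicates of 6+6 animals.

## Known limitations

* The neuron model is a point LIF with stamped waveforms: it validates the
  extractor, not biophysics; AP shape parameters are exact by construction
  rather than emergent.
* Sag-on cells have an effective input resistance that differs from the leak
  R_m (the sag conductance is partly active at rest); recovery claims
  against R_m therefore use sag-free cells, and sag-on cells are checked
  against the operational oracle.
* ANOVA is balanced/complete-design only; there is no REML path for missing
  cells.
* The linear-TPM t-test inherits the heavy-tail sensitivity of the published
  approach; the log mode exists precisely because of this.
* Greenhouse–Geisser-type corrections for many-level within factors are
  deliberately not implemented (none are reported in the designs this
  reproduces); with 7–11 current levels the within-factor p-values should be
  read accordingly.
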