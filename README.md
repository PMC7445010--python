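# ctamem

Analysis pipeline for conditioned-taste-aversion (CTA) studies of
basolateral-amygdala projection neurons and their gustatory-cortex targets.
CTA is one-trial learning: an animal that tastes saccharin and then
experiences LiCl-induced malaise avoids saccharin afterwards, and the
strength of the memory shows up as reduced test-day consumption.  Studies of
this circuit combine four kinds of data, and `ctamem` implements the
computational analysis for each:

* **Intrinsic excitability** from whole-cell current-clamp recordings:
  input resistance from 25 pA seal tests, junction-corrected resting
  potential, the F–I curve and its interpolated rheobase, action-potential
  threshold (membrane potential where dV/dt first exceeds 10 V/s), amplitude
  relative to threshold, full width at half-height, medium and slow
  afterhyperpolarizations from 10–20 Hz trials, sag ratio on −100 pA steps,
  and QC exclusion of cells with series resistance > 30 MΩ or baseline
  drift > 10 mV.
* **Taste palatability coding** from single-unit spike trains: a moving
  window analysis (window 250 ms, step 25 ms) computing the Spearman
  correlation ρ between per-trial firing rates and the hedonic ranking of a
  four-taste battery (sucrose, NaCl, citric acid, quinine), population
  aggregation of |ρ|, and a two-way ANOVA comparing genotypes across time.
* **Cell-type-specific differential expression** on TPM matrices: per-gene
  unpaired t-tests with the three-part gate (fold change ≥ 2 or ≤ 0.5,
  p < 0.01, TPM ≥ 30), marker-panel purity checks, and Bonferroni-corrected
  panel comparisons (e.g. across the AMP-related kinase family).
* **Behavioral memory strength**: per-animal test/training consumption
  ratios, the split-plot (two-way mixed) ANOVA with treatment between
  animals and session within, Bonferroni post-hoc cell comparisons, and
  unpaired t-tests on ratios and on 8-h water controls.

The statistical machinery (pooled/Welch t, fixed two-way ANOVA with Type-I
sums of squares, split-plot ANOVA with subjects-within-groups as the
between-subjects error term, Bonferroni adjustment) is implemented from the
sums-of-squares decompositions in `ctamem.stats_core` and is cross-checked
against pingouin, statsmodels and exhaustive permutation oracles in the test
suite.

A seeded synthetic-data generator (`ctamem.synthetic`) produces every input
with recorded ground truth: a leaky integrate-and-fire neuron with a
first-order sag conductance, slow adaptation, and stamped spike waveforms
whose threshold/amplitude/half-width have closed-form true values;
inhomogeneous-Poisson taste trials whose late-epoch rates follow the
palatability ranking with controllable strength; log-normal TPM matrices
with planted fold changes; and truncated-normal consumption tables with
controllable learning effect sizes.

## The split-plot model

For a design with between-subjects factor *G* (a levels, n_g subjects in
group g) and within-subjects factor *T* (b levels), the decomposition is

    SS_total      = SS_between-subjects + SS_within-subjects
    SS_between    = SS_G + SS_subjects(G)          F_G = MS_G / MS_subjects(G)
    SS_within     = SS_T + SS_GxT + SS_residual    F_T = MS_T / MS_residual
                                                   F_GxT = MS_GxT / MS_residual

with df_subjects(G) = Σ_g (n_g − 1) and df_residual = df_subjects(G)(b − 1).
Complete repeated measures are required; groups may be unequal in size.

## Worked example

```sh
python examples/behavior_stats.py
```

simulates a two-group CTA experiment (control learns strongly, treated group
barely learns) and prints, among other output:

```
split-plot ANOVA (treatment between animals, session within):
group                    1 8.355   0.01609
level                    1 73.41 6.425e-06
group:level              1 31.81 0.0002154

test/training consumption ratios (lower = stronger memory):
control 0.320 0.049  6
treated 0.856 0.058  6

ratio t-test: t(10) = -7.04, p = 3.535e-05
```

The interaction row says the drop in consumption from training to test
differs between the groups — the signature of a learning difference — and
the negative ratio t (control listed first) says the control group keeps the
stronger aversion.  `examples/` contains one script per capability
(intrinsic excitability, genotype comparison, palatability coding, DE
screen, behavior).

A thin CLI orchestrates the stages over files:

```sh
ctamem all --seed 1 --out runs/demo     # simulate + every analysis stage
ctamem behavior --out runs/demo         # one stage over existing inputs
```

Reports are TSV/JSON with provenance headers (config hash, seed); traces
live in an HDF5 container, spike trains and tables in CSV/TSV.

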