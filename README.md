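# morphddm

Drift-diffusion analysis of binary happy–angry face-emotion labeling.

In face-emotion labeling tasks, participants classify faces drawn from a
15-step morph continuum running from prototypically happy (s = 1) to
prototypically angry (s = 15), with maximal ambiguity at the middle morph
(s = 8). `morphddm` is for researchers in computational psychiatry and
cognitive modelling who want to decompose such choice/reaction-time data into
interpretable perceptual and decisional components, compare those components
across clinical groups (e.g. youth with severe irritability vs healthy
controls), and test the behavioral machinery offline on fully synthetic
cohorts.

## The model

Each trial is modelled as a Wiener diffusion with absorbing boundaries: the
upper boundary codes an *angry* response, the lower a *happy* one. The drift
rate is linear in the morph index,

```
v(s) = v_int + s · v_slope,
```

with boundary separation *a*, relative starting point *z*ᵣ = *z*/*a*,
non-decision time *t*₀ and diffusion constant σ fixed at 1. Two derived
metrics summarise each participant:

* **sensitivity** — *v*_slope, how steeply evidence strength tracks valence;
* **perceptual bias** — the indifference point *s*_indiff = −*v*_int/*v*_slope,
  the (real-valued) morph at which drift vanishes; values below the continuum
  midpoint indicate a shift toward angry judgments.

Parameters are estimated per participant by maximising the Wiener
first-passage-time likelihood of the (choice, RT) pairs. Around the core
model the package provides the behavioral QC rules (fast-RT trial exclusion,
extreme-morph accuracy inclusion), group statistics (Bonferroni-corrected
correlation tables, one-way ANOVA with post hoc pairwise tests), a group-level
4-parameter logistic psychometric fit with a Wald inflection-point comparison,
a desk-scale linear/quadratic morph-contrast analysis for ROI beta profiles,
and a synthetic-data generator for every input (task schedules, DDM observer
cohorts, clinical questionnaires with calibrated correlation structure, ROI
betas).

## Worked example

Simulate one observer through a full 450-trial session, apply QC, and fit:

```python
from morphddm import (
    DDMParams, FitConfig, fit_participant,
    generate_task_schedule, simulate_observer_trials, qc_participant,
)

truth = DDMParams(v_int=-1.88, v_slope=0.25, a=1.2, z_r=0.5, t0=0.25)
schedule = generate_task_schedule(seed=0)
trials = simulate_observer_trials(truth, schedule, seed=1, participant="demo")
kept, report = qc_participant(trials)
fit = fit_participant(kept, FitConfig(seed=2))

print(f"trials kept: {len(kept)}/{report.n_trials_in} "
      f"(extreme-morph accuracy {report.extreme_morph_accuracy:.3f})")
print(f"sensitivity (v_slope): {fit.sensitivity:.3f}")
print(f"perceptual bias (s_indiff): {fit.perceptual_bias:.2f}")
print(f"boundary a={fit.params.a:.2f}  start z_r={fit.params.z_r:.2f}  "
      f"t0={fit.params.t0:.3f} s")
```

prints

```
trials kept: 450/450 (extreme-morph accuracy 0.867)
sensitivity (v_slope): 0.243
perceptual bias (s_indiff): 7.36
boundary a=1.17  start z_r=0.48  t0=0.255 s
```

The generating observer had *s*_indiff = −(−1.88)/0.25 = 7.52 and
*v*_slope = 0.25; the fit recovers both within the sampling precision a
450-trial session affords (the indifference point to a few tenths of a morph
step). No trials were faster than 150 ms, and extreme-morph accuracy 0.867
clears the 80% inclusion threshold.

The full pipeline (simulate → qc → fit → psychometric → stats → contrasts)
runs from the command line:

```sh
morphddm all --seed 11 --out-dir out/
```

and emits the per-participant parameter table, the metric-by-clinical-measure
correlation table, ANOVA and post hoc reports, the two-group 4PL psychometric
comparison, the patient-only age–sensitivity correlation, and the ROI
contrast-association report, each stamped with the config hash and seed.

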