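# prismadapt

Simulation and analysis toolkit for **prism-adaptation experiments**:
trial-by-trial visuomotor recalibration, adaptive contrast-sensitivity
staircases, and developmental time-course estimation.

## The problem

When displacing prisms shift the visual field, pointing movements miss
the target by the optical shift; with terminal feedback of the
fingertip, healthy observers correct this systematic error within a few
trials and show a negative **aftereffect** once the prisms are removed —
the two signatures of genuine visuomotor recalibration.  Individuals
treated late for congenital cataract recalibrate poorly right after
surgery and improve only over months to years.  This package implements
the quantitative machinery needed to study that phenomenon end to end on
synthetic cohorts, or on real trial tables loaded through a schema
adapter:

* a **single-state learner** generating trial-level pointing errors
  for a three-phase design (12 pre / 48 prism / 48 post trials, three
  targets, a +11.31° = 20 prism-diopter rightward shift, terminal
  feedback only under the prisms):
  `x ← ρ·x + η·e` on feedback trials, `x ← ρ₀·x` otherwise, with
  recorded error `e = shift·[prism] + bias − x + ε`;
* the **recalibration index**
  `i_recal = (Adaptation − Initial Aftereffect) / (2·Prism Distortion)`,
  where `Adaptation = Prism Distortion − End Prism` (mean of the last 3
  prism-phase errors) and the Initial Aftereffect is the mean of the
  first 3 post-phase errors: 0 = no recalibration, 1 = complete;
* **power-law learning-curve fits** `error = a·x^b` on group-mean
  prism-phase errors (more negative `b` = faster adaptation), with
  participant-level bootstrap CIs;
* a **two-block 3-up-1-down staircase** procedure measuring the contrast
  sensitivity function on a 9-frequency / 8-contrast doubling ladder,
  an inverse-parabola (log-parabola) fit `log₁₀S(f)` with cutoff
  extraction, CSF matching for blur controls, and simulated 2AFC
  observers;
* the **developmental exponential** `i_recal(x) = (a−c)·e^(−b·x) + c`
  with amplitude `a = 0` and asymptote `c` fixed to the blur-control
  mean, rate `b` in 1/years estimated with a cluster bootstrap;
* the **statistical battery**: Kruskal–Wallis with η², Bonferroni-
  corrected rank-sum tests, exact signed-rank for small n, two-sample
  variance F-tests, 3-SD outlier-screened Pearson correlations, and the
  per-participant join with a Multisensory Influence score.

## Worked example

```python
import numpy as np
from prismadapt import simulation as sim, recal_metrics as rm

design = sim.ExperimentDesign()                      # 12/48/48, +11.31 deg
cohort = sim.simulate_group(design, "cataract", n=20, seed=11)
metrics = rm.compute_metrics(cohort, design.prism_shift_deg)
print(round(metrics["i_recal"].mean(), 3))           # 0.301

prism = cohort[cohort.phase == "prism"].pivot_table(
    index="participant_id", columns="trial", values="error_deg")
fit = rm.fit_power(prism.mean(axis=0).to_numpy(), n_boot=0)
print(round(fit.b, 3))                               # -0.113
```

The cataract preset recalibrates weakly (`i_recal ≈ 0.3` vs ≈ 0.7 for
sighted controls) and flattens the learning curve (`b ≈ −0.11` vs
≈ −0.32): residual prism-phase error stays high, the aftereffect is
present but does not decay, and baseline pointing variance is an order
of magnitude above controls.

The staircase CSF pipeline on simulated observers with a true cutoff of
5 cpd:

```python
import numpy as np
from prismadapt import csf

true = csf.CSFModel.from_cutoff(1.3, 0.3, 5.0)       # cutoff 5 cpd
cutoffs = [
    csf.measure_csf(csf.simulate_csf_observer(true, seed=s)).model.cutoff_cpd
    for s in range(20)
]
print(round(float(np.median(cutoffs)), 2))           # 5.24
```

Single runs scatter (staircase rungs double per step), but the median
recovery sits within a few percent of the true cutoff.

A command-line interface exposes the same stages:
`prismadapt simulate-cohort | simulate-csf | analyze | fit-development |
report`.

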