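# audthal

Analysis toolkit for paired pure-tone (PT) / narrowband-noise (NBN)
characterization of auditory detection and thalamic single-unit coding.
It is written for auditory neurophysiologists who present the standard
half-octave frequency x level lattice (11 bands x 8 SPLs x 2 stimulus
kinds) in a go/no-go detection task and in spike-sorted recordings, and
who want the full chain — behavioral signal detection, rate-level fitting,
temporal dynamics, single-unit discriminability, population decoding and
tonotopy — as tested, reusable code.  A calibrated synthetic-data
generator with ground-truth bookkeeping makes every stage verifiable by
parameter-recovery simulation.

## What it computes

* **Behavioral sensitivity.**  Lever-release trials are segmented by
  target onset into hit/miss and false-alarm/correct-rejection windows
  (the FA window is a virtual copy of the hit window placed before the
  target, so FAR cannot depend on target amplitude), giving
  `performance = (HT+CR)/(HT+CR+FA+MS)` and `d' = Z(HR) − Z(FAR)`;
  detection threshold is the lowest amplitude where group d' exceeds zero.
* **Rate-level functions and C50.**  At each frequency the normalized
  response is fitted with a scaled log-normal of SPL,
  `f(x) = E/(xσ√2π)·exp(−(ln x − µ)²/2σ²) + B`; C50 is the SPL at 50% of
  the baseline-to-maximum range, the half-width separates monotonic from
  O-shaped units, and the characteristic frequency (CF) is the frequency
  with the lowest C50 among criterion-passing fits.
* **Temporal dynamics.**  PSTH peak latency (5 ms bins) and the decay
  constant τ of `A·e^(−t/τ) + C` fitted to the short-interval (< 30 ms)
  ISI density, both at the unit's best stimulus.
* **Single-unit frequency discriminability.**  Trial-wise
  `D = ΔCF − Δadj`, `Pc = (n_{D>0} + 0.5(1+n_{D=0}))/(n_tot+1)`,
  `d' = √2·Φ⁻¹(Pc)`, as a function of SPL relative to C50.
* **Population decoding.**  11-class frequency classification from
  pseudopopulations of 50 units with a one-vs-one linear-SVM ECOC
  ensemble and hinge-loss-weighted decoding, with shuffled-label
  baselines and cross-condition (train PT / test NBN) generalization.
* **Tonotopy.**  Per-penetration regression of log2(CF) on distance from
  the probe tip.

## Worked example

```python
import numpy as np
from audthal import synth, pipeline, behavior
from audthal.stimuli import build_stimulus_grid

grid = build_stimulus_grid()                  # 11 bands x 8 SPLs x {PT, NBN}

# --- behavioral arm: 8 animals x 10 sessions ---------------------------
trials, _ = synth.generate_behavior_sessions(synth.BehaviorGenConfig(), seed=1)
outcomes = behavior.classify_trials(trials, seed=2)
per_animal = behavior.aggregate_dprime(behavior.sdt_summary(outcomes))
thr = behavior.detection_thresholds(per_animal)
print(thr["PT"], thr["NBN"], thr["threshold_difference_db"])
# 31.5 28.0 3.5

# --- neural arm: fit rate-level functions, compare C50 across kinds ----
spikes, _ = synth.generate_unit_population(synth.UnitGenConfig(n_units=60),
                                           grid, seed=5)
analysis = pipeline.analyze_units(spikes, grid, seed=0)
paired = pipeline.paired_c50_differences(analysis)
print(len(paired), round(paired["diff_db"].median(), 2))
# 53 1.77
```

The behavioral numbers say the pipeline recovered a pure-tone detection
threshold of 31.5 dB SPL and a narrowband-noise threshold of 28 dB — the
noise target is detected one 3.5 dB amplitude step lower, mirroring the
greater behavioral sensitivity to narrowband noise.  The neural numbers
say that of 60 simulated units, 53 had a consistent characteristic
frequency under both stimulus kinds, and their median paired C50
difference (PT − NBN) was positive: units respond to narrowband noise at
lower sound levels.  At the full 200-unit scale the median lands at the
configured 2.2 dB offset.

A single fitted rate-level function is a model object:

```python
from audthal import RateLevelModel
res = RateLevelModel(spl_db, normalized_rates).fit()
print(res.summary())      # parameters, standard errors, R^2, C50, half-width
res.plot()
```

There is also a thin CLI (`audthal grid`, `audthal synth-behavior`,
`audthal synth-units`, `audthal sdt`, `audthal run`) over the same
functions.

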