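# calltag

Analysis of vocal behavior from groups of simultaneously tagged animals,
built around the study design used for humpback whales (*Megaptera
novaeangliae*) on their feeding grounds: every whale in a small group (2–3
individuals) carries a suction-cup acoustic tag, so each call is recorded on
every tag and can be attributed to the whale whose tag received it loudest.
The package is aimed at bioacousticians and behavioral ecologists working
with multi-tag (Dtag-style) deployments who need caller-attributed call
tables and the downstream statistics: call levels, call timing (bouts and
overlaps), repertoire composition, and age-class comparisons.

## What it computes

**Received levels.** Calls are measured as RMS sound pressure level over the
90% cumulative-energy window of the annotated clip, calibrated through the
hydrophone sensitivity (nominally −171 dB re 1 V/μPa):
`RL = 20 log₁₀(V_rms) + 171` dB re 1 μPa.

**Caller assignment.** Detections from synchronized tags are bundled by
temporal overlap; within a bundle the loudest member is *focal* (the tagged
whale called) if it beats the runner-up by ≥ 1 dB, others are *nonfocal*;
closer than 1 dB the call is *indeterminate*.

**Bout analysis.** Inter-call intervals (onset-to-onset, per individual) are
modeled as a two-process exponential mixture
`f(t) = p·λ_f e^(−λ_f t) + (1−p)·λ_s e^(−λ_s t)` with λ_f > λ_s. The
bout-end criterion (BEC) is the density intersection
`t* = ln(p·λ_f / ((1−p)·λ_s)) / (λ_f − λ_s)`; runs of ≥ 2 calls with all
gaps < BEC form bouts. Estimation is by direct maximum likelihood
(`ExponentialMixtureBEC`) or by a broken-stick fit to the log-ICI histogram
(`BrokenStickBEC`).

**Overlaps.** Pairs of focal calls from different individuals in a group
with strictly intersecting spans.

**Repertoire.** A two-level taxonomy (broad types split by tonal/pulsed
structure and a 2 kHz first-harmonic rule; analyst-consensus subtypes such
as bop, grunt, whup, thwop, knock) with proportional-use tables per
individual or age class.

**Received-level model.** A Gaussian random-intercept model
`rl ~ age_class + (1 | individual)` fitted by profiled (RE)ML, compared to
an intercept-only null by AIC.

A synthetic-scene generator (`calltag.scene`) produces multi-tag annotation
tables and optional rendered audio with known ground truth — call schedules
from the same two-process mixture, spherical spreading loss, repertoire
draws from published proportions — so every stage can be validated without
field data.

## Worked example

```python
import numpy as np
from calltag.pipeline import run_pipeline

report = run_pipeline({
    "simulate": {
        "group_id": "demo", "duration_s": 3600.0, "spacing_m": 50.0,
        "whales": [
            {"whale_id": "mother", "age_class": "adult", "role": "mother"},
            {"whale_id": "calf",   "age_class": "calf",  "role": "calf"},
            {"whale_id": "escort", "age_class": "adult"},
        ],
        "noise_rl_sd_db": 0.0, "seed": 7,
    },
})
fit = report["bout_fit"]
print(f"BEC = {fit.bec_s:.2f} s  (p_fast={fit.p_fast:.2f}, "
      f"lf={fit.lambda_fast:.2f}/s, ls={fit.lambda_slow:.3f}/s)")
print(report["bout_summary"].round(2).to_string(index=False))
```

prints

```
BEC = 2.33 s  (p_fast=0.69, lf=1.97/s, ls=0.050/s)
age_class  n_bouts  n_calls  median_ici_s  iqr_ici_s  cv_ici  median_bout_duration_s  median_calls_per_bout
    adult      221     1075          0.39       0.60    2.17                    2.17                    4.0
     calf      109      542          0.37       0.55    2.16                    1.96                    4.0
```

i.e. the 1617 simulated calls segment into bouts under a recovered BEC of
2.33 s (the generator's true density intersection is 2.326 s), with
within-bout median gaps around 0.4 s. The same report carries the labeled
call table, overlap instances, repertoire proportions, and the ML/REML AIC
comparison of the received-level model.

The same stages are exposed on the command line:

```sh
calltag simulate --config scene.yaml --out-dir scene/
calltag assign --group scene/ --delta-db 1.0 --out calls.csv
calltag bouts --input calls.csv --method mle --out bout_summary.csv
calltag overlaps --input calls.csv --out overlaps.csv
calltag rlstats --input calls.csv --method ML
```

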