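# wardtrig

Ambient environmental triggers of momentary agitation — and its motor and
verbal subtypes — in people with dementia on a specialized ward, as a
tested, reusable analysis pipeline with a synthetic ward generator.

Dementia wards increasingly carry fixed ambient sensors (light in lux,
A-weighted equivalent sound level in dBA, temperature in °C) alongside
experience-sampling surveys in which nurses rate a patient's momentary
agitation on the Pittsburgh Agitation Scale (PAS).  The scientific question
this package operationalizes: *which environmental conditions in the
minutes before a survey raise the odds of an agitated observation, and do
the triggers differ between motor and verbal agitation?*  Answering it
requires a chain of unglamorous steps — room-conditioned window extraction
behind a prediction buffer, sensor fusion, quality filtering, within-room
standardization, mixed-effects modelling with forward selection — and each
step is easy to get quietly wrong.  `wardtrig` implements the chain as a
library with every stage unit-tested and the whole pipeline validated by
parameter recovery on simulated wards with known ground truth.

## The model

For survey *j* of patient *i*, environmental features are computed from the
half-open pre-survey window `[t − 33 min, t − 12 min)` (12-minute buffer so
that an ongoing verbal episode cannot leak into its own predictors), as
min/max/mean/median/SD per modality, z-scored within the majority room.
Binary outcomes (overall, motor, verbal agitation; PAS subtype score ≥ 1)
are modelled with random-intercept binomial GLMMs,

    logit P(y_ij = 1) = x_ij' β + b_i,     b_i ~ N(0, σ_b²),

fitted by adaptive Gauss–Hermite quadrature (25 nodes) over the patient
intercept — each β is a log-odds change per 1 SD of its feature, exp(β) an
odds ratio.  Exploratory single-predictor models
`outcome ~ z_feature + time_group + (1|p_id)` across window lengths pick
the informative window and per-modality features; a forward build-up
(models 0–9: context, sound, light, both, interactions) gated by chi-square
likelihood-ratio ANOVA tests yields the outcome-specific models.  Design
truth in the default generator: SD of sound drives verbal agitation
(β = 0.68), mean light level drives motor agitation (β = −0.61, a dim-ward
understimulation effect), temperature drives nothing.

## Worked example

Simulate a small ward study and run the complete analysis (also available
as `wardtrig all --seed 11 --out scratch/demo_run` from a config file):

```python
import json
from wardtrig import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(
    simulate=SimulationConfig(seed=11, n_patients=20, days_per_patient=4),
    lengths=[12.0, 21.0, 30.0],
    out_dir="scratch/demo_run",
)
out = run_pipeline(cfg)
print(json.loads((out / "selection.json").read_text())["length"])
```

The run directory contains `features.csv`, `quality_report.csv`,
`beta_grid.csv`, `selection.json`, `fits.json`, `anova.csv`,
`summary_table.csv` and `run.log`.  With seed 11 the sweep selects the
**21-minute** window (the causal window planted by the generator), and the
verbal-agitation ANOVA column of `anova.csv` reads:

     model  vs            variable_added            p
         1   0                time_group 9.836039e-01
         2   1            maj_room_group 8.863668e-01
         3   2                z_sound_sd 8.082299e-18
         4   2                z_light_sd 1.084742e-01
         5   3                z_light_sd 6.938843e-01
         5   4                z_sound_sd 2.756636e-17
         6   3     z_sound_sd:time_group 1.045790e-01
         ...

i.e. adding the sound-SD feature improves the verbal model enormously,
adding light does not, and no interaction helps — the dissociation the
design plants.  The fitted model 3 for verbal agitation
(`fits.json`) reports `z_sound_sd`: β̂ = 1.099, SE = 0.168, σ̂_b = 1.00 —
one small-sample draw around the generative 0.68 with 550 analysed
surveys; the recovery experiments below average 20 such replicates at 150
patients, where the mean estimate lands within Monte-Carlo error of truth.

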