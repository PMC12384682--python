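# Methods

`wardtrig` implements, end to end, an experience-sampling analysis of
ambient environmental triggers of agitation in people with dementia on a
closed neuropsychiatric ward, together with a synthetic ward generator that
makes every stage of the analysis verifiable by parameter recovery.  This
note documents the model, the generator, the numerical choices, and the
limits of what the simulation studies can show.

## The analysis

**Outcomes.** Each nurse-completed momentary survey rates the four
Pittsburgh Agitation Scale (PAS) subtypes — motor, verbal,
resistance-to-care, aggression — on 0–4.  A subtype is *present* when its
score is ≥ 1; *overall agitation* is present when any subtype is.  The
analysis models overall agitation, motor and verbal agitation;
resistance-to-care and aggression are too rare to model on their own but
still count toward overall agitation.

**Windows.** For a survey at time *t* the analyzed window is the half-open
interval `[t − (buffer+length)·60 s, t − buffer·60 s)`.  The 12-minute
buffer separates *prediction* from *detection*: an ongoing verbal episode
raises the measured sound level, so the window must end well before the
survey.  Candidate lengths run 3–30 min in 3-min steps; the analysis window
of the design is 21 min, i.e. 33 to 12 minutes pre-survey.

**Extraction.** The window series is conditioned on the patient's room:
each occupied room contributes its sensor's readings clipped to the
occupancy interval; rooms with two enclosures contribute the
timestamp-aligned mean of both; rooms without sensors and off-map time
contribute nothing.  Segments are concatenated chronologically and smoothed
with a **trailing** 5-second moving average (all points in `(t−5 s, t]`).
Trailing rather than centered because the pipeline feeds prediction: no
future samples may leak into a feature.  Smoothing is applied after
concatenation, since its purpose is to soften the steps that room
transitions introduce.

**Features and quality.** Per modality: min, max, mean, median, sample SD
(n−1).  Four independent quality criteria, with the strictness of each
inequality deliberate: off-map time fraction < 50% (strict); number of
points ≥ 50% of expected (non-strict; expected = window seconds / sample
period); majority room must have a sensor; survey inside [08:00, 20:00)
(a survey at exactly 20:00 fails).  The off-map share is measured as *time*
fraction, which is robust to sampling gaps.  Features of quality-passing
rows are z-scored within (majority room × feature × modality), the
standardizer being refitted per window length on passing rows only — so a
value of +1 always reads "1 SD above this room's typical level", which is
what makes coefficients transportable across rooms and wards.

**Models.** Random-intercept binomial GLMMs,
`outcome ~ fixed effects + (1 | patient)`.  Exploratory stage: one model
per (feature, modality, outcome, window length) of the form
`outcome ~ z_feature + time_group + (1|patient)`; the time groups are
[8,12), [12,16), [16,20), [20,8) with group 1 as reference (a sundowning
proxy).  The analysis window is the length where the most grid cells are
simultaneously significant (α = .05) and at their across-length maximum
|β̂|; ties go to the longer window.  Per (outcome, modality) the feature
with the largest |β̂| at that window is carried forward; a modality with no
significant feature for *any* outcome is dropped entirely (with the default
generator this is temperature's designed fate).  Build-up stage, per
outcome: model 0 (intercept + RE), +time groups (1), +majority-room group
(2, reference "living room"), +sound (3), +light (4), +both (5),
+sound×time (6), +sound×room (7), +light×time (8), +light×room (9).  Each
addition is gated by a chi-square likelihood-ratio (ANOVA) test on
identical rows; the contextual covariates are kept regardless of their test
(domain knowledge: sundowning, location confounding), environmental and
interaction terms only on a significant improvement.  No multiplicity
correction anywhere — the analysis is explicitly exploratory.

## The GLMM engine

The marginal likelihood integrates the patient intercept out of each
patient's product of Bernoulli terms.  Per patient the integral is
evaluated by **adaptive Gauss–Hermite quadrature** (default 25 nodes):
a damped Newton iteration finds the posterior mode of b, the negative
curvature there sets the node scale, and the probabilists' Hermite rule is
applied around the mode.  Optimization is L-BFGS-B on (β, log σ_b), bounded
log σ_b ∈ [−8, 3] so the σ_b → 0 boundary is reachable (at the bound the
model is numerically a plain logistic regression).  The gradient is the
*exact* marginal score by Fisher's identity — the posterior-weighted
complete-data score, computed from the same quadrature pass at no extra
cost — so the climb is deterministic, with gradient tolerance 1e-8 and a
deterministic start (plain logistic Newton fit for β, σ_b = 1).
Standard errors come from the observed information (central differences of
the analytic score); fixed-effect inference is Wald with ±1.96·SE
intervals, matching the default summary of the R `glmer` workflow this
mirrors.  Validation: the quadrature agrees with dense trapezoid
integration to ~1e-13 per fit, with `lme4::glmer` (nAGQ = 25) to < 5e-3 on
all parameters, 25 vs 51 nodes differ by < 1e-5, and at the σ_b = 0
boundary the estimates match `statsmodels` GLM to < 1e-4.  Outcomes with a
single class are rejected; quasi-separation (|β̂| > 15) flags the fit
non-converged rather than raising, and a non-converged fit aborts only its
own build-up branch.

Degenerate inputs: empty series produce NaN features (quality then excludes
the row); standardization strata with < 2 rows or zero SD yield undefined z
with a logged reason; LRT comparisons refuse fits on different rows, and a
full model that fits worse than its nested comparator by more than 1e-6
deviance raises instead of reporting a negative statistic (warm starts from
the nested optimum make this unobserved in practice).

## The synthetic ward

The generator emulates the study conditions: a 13-room ward (one ward;
living, dining and activity rooms with two sensor enclosures each, two
hallways, eight patient rooms of which one unsensored, one unsensored
therapy room), 1 Hz sampling, patients included for about a week, nine
semirandomly scheduled prompts per patient-day in 08:00–20:00 (one uniform
draw per equal sub-bin, minute resolution, no minimum spacing — adjacent
windows may overlap, as in reality).

**Streams.** Light is lognormal: log-lux = room-group base + diurnal cosine
(amplitude 1.0, peak 14:00) + slow per-sensor drift (SD 0.45, ~30-min
correlation; lights switched, blinds, occupancy) + white noise (SD 0.6).
Bases are calibrated so the pooled weekly median is ≈ 22 lux with room
medians inside 7–64 lux — a dim, understimulating ward.  Sound (leq, dBA)
is a room base (41–48 dBA) + small diurnal (0.5 dBA) + slow drift (1.5 dBA)
+ white noise (2 dBA) + sporadic positive bursts (0.01/s, mean 8 dBA) —
the bursts are what gives the window SD of sound its between-window
variance.  Temperature is thermostat-like: 22 °C ± small room offsets
(SD 0.25 °C), a 0.2 °C diurnal and an hour-scale drift (0.3 °C); nothing
downstream is driven by it, so it plays the designed null modality.  The
modality-specific slow drifts are mutually independent by construction:
early drafts that gave all modalities strong in-phase diurnals (and
sub-window dwells, below) made every central-tendency feature a proxy of
light mean and inflated all modality SDs jointly in room-spanning windows —
an emulation error that manifested as significant temperature effects and
broken motor/verbal dissociation, i.e. the generator contradicted the very
conditions it was meant to represent.

**Location.** A semi-Markov process: destinations drawn from fixed visit
probabilities (own room 0.30, living 0.22, dining 0.16, hallways 0.14,
other 0.18), lognormal sojourns with room-group mean dwells of 8 min
(hallway) to 90 min (patient room) — residents sit for long stretches, so
most 21-min windows lie in one room.  After each visit an off-map gap
(wearable not worn, untracked location) is inserted with a probability
solved so the long-run off-map fraction hits its target (default 0.15);
when one gap per visit cannot reach the target the gap length stretches
instead.  Off-map time plus the sensorless rooms make the location-driven
criteria the dominant exclusion path, mirroring the real study's attrition.

**Outcomes.**  With z the realized causal-window features standardized
within majority room across all scheduled windows:

    motor  ~ Bernoulli(expit(−2.35 − 0.61·z_light_mean + time + room + b_i))
    verbal ~ Bernoulli(expit(−2.85 + 0.68·z_sound_sd  + time + room + b_i
                             + 0.5·motor))

with b_i ~ N(0, 1) shared between channels, time effects (0.55, 0.90, 0)
for groups 2–4 in the motor channel and small (0.10, 0.15, 0) in the verbal
one, room effects up to 0.95 (hallway), and a 1% chance each of a
resistance-to-care / aggression score (the "agitated but neither motor nor
verbal" surveys).  PAS severities for present subtypes are uniform on
1–4; only presence/absence is analyzed.  Design choices worth making
explicit:

* *Realized-feature truth.* The generator computes its causal features with
  the same windowing code the pipeline uses and standardizes them against
  the population of all scheduled windows.  The planted coefficients are
  therefore exactly the log-odds-per-SD effects of the realized design;
  closed-form window-feature moments for burst noise under a diurnal
  profile would require approximations whose error would bias recovery in
  an uncontrolled way.  The pipeline still re-derives everything
  independently from the raw tables, and its standardizer is fitted on
  quality-passing rows only — that small moment mismatch is part of the
  recovery noise budget.
* *Co-occurrence.* Motor–verbal co-occurrence is carried mainly by the
  shared b_i, which the fitted models absorb; the per-survey κ·motor term
  is kept small (0.5) because the analysis models omit it and logistic
  non-collapsibility would otherwise attenuate recovered coefficients.
  Consequence: the generator matches the study's marginal prevalence
  profile (agitated ≈ 0.28 of surveys, motor-only ≫ verbal-only) but not
  its exact co-occurrence split.
* *Intercepts* were calibrated once against that prevalence profile
  (−2.35 / −2.85; −1.85 for the direct-agitation mode) and frozen.
* *Direct-agitation mode.* For recovery experiments that plant an effect on
  *overall* agitation, OR-of-subtypes generation gives no single generative
  coefficient to compare against; in this mode the agitation channel is
  generated from its own logistic model and expressed as a
  resistance-to-care score (motor/verbal zero).
* *Self-initiated surveys* (nurses may add an EMA when an episode occurs)
  exist as an optional mode — candidate extra prompts accepted with the
  moment's model-implied agitation probability — and are off by default;
  the observed mix in the real protocol is unknown, so it is configurable,
  not inferred.
* Time groups of the generator match the pipeline's; group 4 only arises
  if the prompt window is widened.  Timestamps are naive ward-clock
  seconds throughout (a timezone seam would add DST handling with no
  benefit for a single-site design).
* Sampling period defaults to 1 s so the 5-s smoothing spans five samples;
  the period must divide the smoothing span.

## Simulation studies and their problem sizes

All replicate seeds are spawned from one root seed; every study is exactly
reproducible.  The sizes below are the package's chosen operating points —
large enough that Monte-Carlo error is small against the effects studied,
small enough to run on a laptop core in minutes.

* **Recovery** (`recovery_experiment`): 20 replicates of 150 patients × ~50
  scheduled surveys (6 days × 9 prompts); ~6,000 analysis rows per
  replicate after quality filtering.  Planted coefficients are recovered
  with |bias| within 2 Monte-Carlo SEs (≈ ±0.02 log-odds here).
* **Window selection** (`window_selection_experiment`): 20 replicates of 30
  patients × 5 days, sweep over {12, 21, 30} min at buffer 12; the
  21-minute window is selected essentially always, because every
  |β̂| grid cell with planted signal peaks when the window matches the
  causal [33, 12) interval and dilutes as the window under- or overshoots
  it.
* **Null calibration** (`null_calibration_experiment`): 200 reduced
  replicates (15 patients × 2 days, 5-s sampling) with all environmental
  coefficients zero; the environmental-term LRT rejects at 0.05–0.10 —
  nominal-to-slightly-liberal, as expected for chi-square asymptotics with
  15 groups.
* **Build-up dissociation**: the same 20 selection replicates, running the
  full model 0–9 build-up at 21 min.  The qualitative pattern of the
  design — light (not sound) improving the motor model, sound (not light)
  the verbal model, both the overall model, no interaction improving
  anything — involves roughly fourteen null LRTs per replicate at α = .05
  *with the tested feature chosen by maximum |β̂|*.  Even under a perfectly
  faithful generator the joint probability of all of them staying
  non-significant is bounded well below 1 (≈ 0.95 per independent null test
  before accounting for winner's-curse selection), so the all-components
  conjunction holds only in a minority of replicates even though each
  individual direction holds in most; the experiment reports per-component
  rates for diagnosis.  This is a property of the selection-then-test
  design itself, not of the implementation.

## What passing these studies does — and does not — show

The generator shares the pipeline's windowing code for its truth features
(deliberately, see above), so recovery validates quality filtering,
standardization, model fitting and inference, but is not a test of the
windowing arithmetic itself; that is covered by hand-computed fixtures and
an independent constant-room oracle in the unit tests.  The synthetic ward
also omits much of what makes real ward data hard: sensor dropouts and
clock drift (streams are gapless and synchronized; the real-data path
tolerates gaps but never interpolates), behaviour that *responds* to the
environment (occupancy is independent of the sensor streams, whereas real
patients seek out quiet or bright rooms), non-stationarity over a stay,
measurement error in room-level localization other than off-map gaps, and
any acoustic structure beyond a scalar level.  Agreement of the pipeline
with its planted truth here therefore supports the software's correctness,
not the clinical validity of any coefficient on real data.

Known limitations: Wald (not profile-likelihood) intervals; no random
slopes or crossed random effects; single-ward layouts only; the dual-sensor
fusion assumes synchronized ticks (a nearest-neighbour alignment dialect
for real enclosures is a natural extension); window lengths in the sweep
re-fit the standardizer per length, so features are not comparable *across*
lengths by construction.
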