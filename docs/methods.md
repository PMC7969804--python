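# Methods

## The model

Repeated measurements from the same athlete are not independent: baseline
ONSD varies between healthy individuals by millimetres, and baseline
cognition varies likewise. The core model is therefore a random-intercept
linear mixed-effects (LME) regression,

    y = X β + Z u + ε,    u_i ~ N(0, σ_u²),    ε ~ N(0, σ_ε²),

with the outcome y (ONSD in mm, or PC-ImPACT in PC units), fixed effects X
(principal components of the oculomotor feature battery, plus an intercept
for the raw variant), and Z the subject-indicator incidence matrix. All
variance components are estimated by maximum likelihood (not REML). Two
variants are fitted: **R-LME** on raw values, and **SN-LME** on
subtractively normalized values (each subject's first-session baseline
subtracted from every later measurement; baseline rows are used only for
normalization and excluded from fitting). SN-LME models carry no intercept,
since baseline subtraction removes offsets by construction.

Assumptions: a single additive subject intercept (no random slopes, no
crossed effects); Gaussian residuals; predictions are only made for
subjects with at least one training session — predicting a wholly unseen
subject reduces to the fixed effects x·β.

### Estimation

The likelihood is profiled over the variance ratio λ = σ_u²/σ_ε²: for fixed
λ the GLS fixed effects and the ML residual variance are closed-form in
per-subject sufficient statistics, leaving a one-dimensional optimization
over log λ (bounded search, with the λ = 0 boundary checked explicitly).
Random intercepts are the empirical BLUPs
u_i = λ Σ_i(y − Xβ) / (1 + λ m_i). This implementation is exercised in the
test suite against statsmodels' `MixedLM(reml=False)` and against a
brute-force multivariate-normal likelihood grid; it exists because the
nested cross-validation below requires thousands of fits per run.

### Nested leave-one-session-out cross-validation

Each subject-session is held out once. Inside every outer training set, in
order: missing features are imputed with training means, features are
standardized, a PCA is fitted, and the number of retained top PCs is chosen
by an inner leave-one-session-out loop over the training rows — the count
(from 1 up to min(10, rank, rows−2)) maximizing inner predicted-vs-actual
Pearson correlation wins, ties going to the smallest count. The model is
then refitted on the full training set and the held-out session predicted
as x·β + u_subject, using the subject's intercept estimated from their
*other* sessions (available because folds are sessions, not subjects).
Held-out predictions are pooled into Pearson correlation (two-sided t
p-value), RMSE, bias (mean predicted − mean actual) and R².

Numerical choice: inner-loop fold predictions re-solve the GLS fixed
effects *exactly* for every left-out row via rank-one downdates of the
sufficient statistics, but hold λ at its ML value estimated once per
(outer training set, PC count). Re-optimizing λ inside each of the ~10⁵
inner folds would multiply runtime by two orders of magnitude for no
measurable change in the selected PC counts; the outer-fold models are
always full ML fits. One PCA per outer training set is shared across the
inner enumeration (the PCA precedes the inner loop).

A **fixed-effects-only baseline** (ordinary least squares on the same
feature PCs, same nested selection with λ ≡ 0) quantifies what the random
intercept contributes.

### Feature importance

Per outer fold, the 20 largest-|loading| features of each selected PC
receive weight |loading| × |PC coefficient|; weights are summed per
feature, averaged across folds and normalized so the top feature has
weight exactly 1, reported separately for central (median/count) and
dispersion (SD) channels.

## Outcomes

**PC-ImPACT.** The six ImPACT composites point in different directions, so
reaction time, impulse control and symptom score are reciprocal-transformed
(larger = better everywhere), columns are z-scored (the composites live on
disparate scales — points, seconds, counts — so unstandardized PCA would be
dominated by arbitrary units), and the first principal-component score is
taken. Eigenvectors are sign-ambiguous; the orientation rule makes the
verbal/visual/visual-motor loadings positive, so higher PC-ImPACT means
higher neurocognitive performance. The symptom score is carried through the
computation by default (its loading is near zero in practice) with a
`drop_symptom` switch. Variance explained by the first PC is reported as a
diagnostic.

**SN PC-ImPACT.** Reciprocals of deltas are undefined (deltas can be
non-positive), so the order of operations is: reciprocal-transform the raw
composites, subtract each subject's baseline, then standardize and fit the
PCA on non-baseline rows.

## The synthetic cohort

No raw data are deposited, so the package generates its own study: 30
subjects, 4 complete sessions each (pre-, early-, late-, post-season), all
three tasks simulated per session at full length (35 pursuit cycles, 78
saccade steps, 18 anti-saccade cues; ~4.3 min of 1 kHz gaze per session).

**Gaze simulation.** Saccades follow the velocity-profile family
v(t) ∝ sin(π t/D)^s; the exponent s sets the Q-ratio
(Q = √π Γ(s/2+1)/Γ((s+1)/2); s = 0 is rectangular, Q = 1; s = 2 is a raised
cosine, Q = 2). The default s solves Q = 1.6, a typical physiological
value. Saccade duration obeys the main sequence
duration = 20 ms + 2.5 ms/deg × amplitude. Latency is Gaussian
(200 ± 30 ms, floored at 100 ms). Pursuit tracks the target velocity at a
programmable gain (default 0.92); positional error beyond 1.5° triggers a
catch-up saccade after 125 ms latency, aimed at the target's anticipated
landing-time position. Anti-saccade trials err toward the cue with the
programmed probability, followed by a corrective saccade. Premature
saccades are a Poisson process (default 0.10 /s of fixation). Additive
Gaussian position noise defaults to 0.05° RMS (video-oculography grade),
and one 150 ms blink (invalid samples) is inserted per ~30 s, placed clear
of logged events so the ground-truth log stays a valid oracle.

The pursuit target circles at radius 8° with a phase speed of 120°/s
(linear speed ≈ 16.8°/s). A much slower target would make velocity-gain
estimation meaningless at 1 kHz: the differentiated noise floor after a
20 ms smoothing window is a few deg/s, so the target speed must sit well
above it — 10–20°/s is the standard operating range for circular pursuit
paradigms.

**Cohort structure.** Outcomes follow
ONSD_{i,s} = 4.0 + u_i + shift_s + ε, with subject SD 0.4 mm, residual SD
0.15 mm, and session shifts (0, +0.1, +0.5, +0.3) mm — rising late-season,
within the healthy 3.5–5 mm band. A latent impairment profile
(0, 0.2, 1.0, 0.6) peaks late-season and shifts the oculomotor parameters
(+25 ms latency, +0.4 ms/° slope, −0.08 pursuit gain, +0.10 anti-saccade
error probability, +0.40 /s premature rate, +0.15° landing noise per unit
latent) and the ImPACT composites in their native worsening directions.
Composite subject offsets share a common cognitive factor (loading 0.85 on
the four cognitive composites, 0.15 on impulse control and symptom), which
produces the dominant, cognitively-weighted first PC the outcome
construction expects. All remaining distributional defaults (composite
means/SDs, between-subject oculomotor parameter SDs) are plausible values
chosen once and labelled synthetic; no real cohort statistics exist to
match.

Randomness derives from one root seed through counter-derived per-subject/
per-session substreams, so any session's content is independent of
evaluation order and cohorts are byte-identical across runs.

Three generator modes trade fidelity for speed: `traces` (full pipeline:
simulate → detect → extract, the default), `analytic` (feature vectors
drawn directly from their approximate sampling distributions — used where a
test needs many cohorts and the trace layer is not under test), and
`outcomes` (outcome table only).

**What the simulator does not emulate** — and hence what passing tests do
not establish about real recordings: real tracker artefacts beyond uniform
Gaussian noise and clean blinks (no drift, no partial dropouts, no
calibration error), head-motion coupling, saccadic oscillations or
glissades, fatigue/learning trends within a session, missing sessions, and
any causal link to measured head-impact dose (helmet telemetry is out of
scope). Results on synthetic data certify the machinery — detection
fidelity, leakage-free cross-validation, correct statistics — not clinical
performance.

## Event detection and features

Detection is a fixed-threshold velocity algorithm: positions low-pass
filtered with a centred 21-sample moving average, speed as the Euclidean
norm of the centred-difference derivative, saccades as maximal spans above
30°/s lasting ≥ 4 ms, spans closer than 20 ms merged, events below 0.5°
amplitude or touching the (±50 ms padded) blink mask dropped whole —
truncating would corrupt kinematics. Amplitude is measured between the
positions at onset and offset and duration as offset − onset, a consistent
pair of definitions under which Q ≥ 1 holds exactly. At 1 kHz with low
noise a fixed threshold is reproducible and adequate; every constant is a
keyword argument. Inter-saccade spans ≥ 40 ms become fixations (pursuit
task: pursuit epochs).

Feature conventions: a saccade launched < 80 ms after a target step is
premature, ≥ 80 ms is the response (standard anticipation cutoff);
"accuracy of saccades" is implemented as landing error in degrees;
time-to-fixate is the delay until gaze stays within 2° of the target for
100 ms; pursuit gain is the per-cycle median of eye speed / target speed
excluding saccades and each cycle's first 100 ms; the first 500 ms of the
first pursuit cycle is treated as acquisition, not catch-up; the
main-sequence slope is duration-vs-amplitude. The registry holds 29
features (16 central, 13 dispersion channels). Missing trials yield NaN —
imputation happens only inside the modelling stage, from training folds,
keeping extraction pure and cross-validation leakage-free. "Fixations
prematurely broken" and premature saccades are implemented as one
premature-saccade family with per-task counts.

## Season statistics

Per-session one-sample two-sided t-tests of normalized deltas against zero
(a paired test against baseline is algebraically the same thing); Cohen's d
with (n−1)-weighted pooled SD and the conventional magnitude labels
(negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large); Pearson and
Spearman correlations of ONSD deltas against composite deltas with baseline
(0,0) rows excluded; linear vs quadratic least-squares fits compared by
adjusted R² with F-test p-values; Cook's distance per observation with
D > 1 flagged. No multiple-testing correction is applied; reports carry the
count of tests performed. When a fit is numerically exact (residual mean
square ~ 0), Cook's D is defined as 0 rather than the indeterminate ratio.

## Known limitations

* The permutation-null distribution of the nested-LOSO mixed-model
  correlation is wide (SD ≈ 0.17 with 30 subjects): chance subject
  clustering in a permuted outcome is partially absorbed by the random
  intercept. Null checks therefore assess the centre of the null
  distribution, not single draws.
* The inner loop's fixed-λ approximation (see Estimation) is exact in the
  fixed effects but not in the variance components per inner fold.
* The fixed 30°/s threshold under-segments slow, small saccades and clips
  the tails of slow velocity profiles; detector-level Q-ratios of
  low-peak-velocity events are biased accordingly (the triangular-profile
  check in the tests lowers the threshold for exactly this reason).
* Problem sizes in the test suite are the study's own (30 × 4 cohort, full
  task lengths); the detector oracle uses 20 trials and statistical
  calibration checks use 20 cohort replicates, sizes chosen to make
  sampling error small relative to the tested tolerances.
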